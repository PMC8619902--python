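"""All-vs-all association scanning with type/normality-driven test dispatch.

Every unordered pair of features is compared with a statistical test chosen
from the features' data types and, for numeric data, their normality:

===================  =========================================  ===============
pair                 condition                                  test
===================  =========================================  ===============
numeric / numeric    both samples normal                        Pearson
numeric / numeric    at least one sample non-normal             Spearman
nominal / nominal    any contingency cell below five            (skipped)
nominal / nominal    all contingency cells at least five        chi-squared
numeric / nominal    every category's values normal             one-way ANOVA
numeric / nominal    some category non-normal                   Kruskal-Wallis
===================  =========================================  ===============

Normality is the D'Agostino-Pearson omnibus skew/kurtosis test at
``alpha = 0.05``; samples smaller than 8 are deemed non-normal (the
omnibus statistic is undefined there, and the non-parametric branch is the
safe one).  The chi-squared test uses observed cell counts without the
Yates continuity correction.

The family-wise error rate is controlled by Bonferroni: the base alpha is
divided by the full number of planned comparisons m(m-1)/2 — including
pairs that end up skipped — and only pairs with p <= alpha are stored.
p-values that underflow double precision (p <= 5e-324, the smallest
positive subnormal) are kept with an explicit underflow marker and treated
as "maximally significant" downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import NOMINAL, NUMERIC, MergedDataset

__all__ = [
    "MAX_SIGNIFICANT_P",
    "UNDERFLOW_TOKEN",
    "TestSelection",
    "PairResult",
    "SignificantPairStore",
    "n_pairwise",
    "bonferroni_alpha",
    "is_normal",
    "select_test",
    "compare_pair",
    "scan_all",
]

#: smallest positive representable double; p-values at or below it are
#: "maximally significant"
MAX_SIGNIFICANT_P = 5e-324

#: how underflowed p-values are written in CSV output
UNDERFLOW_TOKEN = "0.0E0_UNDERFLOW"

PEARSON = "pearson"
SPEARMAN = "spearman"
CHI_SQUARED = "chi_squared"
ANOVA = "anova"
KRUSKAL_WALLIS = "kruskal_wallis"
SKIPPED = "skipped"


def n_pairwise(m: int) -> int:
    """Number of unordered pairs (self-comparisons excluded): m(m-1)/2."""
    if m < 0:
        raise ValueError("feature count must be non-negative")
    return m * (m - 1) // 2


def bonferroni_alpha(base_alpha: float, n_comparisons: int) -> float:
    """Family-wise corrected significance level: base_alpha / n_comparisons."""
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return base_alpha / n_comparisons


def is_normal(values: np.ndarray, alpha: float = 0.05) -> bool:
    """Omnibus skew/kurtosis normality check.

    Returns True iff the D'Agostino-Pearson test fails to reject normality
    at ``alpha``.  Samples smaller than 8 (or degenerate constant samples)
    return False and take the non-parametric branch.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 8 or np.ptp(x) == 0.0:
        return False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = stats.normaltest(x)
    return bool(p > alpha)


@dataclass(frozen=True)
class TestSelection:
    """The test chosen for one pair, or a skip with its reason."""

    __test__ = False  # not a pytest collection target

    test: str
    reason: str = ""

    def __post_init__(self) -> None:
        if self.test == SKIPPED and not self.reason:
            raise ValueError("a skipped selection must carry a reason")
        if self.test != SKIPPED and self.reason:
            raise ValueError("only skipped selections carry a reason")


def select_test(
    kind_a: str,
    kind_b: str,
    normal_a: bool | None = None,
    normal_b: bool | None = None,
    all_categories_normal: bool | None = None,
    contingency_min_cell: int | None = None,
) -> TestSelection:
    """Dispatch table mapping pair conditions to a statistical test."""
    kinds = {kind_a, kind_b}
    if kinds == {NUMERIC}:
        if normal_a and normal_b:
            return TestSelection(PEARSON)
        return TestSelection(SPEARMAN)
    if kinds == {NOMINAL}:
        if contingency_min_cell is not None and contingency_min_cell < 5:
            return TestSelection(SKIPPED, reason="contingency cell < 5")
        return TestSelection(CHI_SQUARED)
    if kinds == {NUMERIC, NOMINAL}:
        if all_categories_normal:
            return TestSelection(ANOVA)
        return TestSelection(KRUSKAL_WALLIS)
    raise ValueError(f"unknown feature kinds: {kind_a!r}, {kind_b!r}")


@dataclass(frozen=True)
class PairResult:
    """Outcome of one pairwise comparison (canonical order: feature_a < feature_b)."""

    feature_a: str
    feature_b: str
    selection: TestSelection
    statistic: float = math.nan
    p_value: float | None = None

    def __post_init__(self) -> None:
        if self.feature_a == self.feature_b:
            raise ValueError("self-comparison is not allowed")
        skipped = self.selection.test == SKIPPED
        if skipped and self.p_value is not None:
            raise ValueError("skipped comparisons carry no p-value")
        if not skipped and self.p_value is None:
            raise ValueError("executed comparisons must carry a p-value")

    @property
    def is_underflow(self) -> bool:
        return self.p_value is not None and self.p_value <= MAX_SIGNIFICANT_P

    def significant_at(self, alpha: float) -> bool:
        return self.p_value is not None and self.p_value <= alpha


def _canonical(a: str, b: str) -> tuple[str, str, bool]:
    return (a, b, False) if a < b else (b, a, True)


def compare_pair(
    values_a: np.ndarray,
    kind_a: str,
    values_b: np.ndarray,
    kind_b: str,
    name_a: str = "A",
    name_b: str = "B",
    normality_alpha: float = 0.05,
) -> PairResult:
    """Select and run the appropriate test for one aligned feature pair.

    Inputs must be aligned on the same patients with no unknowns (the
    pipeline imputes first).  The result is symmetric in its arguments:
    the pair is reported in canonical (sorted) feature order and the same
    test is chosen either way.
    """
    ca, cb, swapped = _canonical(name_a, name_b)
    if swapped:
        values_a, values_b = values_b, values_a
        kind_a, kind_b = kind_b, kind_a

    def skip(reason: str) -> PairResult:
        return PairResult(ca, cb, TestSelection(SKIPPED, reason=reason))

    if kind_a == NUMERIC and kind_b == NUMERIC:
        x = np.asarray(values_a, dtype=float)
        y = np.asarray(values_b, dtype=float)
        if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
            return skip("constant numeric feature")
        sel = select_test(kind_a, kind_b, is_normal(x, normality_alpha),
                          is_normal(y, normality_alpha))
        if sel.test == PEARSON:
            res = stats.pearsonr(x, y)
        else:
            res = stats.spearmanr(x, y)
        stat, p = float(res.statistic), float(res.pvalue)
        if math.isnan(p):
            return skip("test statistic undefined")
        return PairResult(ca, cb, sel, statistic=stat, p_value=p)

    if kind_a == NOMINAL and kind_b == NOMINAL:
        table = pd.crosstab(pd.Series(values_a), pd.Series(values_b)).to_numpy()
        if table.shape[0] < 2 or table.shape[1] < 2:
            return skip("fewer than 2 categories")
        sel = select_test(kind_a, kind_b, contingency_min_cell=int(table.min()))
        if sel.test == SKIPPED:
            return PairResult(ca, cb, sel)
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        return PairResult(ca, cb, sel, statistic=float(chi2), p_value=float(p))

    # numeric vs nominal (either order; canonicalize to numeric first)
    if kind_a == NOMINAL:
        values_a, values_b = values_b, values_a
    x = np.asarray(values_a, dtype=float)
    labels = pd.Series(values_b)
    groups = [x[(labels == lev).to_numpy()] for lev in labels.dropna().unique()]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        return skip("fewer than 2 categories")
    all_norm = all(is_normal(g, normality_alpha) for g in groups)
    sel = select_test(NUMERIC, NOMINAL, all_categories_normal=all_norm)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if sel.test == ANOVA:
                stat, p = stats.f_oneway(*groups)
            else:
                stat, p = stats.kruskal(*groups)
    except ValueError as exc:  # e.g. all values identical
        return skip(f"test preconditions failed: {exc}")
    if math.isnan(p):
        return skip("test statistic undefined")
    return PairResult(ca, cb, sel, statistic=float(stat), p_value=float(p))


class SignificantPairStore:
    """Retained significant pairs, queryable symmetrically by feature."""

    def __init__(self, alpha: float, pairs: Iterable[PairResult]):
        self.alpha = alpha
        self.pairs: list[PairResult] = sorted(
            pairs, key=lambda r: (r.feature_a, r.feature_b)
        )
        for r in self.pairs:
            if not r.significant_at(alpha):
                raise ValueError(
                    f"pair ({r.feature_a}, {r.feature_b}) with p={r.p_value} "
                    f"exceeds alpha={alpha}"
                )
        self._index: dict[str, list[PairResult]] = {}
        for r in self.pairs:
            self._index.setdefault(r.feature_a, []).append(r)
            self._index.setdefault(r.feature_b, []).append(r)

    def __len__(self) -> int:
        return len(self.pairs)

    def pairs_for(self, feature: str) -> list[PairResult]:
        return list(self._index.get(feature, []))

    def features(self) -> list[str]:
        return sorted(self._index)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.pairs:
            rows.append(
                {
                    "feature_a": r.feature_a,
                    "feature_b": r.feature_b,
                    "test": r.selection.test,
                    "statistic": r.statistic,
                    "p_value": UNDERFLOW_TOKEN if r.is_underflow else repr(r.p_value),
                }
            )
        return pd.DataFrame(
            rows, columns=["feature_a", "feature_b", "test", "statistic", "p_value"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, alpha: float) -> "SignificantPairStore":
        df = pd.read_csv(path, dtype={"p_value": str})
        pairs = []
        for row in df.itertuples(index=False):
            p = 0.0 if row.p_value == UNDERFLOW_TOKEN else float(row.p_value)
            pairs.append(
                PairResult(
                    row.feature_a,
                    row.feature_b,
                    TestSelection(row.test),
                    statistic=float(row.statistic),
                    p_value=p,
                )
            )
        return cls(alpha, pairs)


def _scan_chunk(
    pair_index: Sequence[tuple[int, int]],
    names: Sequence[str],
    columns: dict[str, np.ndarray],
    kinds: dict[str, str],
    alpha: float,
    normality_alpha: float,
) -> list[PairResult]:
    out = []
    for i, j in pair_index:
        a, b = names[i], names[j]
        res = compare_pair(
            columns[a], kinds[a], columns[b], kinds[b], a, b, normality_alpha
        )
        if res.significant_at(alpha):
            out.append(res)
    return out


def scan_all(
    dataset: MergedDataset,
    base_alpha: float = 0.05,
    n_workers: int = 1,
    normality_alpha: float = 0.05,
    chunk_size: int = 2000,
) -> SignificantPairStore:
    """Scan every unordered feature pair, retaining p <= Bonferroni alpha.

    The alpha divisor is the full planned family m(m-1)/2 over *all*
    features, even when some pairs are later skipped by the contingency
    rule.  Pairs are enumerated in canonical (lexicographic) order and the
    result is independent of worker count and chunk boundaries.
    """
    names = sorted(dataset.feature_names)
    m = len(names)
    if m < 2:
        raise ValueError("need at least 2 features to scan")
    alpha = bonferroni_alpha(base_alpha, n_pairwise(m))

    columns = {}
    for name in names:
        col = dataset.data[name]
        if dataset.kinds[name] == NUMERIC:
            columns[name] = pd.to_numeric(col).to_numpy(dtype=float)
        else:
            columns[name] = col.to_numpy()
    kinds = dict(dataset.kinds)

    pair_index = [(i, j) for i in range(m) for j in range(i + 1, m)]
    chunks = [
        pair_index[k : k + chunk_size] for k in range(0, len(pair_index), chunk_size)
    ]
    if n_workers <= 1 or len(chunks) == 1:
        results = [
            _scan_chunk(c, names, columns, kinds, alpha, normality_alpha)
            for c in chunks
        ]
    else:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=n_workers)(
            delayed(_scan_chunk)(c, names, columns, kinds, alpha, normality_alpha)
            for c in chunks
        )
    pairs = [r for chunk in results for r in chunk]
    return SignificantPairStore(alpha, pairs)
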