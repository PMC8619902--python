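"""Stratified subgroup revalidation of maximally significant pairs.

The full-data scan can be driven by a subgroup of patients.  To check
whether the strongest associations hold across the population, the
patients are split by sex and by clinical dementia rating (CDR = 0
cognitively normal, CDR = 0.5 mild cognitive impairment, CDR >= 1
dementia), and every pair that reached maximal significance in the full
data (p at or below the double-precision underflow threshold, 5e-324) is
re-tested inside each subset with the same dispatch logic — normality and
contingency conditions are re-assessed on the subset, since sample
properties change.

Each pair is classified per subset as retained (still maximally
significant), lost to untestability (a feature collapsed to one value, or
the chosen test's preconditions fail in the subset), or lost to reduced
significance (testable, but p above the threshold).  The three classes
partition the pairs exactly, so ``full = retained + lost_untestable +
lost_significance`` both per feature and in aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .engine import (
    MAX_SIGNIFICANT_P,
    PairResult,
    SignificantPairStore,
    compare_pair,
)
from .preprocess import MergedDataset
from .synthetic import DEMENTIA_COLUMN, SEX_COLUMN

__all__ = [
    "SubsetSpec",
    "SubsetDataset",
    "RevalidationReport",
    "sex_subset_specs",
    "dementia_subset_specs",
    "make_subsets",
    "extract_max_significant",
    "revalidate",
]

RETAINED = "retained"
LOST_UNTESTABLE = "lost_untestable"
LOST_SIGNIFICANCE = "lost_significance"


@dataclass(frozen=True)
class SubsetSpec:
    """One patient subset: a defining column plus a predicate on its values.

    ``op`` is one of ``eq`` (equality, numeric-aware) or ``ge`` (numeric
    greater-or-equal), keeping specs serializable.
    """

    name: str
    column: str
    op: str
    value: object

    def mask(self, series: pd.Series) -> np.ndarray:
        if self.op == "ge":
            vals = pd.to_numeric(series, errors="coerce")
            return (vals >= float(self.value)).to_numpy()
        if self.op == "eq":
            if isinstance(self.value, (int, float)):
                vals = pd.to_numeric(series, errors="coerce")
                return (vals == float(self.value)).to_numpy()
            return (series.astype(str) == str(self.value)).to_numpy()
        raise ValueError(f"unknown predicate op {self.op!r}")


def sex_subset_specs(column: str = SEX_COLUMN) -> list[SubsetSpec]:
    return [
        SubsetSpec("female", column, "eq", "F"),
        SubsetSpec("male", column, "eq", "M"),
    ]


def dementia_subset_specs(column: str = DEMENTIA_COLUMN) -> list[SubsetSpec]:
    return [
        SubsetSpec("cdr_0", column, "eq", 0.0),
        SubsetSpec("cdr_0.5", column, "eq", 0.5),
        SubsetSpec("cdr_ge_1", column, "ge", 1.0),
    ]


@dataclass
class SubsetDataset:
    """A row-filtered view of the merged dataset plus its untestable features."""

    name: str
    dataset: MergedDataset
    untestable: set[str] = field(default_factory=set)

    @property
    def n_patients(self) -> int:
        return len(self.dataset.data)


def _untestable_features(data: pd.DataFrame) -> set[str]:
    out = set()
    for c in data.columns:
        if data[c].dropna().nunique() < 2:
            out.add(c)
    return out


def make_subsets(
    dataset: MergedDataset, specs: Sequence[SubsetSpec]
) -> list[SubsetDataset]:
    """Row-filter the dataset per spec, flagging features that become untestable.

    A feature with fewer than two distinct values inside a subset is
    flagged (not dropped), so downstream accounting can attribute losses
    to untestability explicitly.  An empty subset is an error naming the
    offending spec.
    """
    out = []
    for spec in specs:
        if spec.column not in dataset.data.columns:
            raise KeyError(
                f"subset {spec.name!r}: column {spec.column!r} not in dataset"
            )
        mask = spec.mask(dataset.data[spec.column])
        if not mask.any():
            raise ValueError(f"subset {spec.name!r} selects no patients")
        sub = MergedDataset(
            data=dataset.data.loc[mask].copy(),
            kinds=dict(dataset.kinds),
            domains=dict(dataset.domains),
            counts=dict(dataset.counts),
        )
        out.append(
            SubsetDataset(
                name=spec.name,
                dataset=sub,
                untestable=_untestable_features(sub.data),
            )
        )
    return out


def extract_max_significant(store: SignificantPairStore) -> list[PairResult]:
    """Pairs whose p-value underflowed (p <= 5e-324): the strongest associations."""
    return [r for r in store.pairs if r.is_underflow]


@dataclass
class RevalidationReport:
    """Per-feature and aggregate accounting of a subset revalidation."""

    subset_name: str
    per_pair: pd.DataFrame  # feature_a, feature_b, outcome
    per_feature: pd.DataFrame  # feature, full, retained, lost_*, lost_*

    @property
    def totals(self) -> dict[str, int]:
        n = len(self.per_pair)
        out = {"full": n}
        for cls in (RETAINED, LOST_UNTESTABLE, LOST_SIGNIFICANCE):
            out[cls] = int((self.per_pair["outcome"] == cls).sum())
        return out

    def loss_statistics(self) -> dict[str, float]:
        """Mean and population SD of per-feature losses.

        Computed over features having at least one maximally significant
        pair in the full data (all features in ``per_feature`` qualify by
        construction).
        """
        losses = (
            self.per_feature["lost_untestable"]
            + self.per_feature["lost_significance"]
        ).to_numpy(dtype=float)
        if losses.size == 0:
            return {"mean_loss": 0.0, "sd_loss": 0.0, "n_features": 0}
        return {
            "mean_loss": float(np.mean(losses)),
            "sd_loss": float(np.std(losses)),
            "n_features": int(losses.size),
        }


def revalidate(
    pairs: Iterable[PairResult],
    subset: SubsetDataset,
    max_alpha: float = MAX_SIGNIFICANT_P,
    normality_alpha: float = 0.05,
) -> RevalidationReport:
    """Re-test maximally significant pairs inside one subset.

    Dispatch (normality, contingency conditions) is re-evaluated on the
    subset's data.  Classification: ``lost_untestable`` when either
    feature is flagged untestable or the re-dispatched test cannot run;
    ``retained`` when the re-test's p-value is at or below ``max_alpha``;
    ``lost_significance`` otherwise.
    """
    data = subset.dataset.data
    kinds = subset.dataset.kinds
    rows = []
    for r in pairs:
        a, b = r.feature_a, r.feature_b
        if a in subset.untestable or b in subset.untestable:
            outcome = LOST_UNTESTABLE
        else:
            res = compare_pair(
                data[a].to_numpy(),
                kinds[a],
                data[b].to_numpy(),
                kinds[b],
                a,
                b,
                normality_alpha,
            )
            if res.p_value is None:
                outcome = LOST_UNTESTABLE
            elif res.p_value <= max_alpha:
                outcome = RETAINED
            else:
                outcome = LOST_SIGNIFICANCE
        rows.append({"feature_a": a, "feature_b": b, "outcome": outcome})
    per_pair = pd.DataFrame(rows, columns=["feature_a", "feature_b", "outcome"])

    feat_rows: dict[str, dict[str, int]] = {}
    for row in rows:
        for f in (row["feature_a"], row["feature_b"]):
            rec = feat_rows.setdefault(
                f,
                {"full": 0, RETAINED: 0, LOST_UNTESTABLE: 0, LOST_SIGNIFICANCE: 0},
            )
            rec["full"] += 1
            rec[row["outcome"]] += 1
    per_feature = pd.DataFrame(
        [
            {"feature": f, **rec}
            for f, rec in sorted(feat_rows.items())
        ],
        columns=["feature", "full", RETAINED, LOST_UNTESTABLE, LOST_SIGNIFICANCE],
    )
    return RevalidationReport(
        subset_name=subset.name, per_pair=per_pair, per_feature=per_feature
    )
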