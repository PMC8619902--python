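"""Cleaning, typing, collapsing, merging, filtering and imputing tables.

The pipeline turns raw visit-level tables from several domains into one
analysis-ready patient x feature dataset:

1. headers are uppercased and tables joined on the patient ID, taking the
   most recent value for longitudinal features;
2. each column is typed numeric or nominal from its observed values
   (number-valued columns with fewer than 10 distinct values are treated
   as nominal; text columns with more than 20 distinct values are dropped
   as identifier-like);
3. constant columns, columns with under 80% known values, and nominal
   columns with any category under 20 patients are removed, with a
   per-feature drop-reason log;
4. remaining unknowns are imputed — numeric by an iterative Bayesian-ridge
   regression imputer, nominal by the modal category (ties broken
   lexicographically).

Unknown values are represented as NaN throughout (empty fields in CSV).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NUMERIC = "numeric"
NOMINAL = "nominal"
DROP = "drop"

#: distinct-value threshold below which a number-valued column is nominal
NUMERIC_MIN_UNIQUE = 10
#: distinct-value threshold above which a text column is dropped
NOMINAL_MAX_UNIQUE = 20
#: minimum fraction of known values for a feature to be kept
MIN_KNOWN_FRACTION = 0.80
#: minimum patients per observed category of a nominal feature
MIN_CATEGORY_COUNT = 20

#: column names recognized as the patient identifier (checked uppercase)
DEFAULT_ID_COLUMNS = ("RID", "PTID", "PATIENT_ID")
DEFAULT_DATE_COLUMNS = ("EXAMDATE", "DATE", "VISDATE")

__all__ = [
    "NUMERIC",
    "NOMINAL",
    "DROP",
    "DomainTable",
    "MergedDataset",
    "infer_feature_kind",
    "infer_kinds",
    "collapse_longitudinal",
    "merge_tables",
    "filter_features",
    "impute",
    "shape_expression",
    "assemble",
    "combined_feature_count",
]


@dataclass
class DomainTable:
    """One analysis domain: patients (rows) x typed features (columns)."""

    data: pd.DataFrame  # index: unique patient IDs
    kinds: dict[str, str]  # feature -> NUMERIC | NOMINAL
    domain: str

    def __post_init__(self) -> None:
        if not self.data.index.is_unique:
            raise ValueError("patient IDs must be unique")
        missing = set(self.data.columns) - set(self.kinds)
        if missing:
            raise ValueError(f"columns without a declared kind: {sorted(missing)}")

    @property
    def patient_ids(self) -> list:
        return list(self.data.index)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]


@dataclass
class MergedDataset:
    """The assembled multi-domain dataset restricted to common patients."""

    data: pd.DataFrame
    kinds: dict[str, str]
    domains: dict[str, str]  # feature -> domain label
    counts: dict[str, int]  # domain label -> feature count

    @property
    def total_features(self) -> int:
        return combined_feature_count(*self.counts.values())

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)


def combined_feature_count(*counts: int) -> int:
    """Total feature count of a combined dataset (sum over domains)."""
    for c in counts:
        if c < 0:
            raise ValueError("feature counts must be non-negative")
    return int(sum(counts))


def _coerce_numeric(known: pd.Series) -> pd.Series | None:
    """Return the numeric view of a fully number-valued series, else None."""
    if known.empty:
        return None
    coerced = pd.to_numeric(known, errors="coerce")
    if coerced.isna().any():  # at least one non-numeric token -> text column
        return None
    return coerced


def infer_feature_kind(values: pd.Series) -> str:
    """Classify a raw column as numeric, nominal, or drop.

    Number-valued columns are numeric unless they have fewer than
    ``NUMERIC_MIN_UNIQUE`` distinct observed values (then nominal).  Text
    columns (including mixed text/number, treated conservatively as text)
    are nominal unless they exceed ``NOMINAL_MAX_UNIQUE`` distinct observed
    values, in which case they are identifier-like and dropped.  Unknown
    markers never count as a distinct value.
    """
    known = values.dropna()
    numeric = _coerce_numeric(known)
    if numeric is not None:
        return NUMERIC if numeric.nunique() >= NUMERIC_MIN_UNIQUE else NOMINAL
    return NOMINAL if known.nunique() <= NOMINAL_MAX_UNIQUE else DROP


def infer_kinds(df: pd.DataFrame) -> tuple[dict[str, str], list[str]]:
    """Type every column; returns (kinds for kept columns, dropped names)."""
    kinds: dict[str, str] = {}
    dropped: list[str] = []
    for name in df.columns:
        kind = infer_feature_kind(df[name])
        if kind == DROP:
            dropped.append(name)
        else:
            kinds[name] = kind
    return kinds, dropped


def _date_sort_key(dates: pd.Series) -> pd.Series:
    """Numeric sort key for recording dates; unknown dates sort first."""
    numeric = pd.to_numeric(dates, errors="coerce")
    if numeric.isna().all() and dates.notna().any():
        parsed = pd.to_datetime(dates, errors="coerce", format="mixed")
        as_int = parsed.to_numpy(dtype="datetime64[ns]").view("i8").astype(float)
        numeric = pd.Series(
            np.where(parsed.isna(), np.nan, as_int), index=dates.index
        )
    return numeric.astype(float).fillna(-np.inf)


def collapse_longitudinal(
    table: pd.DataFrame,
    id_column: str,
    date_column: str | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse a visit-level table to one row per patient.

    Per feature, the value from the latest dated visit at which the feature
    is known wins; a known value at an earlier visit beats an unknown at a
    later one.  Rows without a date lose to any dated row; among undated
    rows (and among exact date ties) the first occurrence in input order
    wins, making the arbitrary choice reproducible.

    Returns the collapsed table (indexed by patient ID) and each patient's
    latest known date (-inf when no dates are available), which downstream
    merging uses to resolve cross-table column collisions.
    """
    if id_column not in table.columns:
        raise KeyError(f"missing patient-ID column {id_column!r}")
    work = table.copy()
    if date_column is not None and date_column in work.columns:
        key = _date_sort_key(work[date_column])
        work = work.drop(columns=[date_column])
    else:
        key = pd.Series(-np.inf, index=work.index)
    order = np.lexsort((-np.arange(len(work)), key.to_numpy()))
    work = work.iloc[order]
    key = key.iloc[order]
    grouped = work.groupby(id_column, sort=True)
    collapsed = grouped.last()  # per column: last non-null in sorted order
    last_date = key.groupby(work[id_column].to_numpy()).max()
    last_date = last_date.reindex(collapsed.index)
    return collapsed, last_date


def _find_id_column(
    columns: Iterable[str], candidates: Sequence[str]
) -> str | None:
    upper = {c.upper(): c for c in columns}
    for cand in candidates:
        if cand.upper() in upper:
            return upper[cand.upper()]
    return None


def merge_tables(
    tables: Sequence[pd.DataFrame],
    id_columns: Sequence[str] = DEFAULT_ID_COLUMNS,
    date_columns: Sequence[str] = DEFAULT_DATE_COLUMNS,
) -> tuple[pd.DataFrame, list[str]]:
    """Merge raw domain tables into one patient-indexed table.

    Headers are uppercased before anything else, so a column appearing as
    ``icv`` in one table and ``ICV`` in another collides (and merges).
    Each table is collapsed to one row per patient, then columns are
    unioned across tables.  When two tables carry the same column, the
    value whose source record is most recent (per patient) wins; undated
    sources lose to dated ones, and residual ties go to the earliest table
    in input order.  Tables without a recognizable patient-ID column are
    skipped with a warning (returned, and also emitted via ``warnings``).
    """
    collapsed: list[pd.DataFrame] = []
    dates: list[pd.Series] = []
    skipped: list[str] = []
    for i, raw in enumerate(tables):
        df = raw.copy()
        df.columns = [str(c).upper() for c in df.columns]
        id_col = _find_id_column(df.columns, id_columns)
        if id_col is None:
            msg = f"table {i}: no patient-ID column among {list(id_columns)}; skipped"
            warnings.warn(msg)
            skipped.append(msg)
            continue
        date_col = _find_id_column(df.columns, date_columns)
        ctab, last = collapse_longitudinal(df, id_col, date_col)
        ctab.index.name = "PATIENT"
        collapsed.append(ctab)
        dates.append(last)
    if not collapsed:
        raise ValueError("no mergeable tables (none had a patient-ID column)")

    all_ids = sorted(set().union(*[set(t.index) for t in collapsed]))
    out: dict[str, pd.Series] = {}
    best_date: dict[str, pd.Series] = {}
    for ctab, last in zip(collapsed, dates):
        tab = ctab.reindex(all_ids)
        last = last.reindex(all_ids).astype(float).fillna(-np.inf)
        for col in tab.columns:
            vals = tab[col]
            if col not in out:
                out[col] = vals.copy()
                d = last.copy()
                d[vals.isna()] = -np.inf
                best_date[col] = d
            else:
                cand_date = last.copy()
                cand_date[vals.isna()] = -np.inf
                take = (cand_date > best_date[col]) & vals.notna()
                # a known value always beats a missing one, regardless of date
                take |= out[col].isna() & vals.notna()
                out[col] = out[col].mask(take, vals)
                best_date[col] = best_date[col].mask(take, cand_date)
    merged = pd.DataFrame(out, index=pd.Index(all_ids, name="PATIENT"))
    return merged, skipped


def filter_features(
    table: DomainTable,
    min_known_fraction: float = MIN_KNOWN_FRACTION,
    min_category_count: int = MIN_CATEGORY_COUNT,
) -> tuple[DomainTable, pd.DataFrame]:
    """Drop uninformative or under-observed features, logging one reason each.

    Filters are applied in a fixed order; a column is logged under the
    first rule it trips: (1) fewer than two distinct observed values;
    (2) known fraction below ``min_known_fraction``; (3) nominal with any
    observed category smaller than ``min_category_count`` patients.
    """
    reasons: list[tuple[str, str]] = []
    keep: list[str] = []
    n = len(table.data)
    for name in table.data.columns:
        col = table.data[name]
        known = col.dropna()
        if known.nunique() < 2:
            reasons.append((name, "constant"))
            continue
        if n > 0 and len(known) / n < min_known_fraction:
            reasons.append((name, "low_known_fraction"))
            continue
        if table.kinds[name] == NOMINAL and known.value_counts().min() < min_category_count:
            reasons.append((name, "small_category"))
            continue
        keep.append(name)
    log = pd.DataFrame(reasons, columns=["feature", "reason"])
    filtered = DomainTable(
        data=table.data[keep].copy(),
        kinds={k: table.kinds[k] for k in keep},
        domain=table.domain,
    )
    return filtered, log


def impute(table: DomainTable, seed: int = 0, max_iter: int = 10) -> DomainTable:
    """Fill every unknown value; known values are left untouched.

    Numeric unknowns are filled by scikit-learn's iterative imputer with a
    Bayesian-ridge regressor over the other numeric features (deterministic
    for a fixed seed).  Nominal unknowns become the modal observed
    category, ties broken lexicographically.
    """
    data = table.data.copy()
    num_cols = [c for c in data.columns if table.kinds[c] == NUMERIC]
    nom_cols = [c for c in data.columns if table.kinds[c] == NOMINAL]

    if num_cols:
        block = data[num_cols].apply(pd.to_numeric)
        if block.isna().any().any():
            if block.notna().sum().min() == 0:
                empty = block.columns[block.notna().sum() == 0]
                raise ValueError(
                    f"numeric feature(s) with zero known values: {list(empty)}"
                )
            from sklearn.experimental import enable_iterative_imputer  # noqa: F401
            from sklearn.impute import IterativeImputer
            from sklearn.linear_model import BayesianRidge

            imp = IterativeImputer(
                estimator=BayesianRidge(),
                max_iter=max_iter,
                random_state=seed,
                sample_posterior=False,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                filled = imp.fit_transform(block.to_numpy(dtype=float))
            filled_df = pd.DataFrame(filled, index=block.index, columns=block.columns)
            # guarantee known cells are bit-identical to the input
            result = block.where(block.notna(), filled_df)
            for c in num_cols:
                data[c] = result[c]

    for c in nom_cols:
        col = data[c]
        if col.isna().any():
            counts = col.dropna().value_counts()
            top = counts.max()
            modal = sorted(str(v) for v in counts[counts == top].index)[0]
            # preserve the original dtype of the category labels
            candidates = [v for v in counts.index if str(v) == modal]
            data[c] = col.fillna(candidates[0])

    return DomainTable(data=data, kinds=dict(table.kinds), domain=table.domain)


def shape_expression(raw: pd.DataFrame, domain: str = "expression") -> DomainTable:
    """Turn a features-as-rows expression matrix into a patient x probe table.

    The raw matrix must carry patient IDs as its column header (no header
    -> error).  After transposition, columns with an empty/unknown name
    (headerless) and columns whose values are not fully numeric (metadata)
    are removed; all retained columns are numeric.
    """
    if raw.columns.empty or any(str(c).strip() == "" for c in raw.columns):
        raise ValueError("expression matrix has no patient-ID header")
    wide = raw.T
    keep: dict[str, pd.Series] = {}
    for name in wide.columns:
        if name is None or (isinstance(name, float) and np.isnan(name)):
            continue
        if str(name).strip() == "":
            continue  # headerless
        numeric = _coerce_numeric(wide[name].dropna())
        if numeric is None:
            continue  # metadata
        keep[str(name)] = pd.to_numeric(wide[name])
    data = pd.DataFrame(keep, index=wide.index)
    data.index.name = "PATIENT"
    return DomainTable(
        data=data, kinds={c: NUMERIC for c in data.columns}, domain=domain
    )


def assemble(
    clinical: DomainTable,
    expression: DomainTable,
    image,  # LatentMatrix; structural duck-typing avoids a circular import
) -> MergedDataset:
    """Combine the three domains on the intersection of their patients."""
    image_table = image.to_domain_table() if hasattr(image, "to_domain_table") else image
    tables = [clinical, expression, image_table]
    common = set(tables[0].data.index)
    for t in tables[1:]:
        common &= set(t.data.index)
    if not common:
        raise ValueError("no patients common to all domains")
    ids = sorted(common)

    parts = []
    kinds: dict[str, str] = {}
    domains: dict[str, str] = {}
    counts: dict[str, int] = {}
    for t in tables:
        sub = t.data.loc[ids]
        parts.append(sub)
        kinds.update(t.kinds)
        for c in sub.columns:
            domains[c] = t.domain
        counts[t.domain] = sub.shape[1]
    data = pd.concat(parts, axis=1)
    if data.columns.duplicated().any():
        dupes = data.columns[data.columns.duplicated()].tolist()
        raise ValueError(f"duplicate feature names across domains: {dupes}")
    ds = MergedDataset(data=data, kinds=kinds, domains=domains, counts=counts)
    assert ds.total_features == data.shape[1]
    return ds
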