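"""Synthetic multi-domain datasets with planted correlation structure.

This module fabricates the three kinds of input the scanning pipeline
consumes, at desk scale, with every planted association recorded so that
downstream stages can be validated without any external data:

* a clinical-style visit-level table (mixed numeric/nominal columns,
  identifier-like metadata, duplicate columns under slightly different
  names, missing values, optional longitudinal duplication and
  sex / dementia-rating stratification columns);
* an expression-style wide matrix stored features-as-rows, with a metadata
  row and a headerless row injected so the shaping step has something to
  strip;
* per-patient ordered grayscale image stacks containing smooth geometric
  content (drifting elliptical blobs) that an autoencoder can actually
  compress.

Numeric correlation blocks are drawn from a multivariate normal with a
compound-symmetric correlation matrix, so the expected pairwise Pearson
correlation inside a block equals the requested value exactly.
Nominal-numeric associations are planted as per-category mean shifts,
which is what one-way ANOVA / Kruskal-Wallis detect.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpecificationError",
    "NominalSpec",
    "SyntheticSpec",
    "GroundTruth",
    "ImageStacks",
    "generate_tabular_domain",
    "generate_expression_domain",
    "generate_image_stacks",
    "write_table",
    "write_ground_truth",
    "read_ground_truth",
    "write_stacks",
    "read_stacks",
]

ID_COLUMN = "RID"
DATE_COLUMN = "EXAMDATE"
SEX_COLUMN = "PTGENDER"
DEMENTIA_COLUMN = "CDR"

#: categories used for the dementia-rating stratification column
#: (0 = cognitively normal, 0.5 = mild cognitive impairment, >= 1 = dementia)
DEMENTIA_LEVELS = (0.0, 0.5, 1.0, 2.0)
_DEMENTIA_PROBS = (0.40, 0.30, 0.20, 0.10)


class SpecificationError(ValueError):
    """A generator spec violates one of its invariants."""


@dataclass(frozen=True)
class NominalSpec:
    """One planted nominal feature.

    If ``associated`` is true, a numeric partner column is generated whose
    mean is shifted by ``effect_size`` (in units of the partner's standard
    deviation) per category, and the (nominal, partner) pair is recorded as
    a planted association.
    """

    n_categories: int
    associated: bool = False
    effect_size: float = 1.5


@dataclass
class SyntheticSpec:
    """Full description of one synthetic clinical-style table."""

    n_patients: int = 200
    numeric_blocks: list[tuple[int, float]] = field(default_factory=list)
    n_noise_numeric: int = 0
    nominal_specs: list[NominalSpec] = field(default_factory=list)
    missing_fraction_per_feature: list[float] = field(default_factory=list)
    n_metadata_columns: int = 0
    n_duplicate_pairs: int = 0
    longitudinal: bool = False
    visits_range: tuple[int, int] = (1, 3)
    sex_column: bool = False
    dementia_column: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise SpecificationError("n_patients must be >= 1")
        for size, rho in self.numeric_blocks:
            if size < 2:
                raise SpecificationError(
                    f"numeric_blocks: block_size must be >= 2, got {size}"
                )
            if not 0.0 <= rho <= 1.0:
                raise SpecificationError(
                    f"numeric_blocks: within_block_correlation must be in [0, 1], got {rho}"
                )
        for frac in self.missing_fraction_per_feature:
            if not 0.0 <= frac <= 1.0:
                raise SpecificationError(
                    f"missing_fraction_per_feature: fraction must be in [0, 1], got {frac}"
                )
        for ns in self.nominal_specs:
            if ns.n_categories < 2:
                raise SpecificationError(
                    f"nominal_specs: n_categories must be >= 2, got {ns.n_categories}"
                )
        if self.n_noise_numeric < 0:
            raise SpecificationError("n_noise_numeric must be >= 0")
        if self.n_metadata_columns < 0:
            raise SpecificationError("n_metadata_columns must be >= 0")
        if self.n_duplicate_pairs < 0:
            raise SpecificationError("n_duplicate_pairs must be >= 0")
        lo, hi = self.visits_range
        if not (1 <= lo <= hi):
            raise SpecificationError(
                f"visits_range must satisfy 1 <= lo <= hi, got {self.visits_range}"
            )


@dataclass
class GroundTruth:
    """Planted structure of a generated dataset.

    block_membership
        feature name -> block index, for every member of a correlated block.
    planted_associations
        feature-name pairs expected to reach significance downstream
        (within-block pairs, nominal/partner pairs, duplicate pairs).
    duplicate_pairs
        feature-name pairs that are bit-identical columns under different
        names.
    """

    block_membership: dict[str, int] = field(default_factory=dict)
    planted_associations: list[tuple[str, str]] = field(default_factory=list)
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "block_membership": self.block_membership,
                "planted_associations": [list(p) for p in self.planted_associations],
                "duplicate_pairs": [list(p) for p in self.duplicate_pairs],
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        raw = json.loads(text)
        return cls(
            block_membership=dict(raw["block_membership"]),
            planted_associations=[tuple(p) for p in raw["planted_associations"]],
            duplicate_pairs=[tuple(p) for p in raw["duplicate_pairs"]],
        )


def _patient_ids(n: int) -> list[str]:
    return [f"P{i:04d}" for i in range(n)]


def generate_tabular_domain(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a clinical-style table (visit-level if longitudinal).

    Returns the raw table plus the ground truth of planted structure.  The
    table always carries a patient-ID column; a date column is present only
    in longitudinal mode.  Missing cells are NaN (the package-wide unknown
    marker; written as empty fields in CSV).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    ids = _patient_ids(n)
    truth = GroundTruth()

    columns: dict[str, np.ndarray] = {}
    maskable: list[str] = []  # columns eligible for missingness, in order

    for b, (size, rho) in enumerate(spec.numeric_blocks):
        cov = np.full((size, size), rho, dtype=float)
        np.fill_diagonal(cov, 1.0)
        block = rng.multivariate_normal(np.zeros(size), cov, size=n)
        names = [f"BLK{b}_F{j}" for j in range(size)]
        for j, name in enumerate(names):
            columns[name] = block[:, j]
            truth.block_membership[name] = b
            maskable.append(name)
        for i in range(size):
            for j in range(i + 1, size):
                truth.planted_associations.append((names[i], names[j]))

    for i in range(spec.n_noise_numeric):
        name = f"NUM{i}"
        columns[name] = rng.standard_normal(n)
        maskable.append(name)

    for i, ns in enumerate(spec.nominal_specs):
        name = f"NOM{i}"
        cats = np.array([f"C{k}" for k in range(ns.n_categories)], dtype=object)
        codes = rng.integers(0, ns.n_categories, size=n)
        columns[name] = cats[codes]
        maskable.append(name)
        if ns.associated:
            partner = f"NOM{i}_SHIFT"
            columns[partner] = rng.standard_normal(n) + ns.effect_size * codes
            maskable.append(partner)
            truth.planted_associations.append((name, partner))

    # duplicate pairs: bit-identical columns under slightly different names
    for d in range(spec.n_duplicate_pairs):
        base = rng.standard_normal(n)
        a, b = f"DUP{d}", f"DUP{d}_BL"
        columns[a] = base
        columns[b] = base.copy()
        truth.duplicate_pairs.append((a, b))
        truth.planted_associations.append((a, b))

    # identifier-like metadata: unique text per row
    for m in range(spec.n_metadata_columns):
        columns[f"META{m}"] = np.array(
            [f"ID{m}_{rng.integers(0, 10**9):09d}_{i}" for i in range(n)],
            dtype=object,
        )

    if spec.sex_column:
        columns[SEX_COLUMN] = np.where(rng.random(n) < 0.55, "F", "M").astype(object)
    if spec.dementia_column:
        columns[DEMENTIA_COLUMN] = rng.choice(
            np.array(DEMENTIA_LEVELS), size=n, p=_DEMENTIA_PROBS
        )

    # missingness: fractions map positionally onto maskable feature columns
    # (duplicates, metadata and stratification columns stay fully observed so
    # duplicate pairs remain bit-identical and subsets stay well defined)
    if len(spec.missing_fraction_per_feature) > len(maskable):
        raise SpecificationError(
            "missing_fraction_per_feature: more fractions than eligible feature columns"
        )
    missing_mask: dict[str, np.ndarray] = {}
    for frac, name in zip(spec.missing_fraction_per_feature, maskable):
        missing_mask[name] = rng.random(n) < frac

    if not spec.longitudinal:
        table = pd.DataFrame({ID_COLUMN: ids})
        for name, vals in columns.items():
            col = pd.Series(vals, dtype=object if vals.dtype == object else float)
            mask = missing_mask.get(name)
            if mask is not None:
                col = col.mask(mask)
            table[name] = col.to_numpy()
        return table, truth

    # longitudinal expansion: the cross-sectional value above is the value at
    # the *latest* visit; earlier visits carry perturbed / re-drawn values.
    rows: list[dict] = []
    vlo, vhi = spec.visits_range
    for i, pid in enumerate(ids):
        n_visits = int(rng.integers(vlo, vhi + 1))
        days = np.sort(rng.choice(np.arange(1, 2000), size=n_visits, replace=False))
        for v, day in enumerate(days):
            last = v == n_visits - 1
            row: dict = {ID_COLUMN: pid, DATE_COLUMN: int(day)}
            for name, vals in columns.items():
                mask = missing_mask.get(name)
                if mask is not None and mask[i]:
                    row[name] = np.nan
                    continue
                if name in (SEX_COLUMN, DEMENTIA_COLUMN):
                    row[name] = vals[i]  # constant across visits
                elif name.startswith("META"):
                    row[name] = f"{vals[i]}_V{v}"
                elif last:
                    row[name] = vals[i]
                elif vals.dtype == object:
                    row[name] = vals[int(rng.integers(0, n))]
                else:
                    row[name] = float(vals[i]) + 0.5 * float(rng.standard_normal())
            rows.append(row)
    table = pd.DataFrame(rows)
    return table, truth


def generate_expression_domain(
    n_probes: int,
    n_patients: int,
    n_correlated_pairs: int = 0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate an expression-style matrix stored features-as-rows.

    The returned frame has probe names as the index and patient IDs as the
    column header, i.e. it must be transposed before analysis.  One
    metadata row (text values) and one headerless row (empty name) are
    injected for the shaping step to strip.  Planted correlated probe pairs
    (|r| > 0.9 by construction) are recorded in the ground truth.
    """
    if n_probes < 1:
        raise SpecificationError("n_probes must be >= 1")
    if 2 * n_correlated_pairs > n_probes:
        raise SpecificationError(
            "n_correlated_pairs: need at least two probes per planted pair"
        )
    rng = np.random.default_rng(seed)
    ids = _patient_ids(n_patients)
    probes = [f"PROBE{i:05d}_at" for i in range(n_probes)]

    # log2-intensity-like values
    values = rng.normal(8.0, 2.0, size=(n_probes, n_patients))
    truth = GroundTruth()
    for k in range(n_correlated_pairs):
        a, b = 2 * k, 2 * k + 1
        values[b] = values[a] + rng.normal(0.0, 0.5, size=n_patients)
        truth.planted_associations.append((probes[a], probes[b]))

    raw = pd.DataFrame(values, index=probes, columns=ids)
    # metadata row: text, programmatically indistinguishable until typed
    raw.loc["SAMPLE_BARCODE"] = [f"BC{rng.integers(0, 10**8):08d}" for _ in ids]
    # headerless row: numeric junk with an empty name
    raw.loc[""] = rng.standard_normal(n_patients)
    return raw, truth


@dataclass
class ImageStacks:
    """Ordered grayscale slice stacks, one stack per patient.

    ``data`` has shape (n_patients, n_slices, height, width).
    """

    patient_ids: list[str]
    data: np.ndarray

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    def slice_across_patients(self, slice_index: int) -> np.ndarray:
        """All patients' images at one slice index, shape (P, H, W)."""
        return self.data[:, slice_index]


def generate_image_stacks(
    n_patients: int,
    n_slices: int,
    height: int,
    width: int,
    seed: int = 0,
) -> ImageStacks:
    """Generate smooth synthetic image stacks.

    Each patient's stack contains an elliptical blob whose centre and radii
    drift smoothly with the slice index; patients differ in blob geometry,
    so an autoencoder has a learnable, compressible signal.  A small amount
    of pixel noise is added; values lie in [0, ~1.1] and every slice has
    min < max.
    """
    if min(n_patients, n_slices, height, width) < 1:
        raise SpecificationError("all image-stack dimensions must be >= 1")
    rng = np.random.default_rng(seed)
    yy, xx = np.meshgrid(
        np.linspace(0.0, 1.0, height), np.linspace(0.0, 1.0, width), indexing="ij"
    )
    data = np.empty((n_patients, n_slices, height, width), dtype=float)
    for p in range(n_patients):
        cx0, cy0 = rng.uniform(0.35, 0.65, size=2)
        r0 = rng.uniform(0.12, 0.28)
        phase = rng.uniform(0.0, 2 * np.pi)
        for s in range(n_slices):
            t = s / max(n_slices - 1, 1)
            cx = cx0 + 0.08 * np.sin(2 * np.pi * t + phase)
            cy = cy0 + 0.08 * np.cos(2 * np.pi * t + phase)
            r = r0 * (0.8 + 0.4 * t)
            blob = np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (r**2)))
            noise = 0.03 * rng.random((height, width))
            data[p, s] = blob + noise
    return ImageStacks(patient_ids=_patient_ids(n_patients), data=data)


# ---------------------------------------------------------------------------
# on-disk layout (all plain text)
# ---------------------------------------------------------------------------


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a table as CSV with empty fields as the unknown marker."""
    table.to_csv(path, index=False, na_rep="")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(truth.to_json())


def read_ground_truth(path: str | Path) -> GroundTruth:
    return GroundTruth.from_json(Path(path).read_text())


def write_stacks(stacks: ImageStacks, out_dir: str | Path) -> None:
    """Directory-per-patient layout; one text file per slice."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, pid in enumerate(stacks.patient_ids):
        pdir = out / pid
        pdir.mkdir(exist_ok=True)
        for s in range(stacks.n_slices):
            np.savetxt(pdir / f"slice{s:03d}.csv", stacks.data[i, s], delimiter=",")


def read_stacks(in_dir: str | Path) -> ImageStacks:
    root = Path(in_dir)
    pids = sorted(p.name for p in root.iterdir() if p.is_dir())
    if not pids:
        raise FileNotFoundError(f"no patient directories under {root}")
    all_data = []
    for pid in pids:
        files = sorted((root / pid).glob("slice*.csv"))
        all_data.append(
            np.stack([np.loadtxt(f, delimiter=",", ndmin=2) for f in files])
        )
    return ImageStacks(patient_ids=pids, data=np.stack(all_data))
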