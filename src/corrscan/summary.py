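"""Redundancy frequency tables, mappings, and representative selection.

Given the retained significant pairs, this module tabulates how often each
feature is significantly correlated with features of each domain (the
per-feature frequency table), summarizes those frequencies per
(feature-domain, correlate-domain) cell, expresses counts as a percentage
of a domain, builds the feature -> correlates mapping restricted to
chosen domains, and reduces a mapping to a small set of representative
features via a greedy cover.

Summary statistics use the population (not sample) standard deviation;
percentages are rounded half-away-from-zero to 3 decimal places and
summary means/SDs to 2, matching conventional reporting precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .engine import SignificantPairStore

__all__ = [
    "DOMAINS",
    "count_frequencies",
    "percent_of_domain",
    "summarize",
    "build_mapping",
    "write_mapping",
    "select_representatives",
]

#: canonical domain order used in frequency tables
DOMAINS = ("clinical", "expression", "image")


def _freq_col(domain: str) -> str:
    return f"{domain}_freq"


def count_frequencies(
    store: SignificantPairStore,
    domain_of: Mapping[str, str],
    all_features: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-feature counts of significant correlates, split by partner domain.

    Every stored pair increments both endpoints' counters, each in the
    *partner's* domain column ("handshake" accounting).  Features with no
    significant pairs get all-zero rows when listed in ``all_features``.
    The total column is the row sum by construction.
    """
    features = sorted(all_features) if all_features is not None else store.features()
    counts = {f: {d: 0 for d in DOMAINS} for f in features}
    for r in store.pairs:
        for feat, partner in ((r.feature_a, r.feature_b), (r.feature_b, r.feature_a)):
            if feat not in counts:
                raise KeyError(f"stored feature {feat!r} not in the feature list")
            pdom = domain_of.get(partner)
            if pdom is None:
                raise KeyError(f"feature {partner!r} has no domain label")
            if pdom not in DOMAINS:
                raise KeyError(f"unknown domain {pdom!r} for feature {partner!r}")
            counts[feat][pdom] += 1
    for f in features:
        if f not in domain_of:
            raise KeyError(f"feature {f!r} has no domain label")
    rows = []
    for f in features:
        row = {"feature": f, "domain": domain_of[f]}
        row.update({_freq_col(d): counts[f][d] for d in DOMAINS})
        row["total_freq"] = sum(counts[f].values())
        rows.append(row)
    cols = ["feature", "domain"] + [_freq_col(d) for d in DOMAINS] + ["total_freq"]
    return pd.DataFrame(rows, columns=cols)


def _round_half_up(value: Decimal, places: int) -> float:
    q = Decimal(1).scaleb(-places)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))


def percent_of_domain(count: int, domain_size: int) -> float:
    """100 * count / domain_size, rounded half-away-from-zero to 3 decimals."""
    if domain_size < 1:
        raise ValueError("domain_size must be >= 1")
    if not 0 <= count <= domain_size:
        raise ValueError("count must lie in [0, domain_size]")
    return _round_half_up(Decimal(count) * 100 / Decimal(domain_size), 3)


def summarize(records: pd.DataFrame, round_to: int | None = 2) -> pd.DataFrame:
    """Per (feature-domain, correlate-domain) summary of frequency counts.

    For each feature domain and each correlate column (the three domains
    plus the total), reports the mean, population standard deviation,
    minimum and maximum of the per-feature counts.  ``round_to=None``
    disables rounding (used by the brute-force cross-checks).
    """
    if records.empty:
        raise ValueError("no frequency records to summarize")
    rows = []
    value_cols = [_freq_col(d) for d in DOMAINS] + ["total_freq"]
    labels = list(DOMAINS) + ["total"]
    for fdom, grp in records.groupby("domain", sort=True):
        for col, label in zip(value_cols, labels):
            vals = grp[col].to_numpy(dtype=float)
            mean = float(np.mean(vals))
            sd = float(np.std(vals))  # population SD
            if round_to is not None:
                mean = _round_half_up(Decimal(repr(mean)), round_to)
                sd = _round_half_up(Decimal(repr(sd)), round_to)
            rows.append(
                {
                    "feature_domain": fdom,
                    "correlate_domain": label,
                    "average": mean,
                    "std_dev": sd,
                    "minimum": int(vals.min()),
                    "maximum": int(vals.max()),
                }
            )
    return pd.DataFrame(rows)


def build_mapping(
    store: SignificantPairStore,
    include_domains: set[str],
    domain_of: Mapping[str, str],
) -> dict[str, list[str]]:
    """Feature -> sorted significant correlates, restricted to some domains.

    Both the mapped features and the listed correlates must belong to
    ``include_domains``; pairs touching excluded domains (e.g. the image
    domain, whose autoencoder features carry no direct biological meaning)
    are left out entirely.  The mapping is symmetric by construction.
    """
    mapping: dict[str, set[str]] = {}
    for r in store.pairs:
        da = domain_of.get(r.feature_a)
        db = domain_of.get(r.feature_b)
        if da in include_domains and db in include_domains:
            mapping.setdefault(r.feature_a, set()).add(r.feature_b)
            mapping.setdefault(r.feature_b, set()).add(r.feature_a)
    return {f: sorted(c) for f, c in sorted(mapping.items())}


def write_mapping(mapping: dict[str, list[str]], path: str | Path) -> None:
    Path(path).write_text(json.dumps(mapping, indent=2, sort_keys=True))


def select_representatives(
    mapping: Mapping[str, list[str]],
) -> tuple[list[str], dict[str, list[str]]]:
    """Greedy cover: pick features so every mapped feature is kept or replaced.

    Repeatedly selects the feature covering the most not-yet-covered
    features (itself plus its correlates), ties broken lexicographically,
    until everything is covered.  Returns the kept features (sorted) and a
    kept -> replaced map.  Isolated features cover only themselves and are
    always kept.
    """
    universe = set(mapping)
    for correlates in mapping.values():
        universe.update(correlates)
    uncovered = set(universe)
    kept: list[str] = []
    replaced: dict[str, list[str]] = {}
    neighbors = {f: set(mapping.get(f, ())) for f in universe}
    while uncovered:
        best = min(
            universe,
            key=lambda f: (-len((neighbors[f] | {f}) & uncovered), f),
        )
        gain = (neighbors[best] | {best}) & uncovered
        kept.append(best)
        replaced[best] = sorted(gain - {best})
        uncovered -= gain
    kept.sort()
    return kept, {k: replaced[k] for k in kept}
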