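"""Shared paths and loaders for the numbered analysis scripts."""

from pathlib import Path

import pandas as pd

from corrscan.preprocess import NUMERIC, DomainTable, infer_kinds

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "analysis"

SEED = 1  # study seed; every script derives its sub-seeds from it


def out_path(name: str) -> Path:
    OUT.mkdir(parents=True, exist_ok=True)
    return OUT / name


def load_clinical() -> DomainTable:
    df = pd.read_csv(out_path("clinical.csv"), index_col=0)
    kinds, _ = infer_kinds(df)
    return DomainTable(df[list(kinds)], kinds, "clinical")


def load_numeric_table(name: str, domain: str) -> DomainTable:
    df = pd.read_csv(out_path(name), index_col=0)
    return DomainTable(df, {c: NUMERIC for c in df.columns}, domain)
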