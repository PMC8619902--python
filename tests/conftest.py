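import numpy as np
import pandas as pd
import pytest

from corrscan.preprocess import NOMINAL, NUMERIC, DomainTable, MergedDataset, infer_kinds

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


def make_dataset(
    columns: dict[str, tuple[np.ndarray, str]],
    domain_of: dict[str, str] | None = None,
) -> MergedDataset:
    """Build a MergedDataset directly from (values, kind) column specs."""
    n = len(next(iter(columns.values()))[0])
    ids = [f"P{i:04d}" for i in range(n)]
    data = pd.DataFrame(
        {name: vals for name, (vals, _) in columns.items()},
        index=pd.Index(ids, name="PATIENT"),
    )
    kinds = {name: kind for name, (_, kind) in columns.items()}
    domains = domain_of or {name: "clinical" for name in columns}
    counts: dict[str, int] = {}
    for d in domains.values():
        counts[d] = counts.get(d, 0) + 1
    return MergedDataset(data=data, kinds=kinds, domains=domains, counts=counts)


def dataset_from_frame(df: pd.DataFrame, id_col: str = "RID", domain: str = "clinical"):
    """Type a generated cross-sectional table and wrap it as a dataset."""
    work = df.set_index(id_col) if id_col in df.columns else df
    kinds, _ = infer_kinds(work)
    data = work[list(kinds)]
    return MergedDataset(
        data=data,
        kinds=kinds,
        domains={c: domain for c in kinds},
        counts={domain: len(kinds)},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
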