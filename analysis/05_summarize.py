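"""Summarize feature redundancy.

Builds the per-feature correlate-frequency table split by partner domain,
the per-domain summary statistics, the non-image feature -> correlates
mapping, and a greedy representative reduction of that mapping.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import out_path

from corrscan.engine import SignificantPairStore, n_pairwise
from corrscan.summary import (
    build_mapping,
    count_frequencies,
    percent_of_domain,
    select_representatives,
    summarize,
    write_mapping,
)

domains = pd.read_csv(out_path("domains.csv"))
domain_of = dict(zip(domains["feature"], domains["domain"]))
alpha = 0.05 / n_pairwise(len(domain_of))
store = SignificantPairStore.from_csv(out_path("pairs.csv"), alpha=alpha)

freq = count_frequencies(store, domain_of, domain_of.keys())
freq.to_csv(out_path("frequencies.csv"), index=False)
summarize(freq).to_csv(out_path("frequency_summary.csv"), index=False)

mapping = build_mapping(store, {"clinical", "expression"}, domain_of)
write_mapping(mapping, out_path("mapping.json"))
kept, replaced = select_representatives(mapping)
write_mapping(replaced, out_path("representatives.json"))

n_correlated = int((freq["total_freq"] > 0).sum())
print(f"features with >= 1 significant correlate: {n_correlated} "
      f"({percent_of_domain(n_correlated, len(domain_of))}% of {len(domain_of)})")
top = freq.sort_values("total_freq", ascending=False).head(5)
print("most redundant features:")
print(top[["feature", "domain", "total_freq"]].to_string(index=False))
print(f"non-image mapping: {len(mapping)} features -> "
      f"{len(kept)} greedy representatives")
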