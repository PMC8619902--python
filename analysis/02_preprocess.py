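"""Clean and type the tabular domains.

Collapses the longitudinal clinical table to one row per patient (latest
known value per feature), uppercases headers, types every column numeric
or nominal, drops identifier-like / constant / under-observed features
with a logged reason each, imputes the survivors, and reshapes the
expression matrix (transpose, strip metadata and headerless columns).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import SEED, out_path

from corrscan.pipeline import build_clinical_domain
from corrscan.preprocess import shape_expression

raw = pd.read_csv(out_path("raw_clinical.csv"))
clinical, drop_log = build_clinical_domain(raw, seed=SEED + 3)
clinical.data.to_csv(out_path("clinical.csv"), na_rep="")
drop_log.to_csv(out_path("drop_log.csv"), index=False)

raw_expr = pd.read_csv(out_path("raw_expression.csv"), index_col=0)
expression = shape_expression(raw_expr)
expression.data.to_csv(out_path("expression.csv"))

n_nom = sum(k == "nominal" for k in clinical.kinds.values())
print(f"clinical domain: {clinical.n_features} features "
      f"({n_nom} nominal) for {len(clinical.data)} patients")
print("dropped features by reason:")
print(drop_log["reason"].value_counts().to_string())
print(f"expression domain: {expression.n_features} probes "
      f"for {len(expression.data)} patients")
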