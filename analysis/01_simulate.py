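"""Generate the synthetic study inputs.

Fabricates a visit-level clinical-style table (with a planted 4-feature
correlation block at rho = 0.95, a nominal/numeric association, a
duplicate column pair, identifier-like metadata, missingness including one
feature beyond the 80%-known threshold, and sex / dementia-rating
stratification columns), an expression-style features-as-rows matrix with
two planted probe pairs, and 16x16 image stacks of 4 slices per patient.
Ground truth of everything planted is written alongside.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import SEED, out_path

from corrscan import synthetic

N_PATIENTS = 400

spec = synthetic.SyntheticSpec(
    n_patients=N_PATIENTS,
    numeric_blocks=[(4, 0.95)],
    n_noise_numeric=8,
    nominal_specs=[
        synthetic.NominalSpec(3),
        synthetic.NominalSpec(2, associated=True),
    ],
    missing_fraction_per_feature=[0.10, 0.10, 0.85],
    n_metadata_columns=2,
    n_duplicate_pairs=1,
    longitudinal=True,
    sex_column=True,
    dementia_column=True,
    seed=SEED,
)

table, truth = synthetic.generate_tabular_domain(spec)
expr, expr_truth = synthetic.generate_expression_domain(
    n_probes=24, n_patients=N_PATIENTS, n_correlated_pairs=2, seed=SEED + 1
)
stacks = synthetic.generate_image_stacks(
    N_PATIENTS, n_slices=4, height=16, width=16, seed=SEED + 2
)
truth.planted_associations.extend(expr_truth.planted_associations)

synthetic.write_table(table, out_path("raw_clinical.csv"))
expr.to_csv(out_path("raw_expression.csv"))
synthetic.write_stacks(stacks, out_path("stacks"))
synthetic.write_ground_truth(truth, out_path("ground_truth.json"))

print(f"clinical visit-level table: {table.shape[0]} rows x {table.shape[1]} cols")
print(f"expression raw matrix: {expr.shape[0]} rows (probes+junk) x {expr.shape[1]} patients")
print(f"image stacks: {stacks.data.shape}")
print(f"planted associations: {len(truth.planted_associations)} "
      f"({len(truth.duplicate_pairs)} duplicate pair(s))")
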