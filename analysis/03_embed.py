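"""Tabularize the image stacks.

Min-max normalizes every slice, trains one convolutional autoencoder per
slice index (16x16 -> latent 16, MSE loss, Adam), and concatenates the
per-slice latent vectors into the image domain's feature matrix.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import SEED, out_path

from corrscan.pipeline import embed_stacks
from corrscan.synthetic import read_stacks

stacks = read_stacks(out_path("stacks"))
latent = embed_stacks(stacks, latent_dim=16, epochs=3, seed=SEED + 4)
latent.to_csv(out_path("latent.csv"))

print(f"trained {stacks.n_slices} per-slice autoencoders on "
      f"{len(stacks.patient_ids)} patients")
print(f"image domain: {latent.data.shape[1]} latent features "
      f"({stacks.n_slices} slices x {latent.latent_dim})")
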