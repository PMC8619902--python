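"""End-to-end driver: generate -> preprocess -> embed -> scan -> summarize.

One function runs the whole desk-scale study on synthetic data and writes
every artefact as deterministic plain text, so two runs with the same seed
(and any worker count) produce byte-identical outputs.  The numbered
scripts under ``analysis/`` are thin narrative wrappers over the same
steps; tests and the acceptance script import this module directly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import embedding, engine, preprocess, summary, synthetic

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Desk-scale study conditions for the synthetic end-to-end run."""

    n_patients: int = 120
    numeric_blocks: list[tuple[int, float]] = field(
        default_factory=lambda: [(4, 0.95)]
    )
    n_noise_numeric: int = 8
    nominal_specs: list[synthetic.NominalSpec] = field(
        default_factory=lambda: [
            synthetic.NominalSpec(3),
            synthetic.NominalSpec(2, associated=True),
        ]
    )
    missing_fractions: list[float] = field(
        default_factory=lambda: [0.10, 0.10, 0.85]
    )
    n_metadata_columns: int = 2
    n_duplicate_pairs: int = 1
    longitudinal: bool = True
    n_probes: int = 24
    n_correlated_probe_pairs: int = 2
    n_slices: int = 4
    image_size: int = 16
    latent_dim: int = 16
    epochs: int = 3
    base_alpha: float = 0.05


@dataclass
class PipelineResult:
    out_dir: Path
    files: list[Path]
    store: engine.SignificantPairStore
    dataset: preprocess.MergedDataset
    truth: synthetic.GroundTruth

    def file_hashes(self) -> dict[str, str]:
        return {
            str(f.relative_to(self.out_dir)): hashlib.sha256(
                f.read_bytes()
            ).hexdigest()
            for f in sorted(self.files)
        }


def build_clinical_domain(
    raw: pd.DataFrame, seed: int
) -> tuple[preprocess.DomainTable, pd.DataFrame]:
    """Collapse, type, filter and impute a raw clinical-style table."""
    merged, _ = preprocess.merge_tables([raw])
    kinds, dropped = preprocess.infer_kinds(merged)
    typed = preprocess.DomainTable(
        data=merged[list(kinds)], kinds=kinds, domain="clinical"
    )
    filtered, drop_log = preprocess.filter_features(typed)
    type_log = pd.DataFrame(
        {"feature": dropped, "reason": "identifier_like"}
    )
    drop_log = pd.concat([type_log, drop_log], ignore_index=True)
    imputed = preprocess.impute(filtered, seed=seed)
    return imputed, drop_log


def embed_stacks(
    stacks: synthetic.ImageStacks,
    latent_dim: int,
    epochs: int,
    seed: int,
) -> embedding.LatentMatrix:
    """Train one autoencoder per slice index and concatenate the latents."""
    _, _, h, w = stacks.data.shape
    encoders = []
    for s in range(stacks.n_slices):
        spec = embedding.AutoencoderSpec(
            input_height=h,
            input_width=w,
            latent_dim=latent_dim,
            epochs=epochs,
            seed=seed + 100 + s,
        )
        imgs = np.stack(
            [embedding.minmax_normalize(im) for im in stacks.slice_across_patients(s)]
        )
        encoders.append(embedding.train_slice_autoencoder(imgs, spec))
    return embedding.encode_domain(stacks, encoders)


def run_pipeline(
    out_dir: str | Path,
    seed: int,
    n_workers: int = 1,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    cfg = config or PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def save_df(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, index=index, na_rep="")
        files.append(path)

    # 1. generate the three domains
    spec = synthetic.SyntheticSpec(
        n_patients=cfg.n_patients,
        numeric_blocks=cfg.numeric_blocks,
        n_noise_numeric=cfg.n_noise_numeric,
        nominal_specs=cfg.nominal_specs,
        missing_fraction_per_feature=cfg.missing_fractions,
        n_metadata_columns=cfg.n_metadata_columns,
        n_duplicate_pairs=cfg.n_duplicate_pairs,
        longitudinal=cfg.longitudinal,
        sex_column=True,
        dementia_column=True,
        seed=seed,
    )
    raw_clinical, truth = synthetic.generate_tabular_domain(spec)
    raw_expression, expr_truth = synthetic.generate_expression_domain(
        cfg.n_probes, cfg.n_patients, cfg.n_correlated_probe_pairs, seed=seed + 1
    )
    stacks = synthetic.generate_image_stacks(
        cfg.n_patients, cfg.n_slices, cfg.image_size, cfg.image_size, seed=seed + 2
    )
    truth.planted_associations.extend(expr_truth.planted_associations)
    save_df(raw_clinical, "raw_clinical.csv")
    save_df(raw_expression, "raw_expression.csv", index=True)
    gt_path = out / "ground_truth.json"
    synthetic.write_ground_truth(truth, gt_path)
    files.append(gt_path)

    # 2. preprocess the tabular domains
    clinical, drop_log = build_clinical_domain(raw_clinical, seed=seed + 3)
    save_df(drop_log, "drop_log.csv")
    save_df(clinical.data, "clinical.csv", index=True)
    expression = preprocess.shape_expression(raw_expression)
    save_df(expression.data, "expression.csv", index=True)

    # 3. embed the image stacks
    latent = embed_stacks(stacks, cfg.latent_dim, cfg.epochs, seed=seed + 4)
    save_df(latent.to_domain_table().data, "latent.csv", index=True)

    # 4. assemble and scan
    dataset = preprocess.assemble(clinical, expression, latent)
    store = engine.scan_all(dataset, base_alpha=cfg.base_alpha, n_workers=n_workers)
    store_path = out / "pairs.csv"
    store.to_csv(store_path)
    files.append(store_path)

    # 5. summarize redundancy
    freq = summary.count_frequencies(store, dataset.domains, dataset.feature_names)
    save_df(freq, "frequencies.csv")
    save_df(summary.summarize(freq), "frequency_summary.csv")
    mapping = summary.build_mapping(
        store, {"clinical", "expression"}, dataset.domains
    )
    map_path = out / "mapping.json"
    summary.write_mapping(mapping, map_path)
    files.append(map_path)
    kept, replaced = summary.select_representatives(mapping)
    rep_path = out / "representatives.json"
    summary.write_mapping({k: replaced[k] for k in kept}, rep_path)
    files.append(rep_path)

    return PipelineResult(
        out_dir=out, files=files, store=store, dataset=dataset, truth=truth
    )
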