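"""End-to-end orchestration: simulate -> preprocess -> correct -> associate -> enrich.

Each enabled stage writes its artifacts eagerly (CSV/JSON under the output
directory) so any stage can be re-run from disk, and a manifest records the
seed, configuration, library versions and artifact checksums; together they
fully determine every numeric output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from metabomwas import io
from metabomwas.batchcorrect import combat_correct, variance_partition
from metabomwas.containers import AbundanceMatrix
from metabomwas.enrich import class_enrichment, compose_class_profile
from metabomwas.assoc import mwas_interaction_screen, within_group_associations
from metabomwas.preprocess import PreprocessConfig, harmonize_cohort, preprocess_pipeline
from metabomwas.synth import SynthConfig, generate_cohort

logger = logging.getLogger("metabomwas")


@dataclass
class PipelineConfig:
    out_dir: str = "metabomwas_run"
    seed: int = 0
    simulate: bool = True
    abundance_path: str | None = None  # used when simulate is False
    metadata_path: str | None = None
    annotation_path: str | None = None
    correct: bool = True
    outcomes: tuple[str, ...] = ("braak", "cerad", "reagan", "diagnosis")
    hit_q: float = 0.1
    enrichment_class_col: str = "sub_pathway"
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)

    def __post_init__(self) -> None:
        if not 0 < self.hit_q < 1:
            raise ValueError("hit_q must be in (0, 1)")
        if not self.simulate:
            for p in (self.abundance_path, self.metadata_path, self.annotation_path):
                if p is None or not Path(p).exists():
                    raise ValueError(f"non-synthetic runs need existing input paths (missing {p!r})")

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        synth = SynthConfig(**raw.pop("synth", {}))
        pre = PreprocessConfig(**raw.pop("preprocess", {}))
        if "outcomes" in raw:
            raw["outcomes"] = tuple(raw["outcomes"])
        cfg = cls(**raw, synth=synth, preprocess=pre)
        if "seed" in dataclasses.asdict(cfg) and cfg.simulate:
            cfg.synth.seed = cfg.seed
        return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order; return the summary report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    def save(name: str, writer, *args) -> None:
        path = out / name
        writer(*args, path)
        artifacts[name] = path

    # --- stage 1: inputs -------------------------------------------------
    if config.simulate:
        config.synth.seed = config.seed
        matrix, metadata, annotation, truth = generate_cohort(config.synth)
        save("abundance_raw.csv", io.write_abundance, matrix)
        save("metadata.csv", io.write_metadata, metadata)
        save("annotation.csv", io.write_annotation, annotation)
        truth.to_json(out / "truth.json")
        artifacts["truth.json"] = out / "truth.json"
    else:
        matrix = io.read_abundance(config.abundance_path)
        metadata = io.read_metadata(config.metadata_path)
        annotation = io.read_annotation(config.annotation_path)
    logger.info("inputs: %d samples x %d metabolites", matrix.n_samples, matrix.n_metabolites)

    # --- stage 2: cohort harmonization + preprocessing -------------------
    metadata, exclusion_log = harmonize_cohort(
        metadata, config.preprocess.region_keep, config.preprocess.min_group_size
    )
    save("exclusion_log.csv", lambda df, p: df.to_csv(p), exclusion_log)
    matrix = matrix.subset(samples=metadata.index)
    matrix, qc_report = preprocess_pipeline(matrix, config.preprocess)
    metadata = metadata.loc[matrix.sample_ids]
    save("qc_report.json", io.write_json, qc_report)
    save("abundance_preprocessed.csv", io.write_abundance, matrix)

    # --- stage 3: batch correction ---------------------------------------
    vp_pre = variance_partition(matrix, metadata)
    save("variance_partition_pre.csv", lambda df, p: df.to_csv(p), vp_pre)
    if config.correct:
        matrix, model = combat_correct(matrix, metadata)
        model.to_json(out / "combat_model.json")
        artifacts["combat_model.json"] = out / "combat_model.json"
        save("abundance_corrected.csv", io.write_abundance, matrix)
    vp_post = variance_partition(matrix, metadata)
    save("variance_partition_post.csv", lambda df, p: df.to_csv(p), vp_post)

    # --- stage 4: association screens ------------------------------------
    summary: dict = {
        "seed": config.seed,
        "n_samples": matrix.n_samples,
        "n_metabolites": matrix.n_metabolites,
        "site_variance_pre": float(vp_pre["site"].mean()),
        "site_variance_post": float(vp_post["site"].mean()),
        "hits": {},
    }
    profile = compose_class_profile(annotation, matrix.metabolite_ids)
    save("class_profile.csv", lambda df, p: df.to_csv(p), profile)

    for outcome in config.outcomes:
        try:
            table = mwas_interaction_screen(matrix, metadata, outcome, hit_q=config.hit_q)
        except ValueError as exc:
            raise RuntimeError(f"stage associate[{outcome}] failed: {exc}") from exc
        save(f"assoc_{outcome}.csv", lambda df, p: df.to_csv(p), table)
        hits = table.index[table["hit"]].tolist()
        summary["hits"][outcome] = len(hits)
        if table.attrs.get("n_nonconverged"):
            logger.warning("%s: %d metabolites excluded (non-convergence)",
                           outcome, table.attrs["n_nonconverged"])
        if hits:
            within = within_group_associations(matrix, metadata, hits, outcome)
            save(f"within_group_{outcome}.csv", lambda df, p: df.to_csv(p, index=False), within)
            enr = class_enrichment(
                hits, matrix.metabolite_ids, annotation, class_col=config.enrichment_class_col
            )
            save(f"enrichment_{outcome}.csv", lambda df, p: df.to_csv(p), enr)
            summary[f"top_enrichment_{outcome}"] = (
                enr.head(3)[["a", "class_size", "p", "q"]].reset_index().to_dict(orient="records")
            )

    # --- stage 5: manifest + summary -------------------------------------
    import metabomwas

    manifest = {
        "package_version": metabomwas.__version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "config": {
            **{k: v for k, v in dataclasses.asdict(config).items() if k not in ("synth", "preprocess")},
            "synth": dataclasses.asdict(config.synth),
            "preprocess": dataclasses.asdict(config.preprocess),
        },
        "checksums": {name: _checksum(path) for name, path in sorted(artifacts.items())},
    }
    io.write_json(manifest, out / "manifest.json")
    io.write_json(summary, out / "summary.json")
    return summary
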