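"""End-to-end orchestration: synthesize or ingest inputs, call TFCRs per
stage, annotate, classify dynamics, score genes and optionally train the
score regressor — all from one config with deterministic seeding.

A single global seed fans out to per-module child seeds by stable hashing
of the module name, so each stage is reproducible on its own.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import annotation, caller, dynamics, genomic_io, ml, regscore, synthetic

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "tfcr_out"
    synth: dict = field(default_factory=dict)
    caller: dict = field(default_factory=dict)
    run_dynamics: bool = True
    run_regscore: bool = True
    run_ml: bool = False
    ml_params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def child_seed(seed: int, module: str) -> int:
    """Stable per-module child seed derived from the global seed."""
    return (seed * 2_654_435_761 + zlib.crc32(module.encode())) % (2**32)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute the configured stages; returns the output manifest."""
    if config.run_ml and not config.run_regscore:
        raise ConfigError("ml stage requires regscore outputs")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}

    def record(stage: str, name: str, path: Path) -> None:
        manifest[name] = {"stage": stage, "file": str(path), "sha256": _checksum(path)}

    synth_cfg = synthetic.SynthConfig(
        seed=child_seed(config.seed, "synthetic_data"), **config.synth
    )
    data = synthetic.make_dataset(synth_cfg)
    genomic_io.write_chrom_sizes(data.assembly, outdir / "genome.chrom.sizes")
    record("synth", "chrom_sizes", outdir / "genome.chrom.sizes")
    genomic_io.write_gene_models(data.genes, outdir / "genes.tsv")
    record("synth", "genes", outdir / "genes.tsv")
    for stage_id, hits, expr in zip(
        data.stage_ids, data.hits_by_stage, data.expression_by_stage
    ):
        genomic_io.write_motif_hits_bed(hits, outdir / f"hits_{stage_id}.bed")
        record("synth", f"hits_{stage_id}", outdir / f"hits_{stage_id}.bed")
        genomic_io.write_expression(expr, outdir / f"expression_{stage_id}.tsv")
        record("synth", f"expression_{stage_id}", outdir / f"expression_{stage_id}.tsv")

    params = caller.CallerParams(**config.caller)
    tfcrs_by_stage = []
    for stage_id, hits in zip(data.stage_ids, data.hits_by_stage):
        merged = caller.merge_family_overlaps(hits)
        tfcrs = caller.call_tfcrs(merged, params)
        if len(tfcrs) >= 10:
            tfcrs = caller.assign_decile_groups(tfcrs)
        tfcrs_by_stage.append(tfcrs)
        path = outdir / f"tfcrs_{stage_id}.bed"
        genomic_io.write_tfcrs_bed(tfcrs, path)
        record("caller", f"tfcrs_{stage_id}", path)

    for stage_id, tfcrs in zip(data.stage_ids, tfcrs_by_stage):
        annos = annotation.annotate(tfcrs, data.genes)
        path = outdir / f"annotation_{stage_id}.tsv"
        with open(path, "w") as handle:
            handle.write(
                "tfcr_index\tcategory\tnearest_gene_id\t"
                "distance_to_promoter\tdistance_to_tss\n"
            )
            for a in annos:
                handle.write(
                    f"{a.tfcr_index}\t{a.category}\t{a.nearest_gene_id}\t"
                    f"{a.distance_to_promoter}\t{a.distance_to_tss}\n"
                )
        record("annotation", f"annotation_{stage_id}", path)

    if config.run_dynamics and len(tfcrs_by_stage) >= 2:
        series = dynamics.StageSeries(stage_ids=data.stage_ids, tfcrs=tfcrs_by_stage)
        table = dynamics.classify_dynamics(series)
        path = outdir / "dynamics.tsv"
        table.to_csv(path, sep="\t", index=False)
        record("dynamics", "dynamics", path)

    gene_tables = []
    if config.run_regscore:
        for stage_id, tfcrs, expr in zip(
            data.stage_ids, tfcrs_by_stage, data.expression_by_stage
        ):
            if len(tfcrs) < 10:
                logger.warning("stage %s: too few TFCRs for scoring", stage_id)
                continue
            table = regscore.build_gene_table(tfcrs, data.genes, expr)
            gene_tables.append((stage_id, table))
            path = outdir / f"gene_table_{stage_id}.tsv"
            table.to_csv(path, sep="\t", index=False)
            record("regscore", f"gene_table_{stage_id}", path)

    if config.run_ml:
        if not gene_tables:
            raise ConfigError("ml stage enabled but no scored gene tables produced")
        ml_seed = child_seed(config.seed, "ml_explain")
        defaults = {"n": 2000, "l_promoter": 200, "l_tfcr": 400}
        defaults.update(config.ml_params)
        samples = synthetic.make_regression_dataset(seed=ml_seed, **defaults)
        X, y = ml.encode_matrix(
            samples, defaults["l_promoter"], defaults["l_tfcr"]
        )
        idx_train, idx_test = ml.split_dataset(list(range(len(y))), seed=ml_seed)
        spec = ml.ModelSpec(
            method="gb_trees",
            hyperparams={"iterations": 100, "depth": 3, "max_features": 64},
            seed=ml_seed,
        )
        model = ml.train_regressor(spec, X[idx_train], y[idx_train])
        report = ml.evaluate(model, X[idx_test], y[idx_test])
        path = outdir / "ml_metrics.json"
        path.write_text(json.dumps(report.__dict__, indent=2, sort_keys=True))
        record("ml", "ml_metrics", path)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
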