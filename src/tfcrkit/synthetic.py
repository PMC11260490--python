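"""Synthetic genomes, gene models, clustered TFBSs, stage dynamics and
complexity-coupled expression.

Construction is tile-based: each chromosome is cut into fixed-width tiles;
a tile hosts either a gene (TSS at the tile center, promoter inside the
tile) or serves as a background slot.  Every TFBS cluster occupies its own
tile, which never gets reused across stages, so clusters from different
stages or positions are guaranteed not to overlap — stage-level
gained/lost fractions are exact by construction.

Expression is coupled to promoter cluster size through a calibrated
Gaussian copula: the mixing weight is bisected so the realized Spearman
correlation matches the requested target on the generated sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata, spearmanr

from .genomic_io import (
    ExpressionTable,
    GeneModel,
    GenomeAssembly,
    GenomicInterval,
    MotifHit,
)

TILE_WIDTH = 8000
TF_FAMILIES = tuple(f"fam{i:02d}" for i in range(20))
HIT_WIDTH = 10


@dataclass
class SynthConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 100
    n_clusters: int = 120
    promoter_cluster_prob: float = 0.5
    cluster_size_dist: tuple[str, float] = ("geometric", 0.35)  # or ("fixed", k)
    background_rate: float = 0.0  # isolated hits per Mb
    n_stages: int = 1
    gain_rate: float = 0.2
    loss_rate: float = 0.2
    zga_stage_index: int | None = None
    zga_gain_rate: float = 0.75
    expr_coupling_rho: float = 0.6
    distance_effect_weight: float = 0.9
    jitter_sd: float = 80.0
    same_family_overlap: bool = False
    make_sequences: bool = True  # skip FASTA synthesis for stats-only runs

    def __post_init__(self) -> None:
        for name in ("promoter_cluster_prob", "gain_rate", "loss_rate",
                     "zga_gain_rate", "expr_coupling_rho"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.chrom_length <= 0 or self.n_chroms <= 0:
            raise ValueError("genome dimensions must be positive")
        if self.n_genes * 4000 > self.n_chroms * self.chrom_length:
            raise ValueError("promoters do not fit in the genome")
        if self.zga_stage_index is not None and not (
            0 <= self.zga_stage_index < self.n_stages
        ):
            raise ValueError("zga_stage_index out of range")


@dataclass
class Cluster:
    """Ground-truth TFBS cluster: a tile, a center and member hits."""

    tile: tuple[str, int]
    center: int
    size: int
    gene_id: str | None  # set when placed in a promoter
    hits: list[MotifHit] = field(default_factory=list)


@dataclass
class SynthDataset:
    config: SynthConfig
    assembly: GenomeAssembly
    genes: list[GeneModel]
    stage_ids: list[str]
    hits_by_stage: list[list[MotifHit]]
    expression_by_stage: list[ExpressionTable]
    clusters_by_stage: list[list[Cluster]]
    sequences: dict[str, str]

    def promoter_cluster_sizes(self, stage: int = 0) -> dict[str, int]:
        sizes = {g.gene_id: 0 for g in self.genes}
        for c in self.clusters_by_stage[stage]:
            if c.gene_id is not None:
                sizes[c.gene_id] += c.size
        return sizes

    def write_fasta(self, path: str | Path, line_width: int = 70) -> None:
        with open(path, "w") as handle:
            for chrom, seq in self.sequences.items():
                handle.write(f">{chrom}\n")
                for i in range(0, len(seq), line_width):
                    handle.write(seq[i : i + line_width] + "\n")


def _draw_cluster_size(rng: np.random.Generator, dist: tuple[str, float]) -> int:
    kind, param = dist
    if kind == "fixed":
        return int(param)
    if kind == "geometric":
        return int(rng.geometric(param))
    raise ValueError(f"unknown cluster size distribution {kind!r}")


def _cluster_hits(
    rng: np.random.Generator,
    chrom: str,
    center: int,
    size: int,
    chrom_length: int,
    jitter_sd: float,
    same_family_overlap: bool,
    motif_serial: int,
) -> list[MotifHit]:
    hits = []
    for j in range(size):
        c = int(round(center + rng.normal(0.0, jitter_sd)))
        c = min(max(c, HIT_WIDTH), chrom_length - HIT_WIDTH)
        family = TF_FAMILIES[0 if same_family_overlap else j % len(TF_FAMILIES)]
        hits.append(
            MotifHit(
                interval=GenomicInterval(
                    chrom, c - HIT_WIDTH // 2, c + HIT_WIDTH // 2, "+"
                ),
                motif_id=f"m{motif_serial + j}",
                tf_family=family,
                score=float(rng.uniform(5, 20)),
                p_value=float(10 ** rng.uniform(-9, -5)),
            )
        )
    return hits


def _couple_expression(
    rng: np.random.Generator, sizes: np.ndarray, rho: float
) -> np.ndarray:
    """Positive expression whose Spearman correlation with ``sizes`` is
    calibrated to ``rho`` (as closely as tie structure permits)."""
    n = sizes.size
    eps = rng.standard_normal(n)
    if np.ptp(sizes) == 0 or rho == 0.0:
        return np.exp(eps)
    scores = norm.ppf(rankdata(sizes, method="average") / (n + 1))
    if rho == 1.0:
        return np.exp(scores)

    def realized(w: float) -> float:
        latent = w * scores + np.sqrt(1.0 - w * w) * eps
        return float(spearmanr(sizes, latent).statistic)

    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if realized(mid) < rho:
            lo = mid
        else:
            hi = mid
    w = 0.5 * (lo + hi)
    return np.exp(w * scores + np.sqrt(1.0 - w * w) * eps)


def make_dataset(config: SynthConfig) -> SynthDataset:
    """Generate a full synthetic dataset; byte-reproducible under seed."""
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    assembly = GenomeAssembly(
        name="synth", chrom_sizes={c: config.chrom_length for c in chroms}
    )

    tiles = [
        (chrom, t)
        for chrom in chroms
        for t in range(config.chrom_length // TILE_WIDTH)
    ]
    rng.shuffle(tiles)
    if config.n_genes > len(tiles):
        raise ValueError("not enough tiles for the requested gene count")
    gene_tiles = tiles[: config.n_genes]
    free_tiles = tiles[config.n_genes :]

    genes: list[GeneModel] = []
    tile_center = {}
    for i, (chrom, t) in enumerate(sorted(gene_tiles)):
        center = t * TILE_WIDTH + TILE_WIDTH // 2
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            iv = GenomicInterval(chrom, center, center + 1500, "+")
        else:
            iv = GenomicInterval(chrom, center - 1500, center, "-")
        gene = GeneModel(
            gene_id=f"g{i:05d}",
            interval=iv,
            chrom_length=config.chrom_length,
        )
        genes.append(gene)
        tile_center[gene.gene_id] = (chrom, t, center)

    motif_serial = 0
    free_cursor = 0
    unclustered_genes = [g.gene_id for g in genes]

    def new_cluster() -> Cluster:
        nonlocal motif_serial, free_cursor
        size = _draw_cluster_size(rng, config.cluster_size_dist)
        use_promoter = (
            rng.random() < config.promoter_cluster_prob and unclustered_genes
        )
        if use_promoter:
            gene_id = unclustered_genes.pop(
                int(rng.integers(0, len(unclustered_genes)))
            )
            chrom, t, center = tile_center[gene_id]
        else:
            if free_cursor >= len(free_tiles):
                raise ValueError("ran out of background tiles for clusters")
            chrom, t = free_tiles[free_cursor]
            free_cursor += 1
            center = t * TILE_WIDTH + TILE_WIDTH // 2
            gene_id = None
        hits = _cluster_hits(
            rng, chrom, center, size, config.chrom_length,
            config.jitter_sd, config.same_family_overlap, motif_serial,
        )
        motif_serial += size
        return Cluster(tile=(chrom, t), center=center, size=size,
                       gene_id=gene_id, hits=hits)

    clusters = [new_cluster() for _ in range(config.n_clusters)]
    clusters_by_stage = [clusters]
    for s in range(1, config.n_stages):
        prev = clusters_by_stage[-1]
        n_prev = len(prev)
        n_lost = int(round(config.loss_rate * n_prev))
        keep_idx = rng.permutation(n_prev)[: n_prev - n_lost]
        kept = [prev[i] for i in sorted(keep_idx)]
        g = (
            config.zga_gain_rate
            if config.zga_stage_index == s
            else config.gain_rate
        )
        n_new = int(round(len(kept) * g / (1.0 - g))) if g < 1.0 else len(kept) or 1
        clusters_by_stage.append(kept + [new_cluster() for _ in range(n_new)])

    hits_by_stage: list[list[MotifHit]] = []
    for stage_clusters in clusters_by_stage:
        hits = [h for c in stage_clusters for h in c.hits]
        n_bg = rng.poisson(
            config.background_rate * assembly.genome_size / 1e6
        )
        for _ in range(int(n_bg)):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            c = int(rng.integers(HIT_WIDTH, config.chrom_length - HIT_WIDTH))
            hits.append(
                MotifHit(
                    interval=GenomicInterval(
                        chrom, c - HIT_WIDTH // 2, c + HIT_WIDTH // 2, "+"
                    ),
                    motif_id=f"bg{motif_serial}",
                    tf_family=TF_FAMILIES[int(rng.integers(0, len(TF_FAMILIES)))],
                    score=float(rng.uniform(5, 20)),
                    p_value=float(10 ** rng.uniform(-9, -5)),
                )
            )
            motif_serial += 1
        hits.sort(key=lambda h: (h.interval.chrom, h.interval.start))
        hits_by_stage.append(hits)

    stage_ids = [f"stage{s}" for s in range(config.n_stages)]
    expression_by_stage = []
    gene_ids = [g.gene_id for g in genes]
    for s, stage_clusters in enumerate(clusters_by_stage):
        sizes = {gid: 0 for gid in gene_ids}
        for c in stage_clusters:
            if c.gene_id is not None:
                sizes[c.gene_id] += c.size
        values = _couple_expression(
            rng,
            np.array([sizes[g] for g in gene_ids], dtype=float),
            config.expr_coupling_rho,
        )
        expression_by_stage.append(
            ExpressionTable(
                stage_id=stage_ids[s],
                values={g: float(v) for g, v in zip(gene_ids, values)},
            )
        )

    letters = np.frombuffer(b"ACGT", dtype="S1")
    sequences = {}
    if config.make_sequences:
        sequences = {
            chrom: letters[rng.integers(0, 4, size=config.chrom_length)]
            .tobytes()
            .decode("ascii")
            for chrom in chroms
        }
    return SynthDataset(
        config=config,
        assembly=assembly,
        genes=genes,
        stage_ids=stage_ids,
        hits_by_stage=hits_by_stage,
        expression_by_stage=expression_by_stage,
        clusters_by_stage=clusters_by_stage,
        sequences=sequences,
    )


def make_zga_series(config: SynthConfig) -> list[list[MotifHit]]:
    """Per-stage hit sets with a gain burst at the configured ZGA stage."""
    if config.zga_stage_index is None:
        raise ValueError("zga_stage_index must be set")
    return make_dataset(config).hits_by_stage


def make_regression_dataset(
    n: int,
    l_promoter: int = 200,
    l_tfcr: int = 400,
    distance_effect_weight: float = 0.9,
    seed: int | np.random.Generator = 0,
    max_distance: int = 10_000,
):
    """Synthetic (promoter seq, TFCR seq, distance, score) samples where the
    score depends on distance with the given weight; sequences are noise.

    Returns a dict of lists: promoter_seq, tfcr_seq, distance, score.
    """
    rng = np.random.default_rng(seed)
    letters = np.frombuffer(b"ACGT", dtype="S1")

    def seqs(length: int) -> list[str]:
        draws = letters[rng.integers(0, 4, size=(n, length))]
        return [row.tobytes().decode("ascii") for row in draws]

    prom = seqs(l_promoter)
    tfcr = seqs(l_tfcr)
    dist = rng.integers(0, max_distance, size=n)
    w = distance_effect_weight
    signal = np.exp(-dist / (max_distance / 4.0))
    noise = rng.uniform(0.0, 1.0, size=n)
    score = np.clip(w * signal + (1.0 - w) * noise, 0.0, 1.0)
    return {
        "promoter_seq": prom,
        "tfcr_seq": tfcr,
        "distance": dist.astype(int).tolist(),
        "score": score.tolist(),
    }
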