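"""Synchronization scoring between promoter-TFCR complexity and expression.

score(a, b) = (a/9) * (b/9) * exp(-|a - b| / 5) over decile groups a
(TFCR complexity) and b (expression), each in 0..9.  The score is 0
exactly when either group is 0 and reaches 1 only at (9, 9).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import hypergeom, spearmanr

from .caller import TFCR
from .genomic_io import ExpressionTable, GeneModel


def regulatory_score(g_tfcr: int, g_expr: int) -> float:
    """Exact score for one (TFCR-group, expression-group) pair."""
    if not (0 <= g_tfcr <= 9) or not (0 <= g_expr <= 9):
        raise ValueError("group numbers must be in 0..9")
    return (g_tfcr / 9.0) * (g_expr / 9.0) * math.exp(-abs(g_tfcr - g_expr) / 5.0)


def score_grid() -> np.ndarray:
    """All 100 scores as a 10x10 array indexed [g_tfcr, g_expr]."""
    a = np.arange(10)[:, None]
    b = np.arange(10)[None, :]
    return (a / 9.0) * (b / 9.0) * np.exp(-np.abs(a - b) / 5.0)


def decile_of(values: Sequence[float], tiebreak: Sequence | None = None) -> np.ndarray:
    """Equal-count decile labels 0..9, ties broken deterministically.

    ``tiebreak`` (e.g. gene ids) orders equal values; otherwise input
    order does.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 10:
        raise ValueError("need at least 10 values for deciles")
    keys = list(zip(values, tiebreak if tiebreak is not None else range(n)))
    order = sorted(range(n), key=lambda i: keys[i])
    bounds = np.linspace(0, n, 11).round().astype(int)
    out = np.empty(n, dtype=int)
    for g in range(10):
        for rank in range(bounds[g], bounds[g + 1]):
            out[order[rank]] = g
    return out


@dataclass(frozen=True)
class GeneRegRecord:
    gene_id: str
    g_tfcr: int | None
    g_expr: int | None
    score: float | None
    tfcr_index: int | None
    distance: int | None


def build_gene_table(
    tfcrs: Sequence[TFCR],
    genes: Sequence[GeneModel],
    expression: ExpressionTable,
) -> pd.DataFrame:
    """Associate each TFCR with the nearest gene promoter and score genes.

    TFCR complexity deciles come from the full TFCR set; expression deciles
    from all expressed genes.  A gene holding several TFCRs keeps the
    max-complexity one; genes with no associated TFCR get a null score and
    are excluded from ranking.
    """
    if not expression.values:
        raise ValueError("empty expression table")
    if len(tfcrs) < 10:
        raise ValueError("need at least 10 TFCRs")
    from .annotation import annotate

    annos = annotate(tfcrs, genes)
    tfcr_groups = decile_of(
        [t.complexity for t in tfcrs],
        tiebreak=[(t.strength, t.interval.chrom, t.interval.start) for t in tfcrs],
    )
    expr_genes = sorted(expression.values)
    expr_groups = dict(
        zip(
            expr_genes,
            decile_of([expression.values[g] for g in expr_genes], tiebreak=expr_genes),
        )
    )
    # best (max-complexity) TFCR per gene
    best: dict[str, tuple[int, int]] = {}  # gene -> (tfcr index, distance)
    for a in annos:
        t = tfcrs[a.tfcr_index]
        cur = best.get(a.nearest_gene_id)
        if cur is None or t.complexity > tfcrs[cur[0]].complexity:
            best[a.nearest_gene_id] = (a.tfcr_index, a.distance_to_promoter)
    rows = []
    for g in genes:
        g_expr = expr_groups.get(g.gene_id)
        hit = best.get(g.gene_id)
        if hit is None or g_expr is None:
            rows.append((g.gene_id, None, g_expr, None, None, None))
            continue
        idx, dist = hit
        g_tfcr = int(tfcr_groups[idx])
        rows.append(
            (g.gene_id, g_tfcr, int(g_expr), regulatory_score(g_tfcr, g_expr), idx, dist)
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "g_tfcr", "g_expr", "score", "tfcr_index", "distance"]
    )


def top_fraction_genes(table: pd.DataFrame, top_frac: float = 0.2) -> list[str]:
    """Gene ids in the strict top floor(frac*n) by score among scored genes."""
    scored = table.dropna(subset=["score"]).sort_values(
        ["score", "gene_id"], ascending=[False, True]
    )
    k = int(len(scored) * top_frac)
    return scored["gene_id"].head(k).tolist()


def species_specific_genes(
    tables: Mapping[str, pd.DataFrame],
    homolog_map: Mapping[str, Mapping[str, str]] | None = None,
    top_frac: float = 0.2,
) -> tuple[dict[str, set[str]], set[str]]:
    """Species-specific and conserved gene sets from per-species score tables.

    ``homolog_map`` maps species -> {gene_id -> homolog-group id}; when
    omitted, gene ids are assumed shared.  Only homolog groups scored in
    every species participate.  A group is specific to a species when it is
    in that species' top fraction and nobody else's; conserved when in all.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 species")

    def to_group(species: str, gene: str) -> str | None:
        if homolog_map is None:
            return gene
        return homolog_map.get(species, {}).get(gene)

    universe: set[str] | None = None
    scored_groups: dict[str, dict[str, float]] = {}
    for species, table in tables.items():
        scored = table.dropna(subset=["score"])
        groups: dict[str, float] = {}
        for gene, score in zip(scored["gene_id"], scored["score"]):
            grp = to_group(species, gene)
            if grp is not None:
                groups[grp] = max(groups.get(grp, -1.0), float(score))
        scored_groups[species] = groups
        universe = set(groups) if universe is None else universe & set(groups)
    if not universe:
        raise ValueError("no homolog groups shared by all species")
    top_sets: dict[str, set[str]] = {}
    for species, groups in scored_groups.items():
        shared = sorted(universe, key=lambda g: (-groups[g], g))
        k = int(len(shared) * top_frac)
        top_sets[species] = set(shared[:k])
    counts: dict[str, int] = {}
    for s in top_sets.values():
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    specific = {
        species: {g for g in top if counts[g] == 1}
        for species, top in top_sets.items()
    }
    conserved = {g for g, c in counts.items() if c == len(tables)}
    return specific, conserved


def cluster_species(score_matrix: pd.DataFrame, method: str = "complete") -> np.ndarray:
    """Hierarchical clustering of species by 1 - Spearman(score vectors).

    ``score_matrix`` is genes x species.  Returns a scipy linkage matrix.
    """
    if score_matrix.shape[1] < 3:
        raise ValueError("need at least 3 species")
    if score_matrix.shape[0] < 10:
        raise ValueError("need at least 10 shared genes")
    values = score_matrix.to_numpy(dtype=float)
    if np.any(np.ptp(values, axis=0) == 0):
        raise ValueError("constant score vector: correlation undefined")
    rho = spearmanr(values).statistic
    rho = np.atleast_2d(rho)
    dist = 1.0 - rho
    np.fill_diagonal(dist, 0.0)
    return linkage(squareform(dist, checks=False), method=method)


def hypergeom_enrich(
    hit_set: set[str], gene_set: set[str], universe: set[str]
) -> float:
    """Upper-tail hypergeometric p-value for the hit/gene-set overlap."""
    if not universe:
        raise ValueError("empty universe")
    if not hit_set <= universe or not gene_set <= universe:
        raise ValueError("sets must be subsets of the universe")
    overlap = len(hit_set & gene_set)
    return float(
        hypergeom.sf(overlap - 1, len(universe), len(gene_set), len(hit_set))
    )
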