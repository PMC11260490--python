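"""Annotation of called TFCRs against gene models.

Categories follow a promoter > exon > intron > intergenic priority on
>= 1 bp overlap, with genes treated as single-exon unless exon structure is
supplied.  Distances between intervals are gap sizes (0 when overlapping).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .caller import TFCR
from .genomic_io import GenomeAssembly, GeneModel, GenomicInterval

CATEGORIES = ("promoter", "exon", "intron", "intergenic")


@dataclass(frozen=True)
class TfcrAnnotation:
    tfcr_index: int
    category: str
    nearest_gene_id: str
    distance_to_promoter: int
    distance_to_tss: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category == "promoter" and self.distance_to_promoter != 0:
            raise ValueError("promoter category implies zero promoter distance")


def _tss_distance(iv: GenomicInterval, tss: int) -> int:
    if iv.start <= tss < iv.end:
        return 0
    return tss - iv.end + 1 if tss >= iv.end else iv.start - tss


def annotate(
    tfcrs: Sequence[TFCR],
    genes: Sequence[GeneModel],
    exons: dict[str, list[GenomicInterval]] | None = None,
) -> list[TfcrAnnotation]:
    """Assign a genomic category and nearest gene to every TFCR.

    ``exons`` optionally maps gene_id -> exon intervals; absent that, each
    gene body counts as one exon.  The nearest gene minimizes the gap
    between the TFCR and the gene's promoter; ties go to the smaller
    gene_id.
    """
    if not genes:
        raise ValueError("no gene models supplied")
    out: list[TfcrAnnotation] = []
    for idx, t in enumerate(tfcrs):
        iv = t.interval
        best: tuple[int, str] | None = None
        in_promoter = False
        in_exon = False
        in_intron = False
        tss_d = None
        for g in genes:
            if g.interval.chrom != iv.chrom:
                continue
            prom = g.promoter
            gap = iv.gap_to(prom)
            key = (gap, g.gene_id)
            if best is None or key < (best[0], best[1]):
                best = key
                tss_d = _tss_distance(iv, g.tss)
            if gap == 0:
                in_promoter = True
            if iv.overlaps(g.interval):
                gene_exons = (exons or {}).get(g.gene_id)
                if gene_exons is None:
                    in_exon = True
                elif any(iv.overlaps(e) for e in gene_exons):
                    in_exon = True
                else:
                    in_intron = True
        if best is None:
            raise ValueError(f"no gene on chromosome {iv.chrom}")
        if in_promoter:
            category = "promoter"
        elif in_exon:
            category = "exon"
        elif in_intron:
            category = "intron"
        else:
            category = "intergenic"
        out.append(
            TfcrAnnotation(
                tfcr_index=idx,
                category=category,
                nearest_gene_id=best[1],
                distance_to_promoter=best[0],
                distance_to_tss=int(tss_d),
            )
        )
    return out


def promoter_fraction(tfcrs: Sequence[TFCR], genes: Sequence[GeneModel]) -> float:
    """Fraction of TFCRs overlapping >= 1 bp with any promoter."""
    if not tfcrs:
        raise ValueError("no TFCRs")
    annos = annotate(tfcrs, genes)
    return sum(a.category == "promoter" for a in annos) / len(tfcrs)


def normalized_distance_mode(
    distances: Sequence[int],
    assembly: GenomeAssembly,
    yeast_size: int | None = None,
) -> float:
    """Mode of the TFCR-to-gene distance density, genome-size normalized.

    The mode is the argmax of a Gaussian KDE (Silverman bandwidth) over the
    distance values, divided by the assembly's genome-size multiple of the
    yeast reference.
    """
    values = np.asarray(distances, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 distances")
    n = (
        assembly.genome_size / yeast_size
        if yeast_size is not None
        else assembly.size_multiple_n
    )
    if np.ptp(values) == 0:
        return float(values[0]) / n
    kde = gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), 4096)
    mode = grid[int(np.argmax(kde(grid)))]
    return float(mode) / n
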