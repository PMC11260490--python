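"""Genome-size-normalized top/bottom TFCR selection and gene association.

Per species, TFCRs are sorted from high to low complexity and the first
and last round(50*N) are the top and bottom sets, where N is the genome
size expressed as a multiple of the yeast genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .caller import TFCR
from .genomic_io import GeneModel

BASE_COUNT = 50


@dataclass(frozen=True)
class TopBottomSelection:
    species: str
    n_multiple: float
    top: tuple[TFCR, ...]
    bottom: tuple[TFCR, ...]


def selection_size(n_multiple: float) -> int:
    """round(50 * N), half away from zero."""
    if n_multiple <= 0:
        raise ValueError("N must be positive")
    return int(math.floor(BASE_COUNT * n_multiple + 0.5))


def select_top_bottom(
    tfcrs: Sequence[TFCR], n_multiple: float, species: str = ""
) -> TopBottomSelection:
    """Select the round(50*N) most and least complex TFCRs.

    Ties are broken by strength then coordinates so selection is
    deterministic.
    """
    k = selection_size(n_multiple)
    if len(tfcrs) < 2 * k:
        raise ValueError(
            f"need at least {2 * k} TFCRs for top+bottom selection, got {len(tfcrs)}"
        )
    ranked = sorted(
        tfcrs,
        key=lambda t: (
            -t.complexity,
            -t.strength,
            t.interval.chrom,
            t.interval.start,
        ),
    )
    return TopBottomSelection(
        species=species,
        n_multiple=n_multiple,
        top=tuple(ranked[:k]),
        bottom=tuple(ranked[-k:]),
    )


def gene_association_fraction(
    selection_part: Sequence[TFCR], genes: Sequence[GeneModel]
) -> float:
    """Fraction of TFCRs overlapping >= 1 bp with any gene promoter."""
    if not genes:
        raise ValueError("no gene models")
    if not selection_part:
        raise ValueError("empty TFCR selection")
    promoters = [g.promoter for g in genes]
    n_assoc = sum(
        any(t.interval.overlaps(p) for p in promoters) for t in selection_part
    )
    return n_assoc / len(selection_part)


def associated_gene_fraction(
    selection_part: Sequence[TFCR], genes: Sequence[GeneModel]
) -> float:
    """Fraction of genes whose promoter overlaps >= 1 TFCR of the part."""
    if not genes:
        raise ValueError("no gene models")
    n_assoc = sum(
        any(t.interval.overlaps(g.promoter) for t in selection_part) for g in genes
    )
    return n_assoc / len(genes)
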