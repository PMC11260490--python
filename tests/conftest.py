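import numpy as np
import pytest

from tfcrkit.caller import TFCR
from tfcrkit.genomic_io import GeneModel, GenomicInterval, MotifHit


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_hit(chrom, center, motif_id="m0", family="famA", width=10):
    return MotifHit(
        interval=GenomicInterval(chrom, center - width // 2, center + width // 2, "+"),
        motif_id=motif_id,
        tf_family=family,
    )


def make_tfcr(chrom, start, end, complexity=1, strength=1.0, summit=None):
    summit = summit if summit is not None else (start + end) // 2
    return TFCR(
        interval=GenomicInterval(chrom, start, end),
        summit=summit,
        strength=strength,
        complexity=complexity,
        contributor_ids=(),
    )


def make_gene(gene_id, chrom, tss, strand="+", length=1000, chrom_length=None):
    if strand == "+":
        iv = GenomicInterval(chrom, tss, tss + length, "+")
    else:
        iv = GenomicInterval(chrom, tss - length, tss, "-")
    return GeneModel(gene_id=gene_id, interval=iv, chrom_length=chrom_length)


@pytest.fixture
def simple_genes():
    # promoters: [8000,12000), [28000,32000), [48000,52000)
    return [
        make_gene("gA", "chr1", 10_000),
        make_gene("gB", "chr1", 30_000),
        make_gene("gC", "chr1", 50_000),
    ]
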