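"""Readers/writers for the flat-file formats used by the pipeline, plus
interval algebra and shuffle-null generation.

All coordinates are 0-based half-open (BED convention) internally.  FIMO
output is 1-based inclusive and is converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

STRANDS = ("+", "-", ".")

# Total length of the sacCer3 nuclear genome; default denominator for the
# genome-size multiple N.
YEAST_GENOME_SIZE = 12_157_105


class FormatError(ValueError):
    """Raised for malformed input files; carries the offending line number."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance in bp between two intervals; 0 when they overlap."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start - other.end + 1, other.start - self.end + 1) - 1


@dataclass(frozen=True)
class GenomeAssembly:
    """A named set of chromosome lengths.

    ``size_multiple_n`` is the genome size expressed as a multiple of the
    reference (yeast) genome size; it scales the top/bottom selection rule.
    """

    name: str
    chrom_sizes: Mapping[str, int]
    reference_size: int = YEAST_GENOME_SIZE

    def __post_init__(self) -> None:
        if not self.chrom_sizes:
            raise ValueError("assembly needs at least one chromosome")
        for chrom, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"non-positive size for {chrom}")
        if self.reference_size <= 0:
            raise ValueError("reference_size must be positive")

    @property
    def genome_size(self) -> int:
        return sum(self.chrom_sizes.values())

    @property
    def size_multiple_n(self) -> float:
        return self.genome_size / self.reference_size

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_sizes


@dataclass(frozen=True)
class MotifHit:
    """One TFBS instance: a genomic interval with motif/TF-family identity."""

    interval: GenomicInterval
    motif_id: str
    tf_family: str
    score: float = 0.0
    p_value: float = 1.0

    @property
    def center(self) -> int:
        return (self.interval.start + self.interval.end) // 2


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: GenomicInterval
    promoter_halfwidth: int = 2000
    chrom_length: int | None = None

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("gene strand must be + or -")

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def promoter(self) -> GenomicInterval:
        """TSS +/- 2 kb window, clipped to the chromosome when its length
        is known."""
        start = max(0, self.tss - self.promoter_halfwidth)
        end = self.tss + self.promoter_halfwidth
        if self.chrom_length is not None:
            end = min(end, self.chrom_length)
        return GenomicInterval(self.interval.chrom, start, end, ".")


@dataclass
class ExpressionTable:
    stage_id: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, value in self.values.items():
            if value < 0:
                raise ValueError(f"negative expression for {gene}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_FIMO_COLUMNS = 10


def _split_nonempty(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_motif_hits(
    path: str | Path,
    format: str = "fimo_tsv",
    p_threshold: float = 1e-5,
) -> list[MotifHit]:
    """Read TFBS hits from FIMO TSV or BED, keeping p <= ``p_threshold``.

    FIMO coordinates (1-based inclusive) are converted to 0-based
    half-open.  The TF family is taken from the ``motif_alt_id`` column of
    FIMO output and from the BED name field's ``motif:family`` form.
    """
    if format not in ("fimo_tsv", "bed"):
        raise ValueError(f"unknown motif-hit format {format!r}")
    hits: list[MotifHit] = []
    for lineno, fields in _split_nonempty(path):
        if format == "fimo_tsv":
            if fields[0] == "motif_id":  # header
                continue
            if len(fields) < 8:
                raise FormatError(f"{path}: line {lineno}: expected >= 8 columns")
            try:
                start = int(fields[3]) - 1
                end = int(fields[4])
                score = float(fields[6])
                p_value = float(fields[7])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            if p_value > p_threshold:
                continue
            hits.append(
                MotifHit(
                    interval=GenomicInterval(fields[2], start, end, fields[5]),
                    motif_id=fields[0],
                    tf_family=fields[1] or fields[0],
                    score=score,
                    p_value=p_value,
                )
            )
        else:
            if len(fields) < 6:
                raise FormatError(f"{path}: line {lineno}: expected BED6")
            try:
                start, end = int(fields[1]), int(fields[2])
                score = float(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            motif_id, _, family = fields[3].partition(":")
            hits.append(
                MotifHit(
                    interval=GenomicInterval(fields[0], start, end, fields[5]),
                    motif_id=motif_id,
                    tf_family=family or motif_id,
                    score=score,
                    p_value=0.0,
                )
            )
    return hits


def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    out = []
    for lineno, fields in _split_nonempty(path):
        if len(fields) < 3:
            raise FormatError(f"{path}: line {lineno}: expected >= 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
        strand = fields[5] if len(fields) >= 6 else "."
        out.append(GenomicInterval(fields[0], start, end, strand))
    return out


def read_gene_models(
    path: str | Path,
    assembly: GenomeAssembly | None = None,
    promoter_halfwidth: int = 2000,
) -> list[GeneModel]:
    """Read a gene-model TSV (gene_id, chrom, start, end, strand)."""
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for lineno, fields in _split_nonempty(path):
        if fields[0] == "gene_id":
            continue
        if len(fields) < 5:
            raise FormatError(f"{path}: line {lineno}: expected 5 columns")
        gene_id, chrom = fields[0], fields[1]
        if gene_id in seen:
            raise FormatError(f"{path}: line {lineno}: duplicate gene id {gene_id}")
        seen.add(gene_id)
        try:
            start, end = int(fields[2]), int(fields[3])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
        chrom_length = assembly.chrom_sizes.get(chrom) if assembly else None
        genes.append(
            GeneModel(
                gene_id=gene_id,
                interval=GenomicInterval(chrom, start, end, fields[4]),
                promoter_halfwidth=promoter_halfwidth,
                chrom_length=chrom_length,
            )
        )
    return genes


def read_expression(path: str | Path, stage_id: str | None = None) -> ExpressionTable:
    values: dict[str, float] = {}
    header_stage = None
    for lineno, fields in _split_nonempty(path):
        if fields[0] == "gene_id":
            header_stage = fields[1] if len(fields) > 1 else None
            continue
        if len(fields) < 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns")
        if fields[0] in values:
            raise FormatError(f"{path}: line {lineno}: duplicate gene id {fields[0]}")
        try:
            values[fields[0]] = float(fields[1])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return ExpressionTable(stage_id=stage_id or header_stage or Path(path).stem, values=values)


def read_chrom_sizes(
    path: str | Path,
    name: str | None = None,
    reference_size: int = YEAST_GENOME_SIZE,
) -> GenomeAssembly:
    sizes: dict[str, int] = {}
    for lineno, fields in _split_nonempty(path):
        if len(fields) < 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns")
        try:
            sizes[fields[0]] = int(fields[1])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return GenomeAssembly(
        name=name or Path(path).stem, chrom_sizes=sizes, reference_size=reference_size
    )


def read_homolog_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (with header) mapping species-A gene -> species-B gene."""
    pairs: dict[str, str] = {}
    first = True
    for lineno, fields in _split_nonempty(path):
        if len(fields) < 2:
            raise FormatError(f"{path}: line {lineno}: expected 2 columns")
        if first:
            first = False
            continue  # header
        pairs[fields[0]] = fields[1]
    return pairs


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_bed_intervals(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as handle:
        for i, iv in enumerate(intervals):
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\tiv{i}\t0\t{iv.strand}\n")


def write_tfcrs_bed(tfcrs: Sequence, path: str | Path) -> None:
    """Write TFCRs as BED6+4 (complexity, summit, decile, exact strength).

    BED score = strength * 1000, rounded; the last column carries the
    full-precision strength so write/read round-trips are lossless.
    """
    with open(path, "w") as handle:
        for i, t in enumerate(tfcrs):
            iv = t.interval
            decile = t.decile_group if t.decile_group is not None else -1
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\ttfcr{i}\t"
                f"{round(t.strength * 1000)}\t.\t{t.complexity}\t{t.summit}\t{decile}\t"
                f"{t.strength!r}\n"
            )


def write_chrom_sizes(assembly: GenomeAssembly, path: str | Path) -> None:
    with open(path, "w") as handle:
        for chrom, size in assembly.chrom_sizes.items():
            handle.write(f"{chrom}\t{size}\n")


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("gene_id\tchrom\tstart\tend\tstrand\n")
        for g in genes:
            iv = g.interval
            handle.write(f"{g.gene_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.strand}\n")


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write(f"gene_id\t{table.stage_id}\n")
        for gene_id, value in table.values.items():
            handle.write(f"{gene_id}\t{value!r}\n")


def write_motif_hits_bed(hits: Sequence[MotifHit], path: str | Path) -> None:
    with open(path, "w") as handle:
        for h in hits:
            iv = h.interval
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{h.motif_id}:{h.tf_family}\t"
                f"{h.score!r}\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# interval algebra
# ---------------------------------------------------------------------------


def intersect_hits_with_peaks(
    hits: Sequence[MotifHit],
    peaks: Sequence[GenomicInterval],
    assembly: GenomeAssembly | None = None,
) -> list[MotifHit]:
    """Keep hits whose interval overlaps >= 1 bp with any peak."""
    if assembly is not None:
        for iv in peaks:
            if iv.chrom not in assembly:
                raise ValueError(f"chromosome {iv.chrom} absent from assembly")
        for h in hits:
            if h.interval.chrom not in assembly:
                raise ValueError(f"chromosome {h.interval.chrom} absent from assembly")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in peaks:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    # merge per chromosome so a sorted scan suffices
    merged: dict[str, np.ndarray] = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        out = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = np.asarray(out)
    kept = []
    for h in hits:
        spans = merged.get(h.interval.chrom)
        if spans is None:
            continue
        idx = np.searchsorted(spans[:, 0], h.interval.end)
        if idx > 0 and spans[idx - 1, 1] > h.interval.start:
            kept.append(h)
    return kept


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals, merged per chromosome."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted((iv.start, iv.end) for iv in by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def shuffle_intervals(
    items: Sequence[GenomicInterval],
    assembly: GenomeAssembly,
    seed: int | np.random.Generator,
    avoid_self_overlap: bool = False,
) -> list[GenomicInterval]:
    """Chromosome- and length-preserving random relocation of intervals.

    Start positions are uniform over the valid range per chromosome.
    ``avoid_self_overlap`` resamples (up to a retry cap) so outputs do not
    overlap each other.
    """
    rng = np.random.default_rng(seed)
    placed: dict[str, list[tuple[int, int]]] = {}
    out: list[GenomicInterval] = []
    for iv in items:
        if iv.chrom not in assembly:
            raise ValueError(f"chromosome {iv.chrom} absent from assembly")
        chrom_len = assembly.chrom_sizes[iv.chrom]
        length = len(iv)
        if length > chrom_len:
            raise ValueError(
                f"interval of length {length} does not fit on {iv.chrom} ({chrom_len} bp)"
            )
        for _ in range(1000):
            start = int(rng.integers(0, chrom_len - length + 1))
            if not avoid_self_overlap:
                break
            clashes = any(
                start < e and s < start + length
                for s, e in placed.get(iv.chrom, ())
            )
            if not clashes:
                break
        else:
            raise RuntimeError("could not place interval without self-overlap")
        placed.setdefault(iv.chrom, []).append((start, start + length))
        out.append(GenomicInterval(iv.chrom, start, start + length, iv.strand))
    return out
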