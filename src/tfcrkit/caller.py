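"""TFCR calling from TFBS centers.

A Gaussian kernel density profile (unnormalized kernel, K(0)=1, bandwidth
300 bp by default) is built over the per-bp grid; every strict local
maximum of the profile is one called cluster.  A TFBS is a contributor of a
peak when its kernel value at the summit is at least the contribution
threshold (0.1 by default, i.e. within ~644 bp of the summit at h=300);
complexity is the contributor count after merging overlapping same-family
hits, and strength is the density at the summit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .genomic_io import GenomicInterval, MotifHit

# kernel truncated at 10 sigma, where exp(-50) ~ 2e-22: the excluded mass is
# below half an ulp of any peak-scale density value, so per-bp profiles are
# bit-identical to an untruncated brute-force sum wherever peaks can occur
_TRUNCATION_SIGMAS = 10.0


@dataclass(frozen=True)
class CallerParams:
    bandwidth_h: float = 300.0
    contribution_threshold: float = 0.1
    grid_step: int = 1

    def __post_init__(self) -> None:
        if self.bandwidth_h <= 0:
            raise ValueError("bandwidth_h must be positive")
        if not (0 < self.contribution_threshold < 1):
            raise ValueError("contribution_threshold must be in (0, 1)")
        if self.grid_step != 1:
            raise ValueError("only grid_step=1 is supported")

    @property
    def contribution_radius(self) -> float:
        """Max |center - summit| at which a hit still contributes."""
        return self.bandwidth_h * math.sqrt(-2.0 * math.log(self.contribution_threshold))


@dataclass(frozen=True)
class TFCR:
    interval: GenomicInterval
    summit: int
    strength: float
    complexity: int
    contributor_ids: tuple[int, ...]
    decile_group: int | None = None

    def __post_init__(self) -> None:
        if self.complexity < 1:
            raise ValueError("complexity must be >= 1")
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit outside interval")


def merge_family_overlaps(hits: Sequence[MotifHit]) -> list[MotifHit]:
    """Combine hits of the same TF family at overlapping positions.

    Overlap is >= 1 shared bp and merging is transitive: a chain of
    pairwise-overlapping same-family hits collapses to one hit spanning
    their union.  Hits of different families are left untouched.
    """
    groups: dict[tuple[str, str], list[MotifHit]] = {}
    for h in hits:
        groups.setdefault((h.interval.chrom, h.tf_family), []).append(h)
    merged: list[MotifHit] = []
    for (_, _), members in groups.items():
        members.sort(key=lambda h: (h.interval.start, h.interval.end))
        cur = members[0]
        for h in members[1:]:
            if h.interval.start < cur.interval.end:  # >=1 bp overlap
                cur = replace(
                    cur,
                    interval=GenomicInterval(
                        cur.interval.chrom,
                        cur.interval.start,
                        max(cur.interval.end, h.interval.end),
                        cur.interval.strand,
                    ),
                    score=max(cur.score, h.score),
                    p_value=min(cur.p_value, h.p_value),
                )
            else:
                merged.append(cur)
                cur = h
        merged.append(cur)
    merged.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.end))
    return merged


def _segments(centers: np.ndarray, pad: int) -> list[tuple[int, int]]:
    """Merged [lo, hi] windows of +/- pad around sorted centers."""
    spans: list[list[int]] = []
    for c in centers:
        lo, hi = int(c) - pad, int(c) + pad
        if spans and lo <= spans[-1][1] + 1:
            spans[-1][1] = max(spans[-1][1], hi)
        else:
            spans.append([lo, hi])
    return [(lo, hi) for lo, hi in spans]


def _profile_on_segment(
    centers: np.ndarray, lo: int, hi: int, h: float
) -> np.ndarray:
    """Density values at integer positions lo..hi (inclusive)."""
    values = np.zeros(hi - lo + 1)
    pad = int(math.ceil(_TRUNCATION_SIGMAS * h))
    inv = 1.0 / (2.0 * h * h)
    for c in centers:
        c = int(c)
        a = max(lo, c - pad)
        b = min(hi, c + pad)
        if a > b:
            continue
        offs = np.arange(a, b + 1) - c
        values[a - lo : b - lo + 1] += np.exp(-(offs.astype(float) ** 2) * inv)
    return values


def density_profile(
    hit_centers: Sequence[int], params: CallerParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate the KDE profile near the given centers (one chromosome).

    Returns (positions, density) restricted to the union of truncation
    windows around the centers; the density is an exact per-bp kernel sum
    there and < 1e-9 everywhere else.
    """
    params = params or CallerParams()
    centers = np.sort(np.asarray(hit_centers, dtype=np.int64))
    if centers.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    pad = int(math.ceil(_TRUNCATION_SIGMAS * params.bandwidth_h))
    pos_parts, val_parts = [], []
    for lo, hi in _segments(centers, pad):
        pos_parts.append(np.arange(lo, hi + 1, dtype=np.int64))
        val_parts.append(_profile_on_segment(centers, lo, hi, params.bandwidth_h))
    return np.concatenate(pos_parts), np.concatenate(val_parts)


def _local_maxima(values: np.ndarray) -> list[int]:
    """Indices of strict local maxima; plateaus collapse to their midpoint."""
    n = values.size
    if n == 0:
        return []
    change = np.flatnonzero(np.diff(values) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [n - 1]])
    run_values = values[starts]
    left_ok = np.empty(starts.size, dtype=bool)
    left_ok[0] = True
    left_ok[1:] = run_values[:-1] < run_values[1:]
    right_ok = np.empty(starts.size, dtype=bool)
    right_ok[-1] = True
    right_ok[:-1] = run_values[1:] < run_values[:-1]
    mids = (starts + ends) // 2
    return mids[left_ok & right_ok].tolist()


def call_tfcrs(
    hits: Sequence[MotifHit], params: CallerParams | None = None
) -> list[TFCR]:
    """Call one TFCR per strict local maximum of the per-chromosome KDE.

    Input hits should already be family-merged (see
    :func:`merge_family_overlaps`).  Contributor sets of adjacent peaks may
    overlap; every contributor's interval is spanned by the TFCR interval.
    """
    params = params or CallerParams()
    by_chrom: dict[str, list[tuple[int, MotifHit]]] = {}
    for idx, h in enumerate(hits):
        by_chrom.setdefault(h.interval.chrom, []).append((idx, h))
    radius = params.contribution_radius
    inv = 1.0 / (2.0 * params.bandwidth_h**2)
    tfcrs: list[TFCR] = []
    for chrom in sorted(by_chrom):
        indexed = sorted(by_chrom[chrom], key=lambda ih: ih[1].center)
        ids = np.array([i for i, _ in indexed])
        centers = np.array([h.center for _, h in indexed], dtype=np.int64)
        positions, values = density_profile(centers, params)
        # segment boundaries show up as jumps in `positions`
        breaks = np.flatnonzero(np.diff(positions) != 1)
        seg_bounds = np.concatenate([[0], breaks + 1, [positions.size]])
        for s, e in zip(seg_bounds[:-1], seg_bounds[1:]):
            for k in _local_maxima(values[s:e]):
                summit = int(positions[s + k])
                strength = float(values[s + k])
                lo = np.searchsorted(centers, summit - radius, side="left")
                hi = np.searchsorted(centers, summit + radius, side="right")
                sel = np.arange(lo, hi)
                contrib = np.exp(-((centers[sel] - summit).astype(float) ** 2) * inv)
                sel = sel[contrib >= params.contribution_threshold]
                if sel.size == 0:
                    continue
                start = min(indexed[i][1].interval.start for i in sel)
                end = max(indexed[i][1].interval.end for i in sel)
                start = min(start, summit)
                end = max(end, summit + 1)
                tfcrs.append(
                    TFCR(
                        interval=GenomicInterval(chrom, start, end),
                        summit=summit,
                        strength=strength,
                        complexity=int(sel.size),
                        contributor_ids=tuple(int(ids[i]) for i in sel),
                    )
                )
    return tfcrs


def assign_decile_groups(tfcrs: Sequence[TFCR]) -> list[TFCR]:
    """Split TFCRs into 10 equal-count complexity groups, 0 (low) to 9 (high).

    Ordering is (complexity, strength, chrom, start) so tie handling is
    deterministic; group sizes differ by at most one.
    """
    n = len(tfcrs)
    if n < 10:
        raise ValueError("need at least 10 TFCRs for decile grouping")
    order = sorted(
        range(n),
        key=lambda i: (
            tfcrs[i].complexity,
            tfcrs[i].strength,
            tfcrs[i].interval.chrom,
            tfcrs[i].interval.start,
        ),
    )
    out: list[TFCR | None] = [None] * n
    bounds = np.linspace(0, n, 11).round().astype(int)
    for group in range(10):
        for rank in range(bounds[group], bounds[group + 1]):
            out[order[rank]] = replace(tfcrs[order[rank]], decile_group=group)
    return out  # type: ignore[return-value]


def overlap_compare(
    set_a: Sequence[TFCR],
    set_b: Sequence[TFCR],
    min_shared_frac: float = 0.5,
) -> float:
    """Fraction of set_a TFCRs sharing more than ``min_shared_frac`` of
    their own bases with the union of set_b."""
    if not set_a:
        raise ValueError("set_a is empty")
    from .genomic_io import merge_intervals

    union: dict[str, list[GenomicInterval]] = {}
    if set_b:
        for iv in merge_intervals([t.interval for t in set_b]):
            union.setdefault(iv.chrom, []).append(iv)
    n_over = 0
    for t in set_a:
        shared = sum(t.interval.overlap_len(iv) for iv in union.get(t.interval.chrom, ()))
        if shared > min_shared_frac * len(t.interval):
            n_over += 1
    return n_over / len(set_a)
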