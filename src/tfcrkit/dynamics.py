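"""Stable/gained/lost classification of TFCRs across developmental stages.

A TFCR at stage t is *gained* when it has no >= 1 bp overlap with any TFCR
of stage t-1, *lost* when it has none with stage t+1, and *stable*
otherwise.  "Dynamic" means gained or lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .caller import TFCR
from .genomic_io import GeneModel


@dataclass
class StageSeries:
    stage_ids: list[str]
    tfcrs: list[list[TFCR]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.stage_ids) != len(self.tfcrs):
            raise ValueError("stage_ids and tfcrs length mismatch")

    @property
    def n_stages(self) -> int:
        return len(self.stage_ids)


def _overlaps_any(t: TFCR, others: Sequence[TFCR]) -> bool:
    return any(t.interval.overlaps(o.interval) for o in others)


def classify_dynamics(series: StageSeries) -> pd.DataFrame:
    """Per-TFCR labels for each stage.

    Returns a frame with columns (stage, tfcr_index, gained, lost, label);
    gained is NA at the first stage and lost at the last.  The summary
    label prioritizes gained > lost > stable.
    """
    if series.n_stages < 2:
        raise ValueError("need at least 2 stages")
    rows = []
    for s, stage in enumerate(series.stage_ids):
        current = series.tfcrs[s]
        prev_set = series.tfcrs[s - 1] if s > 0 else None
        next_set = series.tfcrs[s + 1] if s + 1 < series.n_stages else None
        for i, t in enumerate(current):
            gained = None if prev_set is None else not _overlaps_any(t, prev_set)
            lost = None if next_set is None else not _overlaps_any(t, next_set)
            if gained:
                label = "gained"
            elif lost:
                label = "lost"
            else:
                label = "stable"
            rows.append((stage, i, gained, lost, label))
    return pd.DataFrame(rows, columns=["stage", "tfcr_index", "gained", "lost", "label"])


def gained_fraction(series: StageSeries, stage: int | str) -> float:
    """|gained at stage| / |TFCRs at stage|."""
    s = series.stage_ids.index(stage) if isinstance(stage, str) else stage
    if s == 0:
        raise ValueError("first stage has no predecessor")
    current = series.tfcrs[s]
    if not current:
        raise ValueError("no TFCRs at stage")
    prev_set = series.tfcrs[s - 1]
    n_gained = sum(not _overlaps_any(t, prev_set) for t in current)
    return n_gained / len(current)


def lost_fraction(series: StageSeries, stage: int | str) -> float:
    s = series.stage_ids.index(stage) if isinstance(stage, str) else stage
    if s + 1 >= series.n_stages:
        raise ValueError("last stage has no successor")
    current = series.tfcrs[s]
    if not current:
        raise ValueError("no TFCRs at stage")
    next_set = series.tfcrs[s + 1]
    return sum(not _overlaps_any(t, next_set) for t in current) / len(current)


def permutation_test_promoter_fraction(
    stable_set: Sequence[TFCR],
    dynamic_set: Sequence[TFCR],
    genes: Sequence[GeneModel],
    n_perm: int = 9999,
    seed: int | np.random.Generator = 0,
) -> float:
    """One-sided permutation p-value for promoter-fraction(stable) >
    promoter-fraction(dynamic).

    The null permutes stable/dynamic labels over the pooled TFCRs;
    p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if not stable_set or not dynamic_set:
        raise ValueError("both sets must be non-empty")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    from .annotation import annotate

    pooled = list(stable_set) + list(dynamic_set)
    in_prom = np.array(
        [a.category == "promoter" for a in annotate(pooled, genes)], dtype=float
    )
    n1 = len(stable_set)
    n = len(pooled)
    observed = in_prom[:n1].mean() - in_prom[n1:].mean()
    # vectorized label shuffle: each row is one permutation of the pool
    perm = np.tile(in_prom, (n_perm, 1))
    perm = rng.permuted(perm, axis=1)
    null = perm[:, :n1].mean(axis=1) - perm[:, n1:].mean(axis=1)
    return float((1 + np.sum(null >= observed)) / (n_perm + 1))
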