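"""Inter-read gap statistics and the FUG metric.

For a genome whose reads form a homogeneous Poisson process, the
distances between consecutive read start positions are exponentially
distributed with rate lambda = n / Gl.  FUG (Fraction of Unexpected
Gaps) scores how heavy the observed gap distribution's tail is beyond
the expected spacing Delta = round(Gl / n):

    FUG = (Delta - sum_{d >= Delta} p_d * (d - Delta)) / Delta

where p_d is the fraction of observed distances equal to d.  FUG is an
approximation of the exponential CDF evaluated at Delta, so uniformly
spread reads give FUG ~ 1 - 1/e ~ 0.632, while reads clustered into a
small region leave one or two enormous gaps and drive FUG far down --
even when there are so few reads that BER cannot tell the two cases
apart.

Paired-end mates are split into two groups (first mates, second mates)
that are scored independently, because the insert size couples the two
mates of a fragment and would otherwise distort the gap distribution.
Before scoring, two sentinel reads are added to each group: one at
position 0 and one at Gl - round(mean read length).  Reads confined to
one interior region then still produce large boundary gaps, which is
what lets the metric flag such genomes as absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .alignment import GenomePlacements, MateGroup

__all__ = [
    "DistanceHistogram",
    "GapMetrics",
    "add_sentinels",
    "expected_distance",
    "distance_histogram",
    "fug",
    "genome_gap_metrics",
]


@dataclass(frozen=True)
class DistanceHistogram:
    """Histogram of consecutive-start distances for one mate group."""

    values: np.ndarray  # distinct distances d, ascending
    counts: np.ndarray  # N_d for each d
    n_distances: int  # total distances = positions - 1

    @property
    def p(self) -> np.ndarray:
        """p_d = N_d / n_distances; sums to 1."""
        return self.counts / self.n_distances


@dataclass(frozen=True)
class GapMetrics:
    """Per-mate-group FUG values for one genome.

    ``fug_by_group`` maps each mate group present in the data to its FUG
    value, or ``None`` when the group has too few reads for the statistic
    to be meaningful.  ``fug_mean`` averages the defined groups and is
    ``None`` when no group is defined.
    """

    fug_by_group: Dict[MateGroup, Optional[float]] = field(default_factory=dict)
    delta_by_group: Dict[MateGroup, Optional[int]] = field(default_factory=dict)

    @property
    def defined_values(self) -> list:
        return [v for v in self.fug_by_group.values() if v is not None]

    @property
    def fug_mean(self) -> Optional[float]:
        vals = self.defined_values
        return sum(vals) / len(vals) if vals else None


def add_sentinels(
    positions: np.ndarray | Sequence[int], genome_length: int, mean_read_length: float
) -> np.ndarray:
    """Add the two sentinel positions to one mate group's start array.

    One sentinel at the start of the concatenated genome (position 0) and
    one at its end minus the mean read length.  Duplicates of existing
    positions are kept: zero distances are legal observations.
    """
    tail = genome_length - round(mean_read_length)
    if tail < 0:
        raise ValueError(
            f"genome length {genome_length} shorter than the mean read "
            f"length {mean_read_length}"
        )
    pos = np.asarray(positions, dtype=np.int64)
    return np.sort(np.concatenate(([0], pos, [tail])))


def expected_distance(n_positions: int, genome_length: int) -> int:
    """Delta: nearest integer to Gl / n (banker's rounding on ties).

    ``n_positions`` counts every entry of the mate-group array, sentinels
    included.
    """
    if n_positions < 2:
        raise ValueError("expected distance needs at least two positions")
    return round(genome_length / n_positions)


def distance_histogram(positions: np.ndarray) -> DistanceHistogram:
    """Histogram of successive start-position differences (sorted input)."""
    pos = np.asarray(positions, dtype=np.int64)
    if len(pos) < 2:
        raise ValueError("need at least two positions to form distances")
    dists = np.diff(pos)
    values, counts = np.unique(dists, return_counts=True)
    return DistanceHistogram(values, counts, len(dists))


def fug(positions_with_sentinels: np.ndarray, genome_length: int) -> float:
    """FUG for one mate group's sentinel-augmented, sorted position array.

    Equals 1 exactly when no gap exceeds Delta; can go negative for
    extremely clustered reads (the tail penalty exceeds Delta itself).
    """
    pos = np.asarray(positions_with_sentinels, dtype=np.int64)
    if len(pos) < 2:
        raise ValueError("FUG needs at least two positions")
    delta = expected_distance(len(pos), genome_length)
    dists = np.diff(pos)
    # sum_{d >= Delta} p_d * (d - Delta) == mean over all distances of
    # max(d - Delta, 0), since terms below Delta vanish.
    penalty = np.clip(dists - delta, 0, None).mean()
    return float((delta - penalty) / delta)


def genome_gap_metrics(
    gp: GenomePlacements,
    *,
    min_group_size: int = 2,
) -> GapMetrics:
    """FUG per mate group for one genome.

    Groups with fewer than ``min_group_size`` non-sentinel reads are
    undefined (the formula degenerates); the evidential 80-read detection
    limit is a separate, genome-level rule applied by the caller.
    """
    out = GapMetrics()
    for group, positions in sorted(
        gp.positions_by_group.items(), key=lambda kv: kv[0].value
    ):
        if len(positions) < min_group_size:
            out.fug_by_group[group] = None
            out.delta_by_group[group] = None
            continue
        augmented = add_sentinels(positions, gp.genome_length, gp.mean_read_length)
        out.fug_by_group[group] = fug(augmented, gp.genome_length)
        out.delta_by_group[group] = expected_distance(len(augmented), gp.genome_length)
    return out
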