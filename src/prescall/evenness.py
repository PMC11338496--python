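"""Per-genome depth profile, coverage, breadth, and the BER statistic.

Under random shotgun fragmentation, read start positions on a genome that
is truly in the sample approximate a homogeneous Poisson process, so the
per-base depth is Poisson with mean C (the average coverage).  The
fraction of the genome covered at least once ("breadth") then has a
predictable relationship to C:

    Be = 1 - exp(-0.883 * C)

where the 0.883 factor is an empirical correction to the ideal Poisson
exponent, fitted by Olm and colleagues on resequencing data.  The
Breadth-to-Expected-breadth Ratio,

    BER = Bo / Be,

is close to 1 for genomes whose reads spread genome-wide and drops well
below 1 when reads pile into a restricted region -- the signature of
reads that merely mismap onto a conserved fragment of an absent genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .alignment import GenomePlacements
from .catalog import GenomeCatalog

__all__ = [
    "EXPECTED_BREADTH_EXPONENT",
    "EvennessMetrics",
    "depth_profile",
    "coverage_and_breadth",
    "expected_breadth",
    "ber",
    "genome_evenness",
]

#: Empirical correction to the Poisson exponent in the coverage->breadth
#: curve (Olm et al.); fixed, not a tuning parameter.
EXPECTED_BREADTH_EXPONENT = 0.883


@dataclass(frozen=True)
class EvennessMetrics:
    """Coverage C, observed breadth Bo, expected breadth Be, and BER.

    All fields are ``None`` when the genome has no mapped reads (the
    ratio is undefined at Be = 0).
    """

    coverage: Optional[float]
    breadth: Optional[float]
    expected_breadth: Optional[float]
    ber: Optional[float]

    @property
    def defined(self) -> bool:
        return self.ber is not None


def depth_profile(
    placements_on_contig: Sequence[Tuple[int, int]], contig_length: int
) -> np.ndarray:
    """Per-base depth of one contig from (start, read_length) pairs.

    Built as a difference array: +1 at each read start, -1 at start +
    read_length, then a prefix sum.  Reads overhanging the contig end are
    clamped to it (their -1 lands past the last base), so a read
    contributes exactly ``min(read_length, contig_length - start)`` to
    the total depth.
    """
    if contig_length < 1:
        raise ValueError(f"contig length must be >= 1, got {contig_length}")
    diff = np.zeros(contig_length + 1, dtype=np.int64)
    for start, read_length in placements_on_contig:
        if start < 0 or start >= contig_length:
            raise ValueError(
                f"read start {start} outside contig of length {contig_length}"
            )
        if read_length < 1:
            raise ValueError(f"read length must be >= 1, got {read_length}")
        end = min(start + read_length, contig_length)
        diff[start] += 1
        diff[end] -= 1
    return np.cumsum(diff[:-1])


def coverage_and_breadth(
    depth_profiles: Iterable[np.ndarray], genome_length: int
) -> Tuple[float, float]:
    """Average coverage C and observed breadth Bo over a whole genome.

    C is the mean depth across all positions of all contigs; Bo is one
    minus the fraction of zero-depth positions.  Contigs without any
    mapped read may simply be absent from ``depth_profiles``: the genome
    length in the denominator accounts for them.
    """
    total_depth = 0
    covered = 0
    seen = 0
    for profile in depth_profiles:
        total_depth += int(profile.sum())
        covered += int(np.count_nonzero(profile))
        seen += len(profile)
    if seen > genome_length:
        raise ValueError(
            f"depth profiles span {seen} bp but genome length is {genome_length}"
        )
    return total_depth / genome_length, covered / genome_length


def expected_breadth(coverage: float) -> float:
    """Breadth predicted from coverage: Be = 1 - exp(-0.883 * C)."""
    if coverage < 0:
        raise ValueError(f"coverage must be >= 0, got {coverage}")
    return 1.0 - math.exp(-EXPECTED_BREADTH_EXPONENT * coverage)


def ber(breadth: float, exp_breadth: float) -> float:
    """BER = Bo / Be.  May exceed 1; undefined (error) when Be = 0."""
    if exp_breadth <= 0:
        raise ValueError("BER is undefined when the expected breadth is zero")
    return breadth / exp_breadth


def genome_evenness(
    gp: GenomePlacements, catalog: GenomeCatalog
) -> EvennessMetrics:
    """Compute the full evenness block for one genome.

    A genome with zero mapped reads gets all-``None`` metrics; the
    presence caller reports it absent with reason ``no_reads``.
    """
    if gp.is_empty:
        return EvennessMetrics(None, None, None, None)
    profiles = (
        depth_profile(placements, catalog.contig(contig_id).length)
        for contig_id, placements in gp.placements_by_contig.items()
    )
    c, bo = coverage_and_breadth(profiles, gp.genome_length)
    be = expected_breadth(c)
    return EvennessMetrics(c, bo, be, ber(bo, be))
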