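"""Streaming of read placements from a coordinate-sorted SAM/BAM file.

Only the information the evenness and gap metrics consume is extracted
from each alignment record: the contig, the 0-based leftmost mapping
position, the read length, and which mate group the record belongs to.
Mapping quality, CIGAR details, alignment scores, and multimapper status
are deliberately ignored: the metrics operate on mapping positions alone.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional

import numpy as np
import pysam

from .catalog import GenomeCatalog

logger = logging.getLogger(__name__)

__all__ = [
    "MateGroup",
    "ReadPlacement",
    "GenomePlacements",
    "stream_placements",
    "collect_genome_placements",
    "count_mapped_records",
]


class MateGroup(enum.Enum):
    """Which point process a record contributes to.

    Paired mates are split into two groups so insert-size correlation
    between the mates of one fragment cannot distort the inter-read
    distance distribution within a group.
    """

    FIRST = "first"
    SECOND = "second"
    UNPAIRED = "unpaired"


@dataclass(frozen=True)
class ReadPlacement:
    """One mapped alignment record reduced to its placement.

    ``start`` is the 0-based leftmost mapping coordinate on the contig
    (SAM POS minus one).  ``name`` is carried for simulation round trips
    and pair-aware subsampling; the metrics never read it.
    """

    contig_id: str
    start: int
    read_length: int
    mate_group: MateGroup = MateGroup.UNPAIRED
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start}")
        if self.read_length < 1:
            raise ValueError(f"read length must be >= 1, got {self.read_length}")


@dataclass
class GenomePlacements:
    """All placements of one genome, organised for the two metric families.

    ``positions_by_group`` holds sorted concatenated-coordinate start
    positions per mate group (for the gap statistics);
    ``placements_by_contig`` keeps contig-local (start, read_length)
    pairs (for the depth profile).  ``n_reads`` counts alignment records,
    so both mates of a pair count separately.
    """

    genome_id: str
    genome_length: int
    positions_by_group: Dict[MateGroup, np.ndarray] = field(default_factory=dict)
    placements_by_contig: Dict[str, List[tuple]] = field(default_factory=dict)
    n_reads: int = 0
    mean_read_length: float = 0.0

    @property
    def is_empty(self) -> bool:
        return self.n_reads == 0


def _mate_group(rec: pysam.AlignedSegment) -> MateGroup:
    if rec.is_paired:
        return MateGroup.FIRST if rec.is_read1 else MateGroup.SECOND
    return MateGroup.UNPAIRED


def stream_placements(
    alignment_path: str | Path,
    catalog: GenomeCatalog,
    *,
    strict: bool = False,
    primary_only: bool = False,
    default_read_length: int = 150,
) -> Iterator[ReadPlacement]:
    """Yield one :class:`ReadPlacement` per mapped record.

    The file must be coordinate-sorted (checked from the header and
    verified while streaming).  Records on contigs absent from the
    catalog are skipped with a warning, or are fatal under ``strict``.
    ``primary_only`` drops secondary/supplementary records; by default
    they are kept, since multimapper status does not enter the metrics.
    Records without a stored sequence fall back to ``default_read_length``.
    """
    path = str(alignment_path)
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        so = (af.header.get("HD") or {}).get("SO")
        if so != "coordinate":
            raise ValueError(
                f"{path}: alignment must be coordinate-sorted "
                f"(header sort order: {so!r})"
            )
        warned: set = set()
        last_key = (-1, -1)
        for rec in af:
            if rec.is_unmapped:
                continue
            if primary_only and (rec.is_secondary or rec.is_supplementary):
                continue
            key = (rec.reference_id, rec.reference_start)
            if key < last_key:
                raise ValueError(f"{path}: records are not coordinate-sorted")
            last_key = key
            contig = rec.reference_name
            if contig not in catalog:
                if strict:
                    raise ValueError(
                        f"{path}: contig {contig!r} not present in the genome catalog"
                    )
                if contig not in warned:
                    logger.warning(
                        "contig %r not in catalog; skipping its records", contig
                    )
                    warned.add(contig)
                continue
            rl = rec.query_length or default_read_length
            yield ReadPlacement(
                contig_id=contig,
                start=rec.reference_start,
                read_length=rl,
                mate_group=_mate_group(rec),
                name=rec.query_name,
            )


def collect_genome_placements(
    placements: Iterable[ReadPlacement],
    catalog: GenomeCatalog,
) -> Dict[str, GenomePlacements]:
    """Group placements by genome; every catalog genome gets an entry.

    Start positions are projected onto the genome concatenation
    (contig offset + contig-local start) and sorted per mate group.
    """
    by_genome: Dict[str, GenomePlacements] = {
        g: GenomePlacements(g, catalog.genome_length(g)) for g in catalog.genome_ids
    }
    raw_positions: Dict[str, Dict[MateGroup, List[int]]] = {
        g: {} for g in catalog.genome_ids
    }
    length_sums: Dict[str, int] = {g: 0 for g in catalog.genome_ids}

    for p in placements:
        rec = catalog.contig(p.contig_id)
        gp = by_genome[rec.genome_id]
        concat = rec.offset + p.start
        raw_positions[rec.genome_id].setdefault(p.mate_group, []).append(concat)
        gp.placements_by_contig.setdefault(p.contig_id, []).append(
            (p.start, p.read_length)
        )
        gp.n_reads += 1
        length_sums[rec.genome_id] += p.read_length

    for genome_id, gp in by_genome.items():
        for group, pos in raw_positions[genome_id].items():
            gp.positions_by_group[group] = np.sort(
                np.asarray(pos, dtype=np.int64)
            )
        if gp.n_reads:
            gp.mean_read_length = length_sums[genome_id] / gp.n_reads
    return by_genome


def count_mapped_records(alignment_path: str | Path) -> int:
    """Flag-based count of mapped records, independent of the streamer."""
    path = str(alignment_path)
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as af:
        return sum(1 for rec in af if not rec.is_unmapped)
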