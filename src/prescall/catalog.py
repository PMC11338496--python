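"""Genome catalog: which contigs belong to which genome, and where each
contig sits inside its genome's concatenated coordinate system.

A "genome" here is any set of contigs analysed as one unit -- a complete
reference genome, a MAG, or a draft assembly.  For the gap statistics the
contigs of a genome are arbitrarily joined into one contiguous sequence;
the catalog stores the cumulative offset of each contig in that
concatenation so contig-local positions can be projected onto it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from Bio import SeqIO

__all__ = ["ContigRecord", "GenomeCatalog", "load_genome_catalog"]


@dataclass(frozen=True)
class ContigRecord:
    """One contig: its id, length in bp, owning genome, and the offset of
    its first base inside the genome's concatenated coordinates."""

    contig_id: str
    length: int
    genome_id: str
    offset: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(
                f"contig {self.contig_id!r}: length must be >= 1, got {self.length}"
            )


@dataclass
class GenomeCatalog:
    """Ordered contigs per genome, genome lengths, and concatenation offsets.

    Contig order within a genome is the insertion order (FASTA record
    order or map-file line order) and fixes the concatenation: contig k
    starts at the sum of the lengths of contigs 1..k-1.
    """

    contigs_by_genome: Dict[str, List[ContigRecord]] = field(default_factory=dict)
    _contig_index: Dict[str, ContigRecord] = field(default_factory=dict)

    @classmethod
    def from_contig_lengths(
        cls, genomes: Mapping[str, Sequence[Tuple[str, int]]]
    ) -> "GenomeCatalog":
        """Build a catalog from ``{genome_id: [(contig_id, length), ...]}``."""
        cat = cls()
        for genome_id, contigs in genomes.items():
            for contig_id, length in contigs:
                cat.add_contig(contig_id, length, genome_id)
        cat.validate()
        return cat

    def add_contig(self, contig_id: str, length: int, genome_id: str) -> ContigRecord:
        if contig_id in self._contig_index:
            other = self._contig_index[contig_id].genome_id
            raise ValueError(
                f"duplicate contig id {contig_id!r} (genomes {other!r} and {genome_id!r})"
            )
        existing = self.contigs_by_genome.setdefault(genome_id, [])
        offset = existing[-1].offset + existing[-1].length if existing else 0
        rec = ContigRecord(contig_id, length, genome_id, offset)
        existing.append(rec)
        self._contig_index[contig_id] = rec
        return rec

    def validate(self) -> None:
        for genome_id, contigs in self.contigs_by_genome.items():
            if not contigs:
                raise ValueError(f"genome {genome_id!r} has no contigs")

    # -- lookups -------------------------------------------------------

    @property
    def genome_ids(self) -> List[str]:
        return sorted(self.contigs_by_genome)

    def __contains__(self, contig_id: str) -> bool:
        return contig_id in self._contig_index

    def contig(self, contig_id: str) -> ContigRecord:
        return self._contig_index[contig_id]

    def genome_of(self, contig_id: str) -> str:
        return self._contig_index[contig_id].genome_id

    def genome_length(self, genome_id: str) -> int:
        """Total length Gl of the genome (sum of its contig lengths)."""
        contigs = self.contigs_by_genome[genome_id]
        return contigs[-1].offset + contigs[-1].length

    def concatenated_position(self, contig_id: str, start: int) -> int:
        """Project a contig-local 0-based start onto the genome concatenation."""
        rec = self._contig_index[contig_id]
        if not 0 <= start < rec.length:
            raise ValueError(
                f"position {start} outside contig {contig_id!r} (length {rec.length})"
            )
        return rec.offset + start

    def total_length(self) -> int:
        return sum(self.genome_length(g) for g in self.contigs_by_genome)


def _load_from_fasta_dir(fasta_dir: Path) -> GenomeCatalog:
    exts = {".fa", ".fasta", ".fna"}
    files = sorted(p for p in fasta_dir.iterdir() if p.suffix.lower() in exts)
    if not files:
        raise ValueError(f"no FASTA files (*.fa, *.fasta, *.fna) found in {fasta_dir}")
    cat = GenomeCatalog()
    for path in files:
        genome_id = path.stem
        n = 0
        for rec in SeqIO.parse(str(path), "fasta"):
            cat.add_contig(rec.id, len(rec.seq), genome_id)
            n += 1
        if n == 0:
            raise ValueError(f"FASTA file {path} contains no records")
    cat.validate()
    return cat


def _load_from_map(map_path: Path, contig_lengths: Mapping[str, int]) -> GenomeCatalog:
    cat = GenomeCatalog()
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{map_path}:{lineno}: expected two tab-separated columns "
                    f"(contig_id, genome_id), got {len(parts)}"
                )
            contig_id, genome_id = parts
            if contig_id not in contig_lengths:
                raise ValueError(
                    f"{map_path}:{lineno}: contig {contig_id!r} has no known length "
                    "(absent from the length source)"
                )
            cat.add_contig(contig_id, contig_lengths[contig_id], genome_id)
    cat.validate()
    if not cat.contigs_by_genome:
        raise ValueError(f"contig map {map_path} is empty")
    return cat


def read_fai_lengths(fai_path: os.PathLike | str) -> Dict[str, int]:
    """Contig lengths from a samtools-style .fai index (name, length, ...)."""
    lengths: Dict[str, int] = {}
    with open(fai_path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            lengths[parts[0]] = int(parts[1])
    return lengths


def load_genome_catalog(
    path: os.PathLike | str,
    contig_lengths: Mapping[str, int] | None = None,
) -> GenomeCatalog:
    """Load the genome catalog from either source the tool accepts.

    ``path`` may be a directory of FASTA files (one genome per file;
    genome id = file stem; contigs in record order) or a two-column TSV
    mapping contig_id -> genome_id.  The TSV form needs ``contig_lengths``
    -- e.g. from :func:`read_fai_lengths` or the alignment header.
    """
    path = Path(path)
    if path.is_dir():
        return _load_from_fasta_dir(path)
    if contig_lengths is None:
        raise ValueError(
            "a contig map file requires contig_lengths (from a .fai index "
            "or the alignment header)"
        )
    return _load_from_map(path, contig_lengths)
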