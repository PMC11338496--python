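"""Synthetic genomes and read placements with controlled mapping patterns.

Reads are *placed*, not sequenced: start positions are drawn directly
from a placement model and written straight into a sorted SAM file, with
no base errors and no aligner in the loop.  The presence metrics consume
mapping positions only, so this isolates their behaviour from mapper
artefacts while still exercising the full alignment-file code path.

Three placement patterns cover the mapping regimes the metrics must
distinguish:

* ``Uniform`` -- starts i.i.d. uniform over the genome: the signature of
  a genome truly in the sample (homogeneous Poisson placements).
* ``RegionRestricted`` -- starts confined to one or more intervals
  totalling a stated fraction of the genome: the signature of reads
  mismapping onto the conserved regions of an absent genome.
* ``Bimodal`` -- a uniform background plus a region-restricted spike,
  giving a two-mode per-base depth distribution: a present genome
  contaminated by mismapped reads.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pysam

from .alignment import MateGroup, ReadPlacement
from .catalog import GenomeCatalog

__all__ = [
    "Uniform",
    "RegionRestricted",
    "Bimodal",
    "GenomeSpec",
    "SimulationSpec",
    "genome_rng",
    "make_genomes",
    "sample_placements",
    "subsample_placements",
    "write_alignment",
    "write_truth",
    "simulate_scenario",
]


@dataclass(frozen=True)
class Uniform:
    """Homogeneous placements at the given mean coverage (x)."""

    coverage: float
    present: bool = True

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError(f"coverage must be >= 0, got {self.coverage}")


@dataclass(frozen=True)
class RegionRestricted:
    """Placements confined to ``n_regions`` disjoint intervals that
    together span ``covered_fraction`` of the genome.  ``coverage`` is
    still the genome-wide mean (reads inside the regions are denser)."""

    coverage: float
    covered_fraction: float
    n_regions: int = 1
    present: bool = False

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError(f"coverage must be >= 0, got {self.coverage}")
        if not 0 < self.covered_fraction <= 1:
            raise ValueError(
                f"covered_fraction must be in (0, 1], got {self.covered_fraction}"
            )
        if self.n_regions < 1:
            raise ValueError(f"n_regions must be >= 1, got {self.n_regions}")


@dataclass(frozen=True)
class Bimodal:
    """Uniform background at ``base_coverage`` plus a region-restricted
    spike at ``spike_coverage`` on ``spike_fraction`` of the genome."""

    base_coverage: float
    spike_coverage: float
    spike_fraction: float
    present: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.spike_fraction < 1:
            raise ValueError(
                f"spike_fraction must be in (0, 1), got {self.spike_fraction}"
            )
        if self.base_coverage < 0 or self.spike_coverage < 0:
            raise ValueError("coverages must be >= 0")


Pattern = Union[Uniform, RegionRestricted, Bimodal]


@dataclass(frozen=True)
class GenomeSpec:
    """One synthetic genome: contig lengths and its placement pattern."""

    genome_id: str
    contig_lengths: Tuple[int, ...]
    pattern: Pattern

    def __post_init__(self) -> None:
        for length in self.contig_lengths:
            if length < 1:
                raise ValueError(
                    f"genome {self.genome_id!r}: contig lengths must be >= 1"
                )

    @property
    def genome_length(self) -> int:
        return sum(self.contig_lengths)


@dataclass(frozen=True)
class SimulationSpec:
    """A full scenario: genomes, read geometry, and the master seed.

    Identical spec + seed give byte-identical outputs.  Defaults mirror
    common short-read metagenome sequencing: 150 bp reads, paired ends
    with a 270 bp mean insert.
    """

    genomes: Tuple[GenomeSpec, ...]
    read_length: int = 150
    paired: bool = True
    insert_mean: float = 270.0
    insert_sd: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValueError(f"read_length must be >= 1, got {self.read_length}")

    def catalog(self) -> GenomeCatalog:
        return GenomeCatalog.from_contig_lengths(
            {
                g.genome_id: [
                    (f"{g.genome_id}_c{k}", length)
                    for k, length in enumerate(g.contig_lengths)
                ]
                for g in self.genomes
            }
        )

    def truth(self) -> Dict[str, bool]:
        return {g.genome_id: g.pattern.present for g in self.genomes}


def genome_rng(seed: int, genome_id: str) -> np.random.Generator:
    """Per-genome random stream, stable under genome reordering."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(genome_id.encode())])
    )


# -- genome sequences ---------------------------------------------------


def make_genomes(spec: SimulationSpec, out_dir: str | Path) -> List[Path]:
    """Write one FASTA per genome (random A/C/G/T), returning the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for g in spec.genomes:
        rng = genome_rng(spec.seed, g.genome_id)
        path = out_dir / f"{g.genome_id}.fasta"
        with open(path, "w") as fh:
            for k, length in enumerate(g.contig_lengths):
                seq = bases[rng.integers(0, 4, size=length)].tobytes().decode()
                fh.write(f">{g.genome_id}_c{k}\n")
                for i in range(0, length, 80):
                    fh.write(seq[i : i + 80] + "\n")
        paths.append(path)
    return paths


# -- placement sampling -------------------------------------------------


def _concat_to_contig(
    spec_genome: GenomeSpec, concat_start: int
) -> Tuple[str, int]:
    """Map a concatenated-coordinate start back to (contig_id, local start)."""
    offset = 0
    for k, length in enumerate(spec_genome.contig_lengths):
        if concat_start < offset + length:
            return f"{spec_genome.genome_id}_c{k}", concat_start - offset
        offset += length
    raise ValueError(
        f"start {concat_start} outside genome {spec_genome.genome_id!r}"
    )


def _sample_regions(
    rng: np.random.Generator, genome_length: int, covered_fraction: float, n_regions: int
) -> List[Tuple[int, int]]:
    """Disjoint intervals totalling covered_fraction * Gl.

    The genome is cut into ``n_regions`` equal slots and one interval of
    length covered_fraction * Gl / n_regions is placed uniformly inside
    each slot, which guarantees disjointness.
    """
    slot = genome_length // n_regions
    region_len = max(1, int(round(covered_fraction * genome_length / n_regions)))
    if region_len > slot:
        raise ValueError("covered_fraction too large for the requested n_regions")
    regions = []
    for k in range(n_regions):
        lo = k * slot + int(rng.integers(0, slot - region_len + 1))
        regions.append((lo, lo + region_len))
    return regions


def _uniform_starts(
    rng: np.random.Generator, n: int, genome_length: int, read_length: int
) -> np.ndarray:
    hi = max(1, genome_length - read_length + 1)
    return rng.integers(0, hi, size=n)


def _region_starts(
    rng: np.random.Generator,
    n: int,
    regions: Sequence[Tuple[int, int]],
    genome_length: int,
    read_length: int,
) -> np.ndarray:
    lengths = np.array([hi - lo for lo, hi in regions], dtype=np.int64)
    cum = np.concatenate(([0], np.cumsum(lengths)))
    u = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, u, side="right") - 1
    starts = np.array([regions[i][0] for i in idx]) + (u - cum[idx])
    return np.minimum(starts, max(0, genome_length - read_length))


def _read_count(coverage: float, genome_length: int, read_length: int) -> int:
    n = int(round(coverage * genome_length / read_length))
    if coverage > 0 and n == 0:
        import warnings

        warnings.warn(
            f"requested coverage {coverage} yields zero reads "
            f"(Gl={genome_length}, Rl={read_length})"
        )
    return n


def _layer_placements(
    rng: np.random.Generator,
    starts: np.ndarray,
    g: GenomeSpec,
    spec: SimulationSpec,
    name_prefix: str,
) -> List[ReadPlacement]:
    """Turn first-mate concatenated starts into placements; paired mode
    adds a second mate offset by (insert - read length) downstream,
    clamped onto the genome."""
    gl = g.genome_length
    rl = spec.read_length
    out: List[ReadPlacement] = []
    if spec.paired:
        shifts = np.rint(
            rng.normal(spec.insert_mean - rl, spec.insert_sd, size=len(starts))
        ).astype(np.int64)
        mates = np.clip(starts + np.maximum(shifts, 0), 0, max(0, gl - rl))
        for i, (s1, s2) in enumerate(zip(starts, mates)):
            name = f"{name_prefix}_{i}"
            c1, p1 = _concat_to_contig(g, int(s1))
            c2, p2 = _concat_to_contig(g, int(s2))
            out.append(ReadPlacement(c1, p1, rl, MateGroup.FIRST, name))
            out.append(ReadPlacement(c2, p2, rl, MateGroup.SECOND, name))
    else:
        for i, s in enumerate(starts):
            c, p = _concat_to_contig(g, int(s))
            out.append(
                ReadPlacement(c, p, rl, MateGroup.UNPAIRED, f"{name_prefix}_{i}")
            )
    return out


def sample_placements(spec: SimulationSpec, g: GenomeSpec) -> List[ReadPlacement]:
    """Draw all read placements for one genome according to its pattern.

    In paired mode the requested coverage is split over the two mates:
    the number of pairs is half the single-end read count.
    """
    rng = genome_rng(spec.seed, g.genome_id)
    gl, rl = g.genome_length, spec.read_length
    pattern = g.pattern

    def n_units(coverage: float) -> int:
        n = _read_count(coverage, gl, rl)
        return n // 2 if spec.paired else n

    placements: List[ReadPlacement] = []
    if isinstance(pattern, Uniform):
        starts = _uniform_starts(rng, n_units(pattern.coverage), gl, rl)
        placements = _layer_placements(rng, starts, g, spec, g.genome_id)
    elif isinstance(pattern, RegionRestricted):
        regions = _sample_regions(rng, gl, pattern.covered_fraction, pattern.n_regions)
        starts = _region_starts(rng, n_units(pattern.coverage), regions, gl, rl)
        placements = _layer_placements(rng, starts, g, spec, g.genome_id)
    elif isinstance(pattern, Bimodal):
        base = _uniform_starts(rng, n_units(pattern.base_coverage), gl, rl)
        regions = _sample_regions(rng, gl, pattern.spike_fraction, 1)
        spike = _region_starts(rng, n_units(pattern.spike_coverage), regions, gl, rl)
        placements = _layer_placements(
            rng, base, g, spec, f"{g.genome_id}_base"
        ) + _layer_placements(rng, spike, g, spec, f"{g.genome_id}_spike")
    else:  # pragma: no cover
        raise TypeError(f"unknown pattern {pattern!r}")
    return placements


def subsample_placements(
    placements: Sequence[ReadPlacement], fraction: float, seed: int
) -> List[ReadPlacement]:
    """Keep each read independently with probability ``fraction``.

    Mates of a pair share a read name and are kept or dropped together,
    mirroring read-level subsampling of an alignment file.
    """
    if not 0 <= fraction <= 1:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B5A]))
    decisions: Dict[str, bool] = {}
    kept = []
    for p in placements:
        key = p.name if p.name is not None else id(p)
        if key not in decisions:
            decisions[key] = bool(rng.random() < fraction)
        if decisions[key]:
            kept.append(p)
    return kept


# -- SAM output ---------------------------------------------------------

_FLAG = {
    MateGroup.UNPAIRED: 0,
    MateGroup.FIRST: 0x1 | 0x40,
    MateGroup.SECOND: 0x1 | 0x80,
}


def write_alignment(
    placements: Sequence[ReadPlacement],
    catalog: GenomeCatalog,
    path: str | Path,
) -> Path:
    """Write placements as a valid coordinate-sorted SAM file.

    Each record carries a ``<read length>M`` CIGAR and a dummy sequence;
    the header declares every catalog contig and the coordinate sort.
    """
    path = Path(path)
    sq = []
    contig_order: Dict[str, int] = {}
    for genome_id in catalog.genome_ids:
        for rec in catalog.contigs_by_genome[genome_id]:
            contig_order[rec.contig_id] = len(sq)
            sq.append({"SN": rec.contig_id, "LN": rec.length})
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": sq}
    )
    for p in placements:
        if p.contig_id not in contig_order:
            raise ValueError(f"placement on unknown contig {p.contig_id!r}")
        if p.start >= catalog.contig(p.contig_id).length:
            raise ValueError(
                f"placement start {p.start} off contig {p.contig_id!r}"
            )
    ordered = sorted(placements, key=lambda p: (contig_order[p.contig_id], p.start))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for i, p in enumerate(ordered):
            a = pysam.AlignedSegment(header)
            a.query_name = p.name if p.name is not None else f"read_{i}"
            a.flag = _FLAG[p.mate_group]
            a.reference_id = contig_order[p.contig_id]
            a.reference_start = p.start
            a.mapping_quality = 60
            a.cigartuples = [(0, p.read_length)]
            a.query_sequence = "A" * p.read_length
            out.write(a)
    return path


def write_truth(spec: SimulationSpec, path: str | Path) -> Path:
    """Write the scenario's truth labels as a two-column TSV."""
    path = Path(path)
    with open(path, "w") as fh:
        for genome_id in sorted(spec.truth()):
            fh.write(f"{genome_id}\t{1 if spec.truth()[genome_id] else 0}\n")
    return path


def simulate_scenario(
    spec: SimulationSpec,
    out_dir: str | Path,
    *,
    write_fasta: bool = True,
) -> Dict[str, Path]:
    """Materialise a scenario: FASTA genomes, sorted SAM, truth TSV.

    Returns paths under keys ``genomes`` (directory), ``alignment`` and
    ``truth``.  ``write_fasta=False`` skips the sequence files for
    position-only workflows (the catalog is still available from the
    spec).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome_dir = out_dir / "genomes"
    if write_fasta:
        make_genomes(spec, genome_dir)
    catalog = spec.catalog()
    placements: List[ReadPlacement] = []
    for g in spec.genomes:
        placements.extend(sample_placements(spec, g))
    sam = write_alignment(placements, catalog, out_dir / "reads.sam")
    truth = write_truth(spec, out_dir / "truth.tsv")
    return {"genomes": genome_dir, "alignment": sam, "truth": truth}
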