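import numpy as np
import pytest

from prescall import (
    GenomeCatalog,
    GenomeSpec,
    RegionRestricted,
    SimulationSpec,
    Uniform,
    simulate_scenario,
)


@pytest.fixture
def two_contig_catalog() -> GenomeCatalog:
    """One genome of two contigs (300 + 700 bp) plus a single-contig one."""
    return GenomeCatalog.from_contig_lengths(
        {"gA": [("cA1", 300), ("cA2", 700)], "gB": [("cB1", 100)]}
    )


@pytest.fixture
def small_scenario(tmp_path):
    """A materialised scenario: one uniform, one region-restricted, one
    empty genome; returns (spec, paths dict)."""
    spec = SimulationSpec(
        genomes=(
            GenomeSpec("present_uniform", (50_000,), Uniform(1.0)),
            GenomeSpec(
                "absent_region", (30_000, 20_000), RegionRestricted(0.6, 0.08)
            ),
            GenomeSpec("no_reads", (40_000,), Uniform(0.0)),
        ),
        seed=11,
    )
    return spec, simulate_scenario(spec, tmp_path / "scn")


def naive_depth(placements, contig_length):
    """Per-base overlap count by direct per-position accumulation."""
    depth = np.zeros(contig_length, dtype=int)
    for start, read_length in placements:
        depth[start : min(start + read_length, contig_length)] += 1
    return depth
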