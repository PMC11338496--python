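"""End-to-end orchestration: alignment file + catalog -> presence calls."""

from __future__ import annotations

import logging
from multiprocessing import Pool
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from .alignment import GenomePlacements, collect_genome_placements, stream_placements
from .caller import ClassifierConfig, PresenceCall, classify, rcn
from .catalog import GenomeCatalog
from .evenness import EvennessMetrics, genome_evenness
from .gaps import GapMetrics, genome_gap_metrics

logger = logging.getLogger(__name__)

__all__ = ["compute_metrics", "call_presence"]

# module-level so Pool workers can pickle the task function
_WORK_CATALOG: Optional[GenomeCatalog] = None


def _metrics_for_genome(
    args: Tuple[GenomePlacements, GenomeCatalog]
) -> Tuple[str, EvennessMetrics, GapMetrics]:
    gp, catalog = args
    return gp.genome_id, genome_evenness(gp, catalog), genome_gap_metrics(gp)


def compute_metrics(
    alignment_path: str | Path,
    catalog: GenomeCatalog,
    *,
    strict: bool = False,
    primary_only: bool = False,
    processes: int = 1,
) -> Tuple[Dict[str, EvennessMetrics], Dict[str, GapMetrics], Dict[str, GenomePlacements]]:
    """Stream the alignment once and compute both metric families per genome.

    Genomes are independent work units; with ``processes > 1`` they are
    distributed over a pool, and results are re-keyed by genome id so
    scheduling never changes the output.
    """
    placements = stream_placements(
        alignment_path, catalog, strict=strict, primary_only=primary_only
    )
    by_genome = collect_genome_placements(placements, catalog)
    logger.info(
        "collected %d genomes, %d mapped reads",
        len(by_genome),
        sum(gp.n_reads for gp in by_genome.values()),
    )
    tasks = [(gp, catalog) for gp in by_genome.values()]
    if processes > 1:
        with Pool(processes) as pool:
            results = pool.map(_metrics_for_genome, tasks)
    else:
        results = [_metrics_for_genome(t) for t in tasks]
    evenness = {gid: ev for gid, ev, _ in results}
    gaps = {gid: gm for gid, _, gm in results}
    return evenness, gaps, by_genome


def call_presence(
    alignment_path: str | Path,
    catalog: GenomeCatalog,
    config: ClassifierConfig = ClassifierConfig(),
    *,
    strict: bool = False,
    primary_only: bool = False,
    processes: int = 1,
) -> List[PresenceCall]:
    """Full pipeline: metrics plus the decision rule, one call per genome.

    Rtot in the abundance normalisation is the total number of mapped
    reads collected across all catalog genomes.
    """
    evenness, gaps, by_genome = compute_metrics(
        alignment_path,
        catalog,
        strict=strict,
        primary_only=primary_only,
        processes=processes,
    )
    total_reads = sum(gp.n_reads for gp in by_genome.values())
    calls = []
    for genome_id in catalog.genome_ids:
        gp = by_genome[genome_id]
        rcn_value = (
            rcn(gp.n_reads, gp.genome_length, total_reads) if total_reads else 0.0
        )
        calls.append(
            classify(
                genome_id,
                gp.genome_length,
                evenness[genome_id],
                gaps[genome_id],
                gp.n_reads,
                rcn_value,
                config,
            )
        )
    n_present = sum(c.present for c in calls)
    logger.info("called %d of %d genomes present", n_present, len(calls))
    return calls
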