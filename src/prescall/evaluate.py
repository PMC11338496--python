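"""Scoring of presence calls against truth labels.

Besides plain confusion rates (TPR, TNR, balanced accuracy), calls can
be binned by genome coverage on a log2 grid to show how each metric's
reliability depends on sequencing depth: bin i covers the half-open
coverage interval (0.00004 * 2^i, 0.00004 * 2^(i+1)].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .caller import PresenceCall

logger = logging.getLogger(__name__)

__all__ = [
    "BIN_BASE",
    "CoverageBin",
    "confusion_rates",
    "coverage_bin_index",
    "binned_rates",
    "load_truth",
    "write_binned_rates",
]

#: Lower boundary of bin 0 on the coverage axis.
BIN_BASE = 0.00004


@dataclass(frozen=True)
class CoverageBin:
    """One log2 coverage bin with its member counts and rates."""

    index: int
    low: float
    up: float
    n_present: int  # truth-present observations in the bin
    n_absent: int  # truth-absent observations in the bin
    tpr: Optional[float]
    tnr: Optional[float]

    @property
    def n(self) -> int:
        return self.n_present + self.n_absent


def confusion_rates(
    calls: Sequence[PresenceCall], truth: Mapping[str, bool]
) -> Tuple[Optional[float], Optional[float], Optional[float]]:
    """TPR, TNR and balanced accuracy of calls against truth labels.

    Every call must have a label.  A rate whose class is empty is
    ``None``; balanced accuracy is ``None`` unless both rates exist.
    """
    tp = fn = tn = fp = 0
    for call in calls:
        if call.genome_id not in truth:
            raise KeyError(f"no truth label for genome {call.genome_id!r}")
        if truth[call.genome_id]:
            if call.present:
                tp += 1
            else:
                fn += 1
        else:
            if call.present:
                fp += 1
            else:
                tn += 1
    tpr = tp / (tp + fn) if tp + fn else None
    tnr = tn / (tn + fp) if tn + fp else None
    bacc = (tpr + tnr) / 2 if tpr is not None and tnr is not None else None
    return tpr, tnr, bacc


def coverage_bin_index(coverage: float) -> int:
    """Index i of the bin with 0.00004 * 2^i < coverage <= 0.00004 * 2^(i+1).

    Negative indices mean the coverage falls below bin 0.
    """
    if coverage <= 0:
        raise ValueError(f"coverage must be > 0 to be binned, got {coverage}")
    i = math.ceil(math.log2(coverage / BIN_BASE)) - 1
    # guard against log2 rounding at exact boundaries
    while BIN_BASE * 2.0**i >= coverage:
        i -= 1
    while BIN_BASE * 2.0 ** (i + 1) < coverage:
        i += 1
    return i


def binned_rates(
    observations: Iterable[Tuple[float, bool, bool]],
    i_max: int = 21,
    i_min: int = 0,
) -> List[CoverageBin]:
    """Per-coverage-bin TPR/TNR from (coverage, called_present, truth) triples.

    Observations outside bins ``i_min..i_max`` are dropped with a
    warning.  All bins in range are reported, including empty ones.
    """
    counts: Dict[int, List[int]] = {i: [0, 0, 0, 0] for i in range(i_min, i_max + 1)}
    dropped = 0
    for coverage, called, truly_present in observations:
        i = coverage_bin_index(coverage)
        if i < i_min or i > i_max:
            dropped += 1
            continue
        tp_fn_tn_fp = counts[i]
        if truly_present:
            tp_fn_tn_fp[0 if called else 1] += 1
        else:
            tp_fn_tn_fp[3 if called else 2] += 1
    if dropped:
        logger.warning("%d observations outside bins %d..%d dropped", dropped, i_min, i_max)
    bins = []
    for i in range(i_min, i_max + 1):
        tp, fn, tn, fp = counts[i]
        bins.append(
            CoverageBin(
                index=i,
                low=BIN_BASE * 2.0**i,
                up=BIN_BASE * 2.0 ** (i + 1),
                n_present=tp + fn,
                n_absent=tn + fp,
                tpr=tp / (tp + fn) if tp + fn else None,
                tnr=tn / (tn + fp) if tn + fp else None,
            )
        )
    return bins


def load_truth(path: str | Path) -> Dict[str, bool]:
    """Truth labels from a two-column TSV (genome_id, present as 0/1)."""
    truth: Dict[str, bool] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or parts[1] not in ("0", "1"):
                raise ValueError(
                    f"{path}:{lineno}: expected 'genome_id<TAB>0|1', got {line!r}"
                )
            truth[parts[0]] = parts[1] == "1"
    return truth


def write_binned_rates(bins: Sequence[CoverageBin], path: str | Path) -> None:
    """Write bins as TSV (i, low, up, n, tpr, tnr)."""
    df = pd.DataFrame(
        {
            "i": [b.index for b in bins],
            "low": [b.low for b in bins],
            "up": [b.up for b in bins],
            "n": [b.n for b in bins],
            "tpr": [b.tpr if b.tpr is not None else float("nan") for b in bins],
            "tnr": [b.tnr if b.tnr is not None else float("nan") for b in bins],
        }
    )
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
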