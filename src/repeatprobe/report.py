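"""Binding tracks, imaging-window calls, and summary statistics.

The per-bin predicted binding sums are min-max normalized onto the 0-255
integer scale for browser display (all-equal input maps to 0), an imaging
window is called as the smallest interval spanning every target-overlapping
bin whose raw binding exceeds ``align_thresh``, and a two-sided Fisher
exact test is provided for contingency comparisons of probe performance
counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genome import BedInterval

logger = logging.getLogger(__name__)


class NoImagingWindowError(ValueError):
    """No bin overlapping the target exceeds the threshold."""


@dataclass
class BindingTrack:
    bins: list[BedInterval]
    raw: np.ndarray
    normalized: np.ndarray  # integers in [0, 255]


def normalize_track(bins: list[BedInterval], raw: Sequence[float]) -> BindingTrack:
    """Min-max scale per-bin sums to [0, 255], rounded half-up to integers."""
    if len(bins) == 0 or len(bins) != len(raw):
        raise ValueError("bins and raw sums must be non-empty and equal length")
    raw_arr = np.asarray(raw, dtype=float)
    lo, hi = raw_arr.min(), raw_arr.max()
    if hi > lo:
        scaled = 255.0 * (raw_arr - lo) / (hi - lo)
        normalized = np.floor(scaled + 0.5).astype(int)
    else:
        normalized = np.zeros(len(raw_arr), dtype=int)
    return BindingTrack(bins=list(bins), raw=raw_arr, normalized=normalized)


def imaging_window(
    track: BindingTrack, target: BedInterval, align_thresh: float
) -> BedInterval:
    """Smallest interval spanning target-overlapping bins above threshold."""
    qualifying = [
        b
        for b, raw in zip(track.bins, track.raw)
        if raw > align_thresh and b.overlaps(target)
    ]
    if not qualifying:
        raise NoImagingWindowError(
            f"no bin overlapping {target.scaffold}:{target.start}-{target.end} "
            f"exceeds align_thresh={align_thresh}"
        )
    return BedInterval(
        target.scaffold,
        min(b.start for b in qualifying),
        max(b.end for b in qualifying),
    )


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The two-sided p sums all tables with the observed margins whose
    hypergeometric probability does not exceed the observed table's.  A
    zero margin carries no information; p = 1 by convention.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        logger.warning("degenerate 2x2 table (zero margin); returning p = 1")
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def write_bedgraph(
    bins: Iterable[BedInterval], values: Iterable[float], path: str | Path,
    integer: bool = False,
) -> None:
    with open(path, "w") as fh:
        for b, v in zip(bins, values):
            value = f"{int(v)}" if integer else f"{v:.4f}"
            fh.write(f"{b.scaffold}\t{b.start}\t{b.end}\t{value}\n")
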