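"""De novo repeat-interval discovery from per-position k-mer counts.

A sliding window of ``W`` positions moves over the per-position count
stream of a scaffold.  Positions whose count strictly exceeds the threshold
``T`` are flagged; a window is repeat-positive when the fraction of flagged
positions inside it reaches the composition score ``C``.  Runs of positive
windows are merged, trimmed to the flagged positions they contain (so the
reported interval tracks the repetitive sequence itself rather than the
window footprint), and extended by k-1 bp so the footprint of the final
k-mer is covered.

An alternative composition reading — mean window count >= C — is available
via ``mode="mean"``; the flagged-fraction rule is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import BedInterval


class DiscoveryError(ValueError):
    pass


@dataclass(frozen=True)
class RepeatInterval:
    """A scaffold-anchored interval flagged as repetitive."""

    scaffold: str
    start: int
    end: int
    composition: float  # fraction of interval positions exceeding T

    def __len__(self) -> int:
        return self.end - self.start

    def as_bed(self) -> BedInterval:
        return BedInterval(self.scaffold, self.start, self.end,
                           name=f"{self.composition:.4f}")


def discover_repeats(
    counts,
    scaffold: str,
    W: int,
    T: float,
    C: float,
    k: int,
    file_start: int = 0,
    scaffold_length: int | None = None,
    mode: str = "flagged",
) -> list[RepeatInterval]:
    """Identify repetitive intervals in one scaffold's count stream.

    Parameters
    ----------
    counts
        Per-position genome-wide k-mer counts (one per k-mer start).
    W, T, C
        Window size (positions), count threshold (a position is flagged iff
        count > T), and composition score.
    k
        k-mer length used to build the counts; interval ends are extended by
        k - 1 bp.
    file_start
        bp offset at which scanning begins (applied per scaffold).
    scaffold_length
        When given, interval ends are clamped to it.
    mode
        "flagged" (fraction of flagged positions >= C, C in [0, 1]) or
        "mean" (mean window count >= C).
    """
    if W < 1:
        raise DiscoveryError(f"window size W must be >= 1, got {W}")
    if mode not in ("flagged", "mean"):
        raise DiscoveryError(f"unknown composition mode: {mode!r}")
    if mode == "flagged" and not 0.0 <= C <= 1.0:
        raise DiscoveryError(f"composition C must lie in [0, 1], got {C}")
    if file_start < 0:
        raise DiscoveryError(f"file_start must be >= 0, got {file_start}")

    counts = np.asarray(counts, dtype=float)[file_start:]
    n = len(counts)
    if n < W:
        return []

    flags = counts > T
    kernel = np.ones(W)
    if mode == "flagged":
        window_score = np.convolve(flags.astype(float), kernel, "valid") / W
    else:
        window_score = np.convolve(counts, kernel, "valid") / W
    positive = window_score >= C
    if not positive.any():
        return []

    intervals: list[RepeatInterval] = []
    # runs of consecutive positive windows
    idx = np.flatnonzero(positive)
    run_breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate(([0], run_breaks + 1))
    run_ends = np.concatenate((run_breaks, [len(idx) - 1]))
    for rs, re_ in zip(run_starts, run_ends):
        span_lo, span_hi = int(idx[rs]), int(idx[re_]) + W  # position-space span
        span_flags = flags[span_lo:span_hi]
        flagged = np.flatnonzero(span_flags)
        if len(flagged):
            lo = span_lo + int(flagged[0])
            hi = span_lo + int(flagged[-1]) + 1
        else:  # possible in "mean" mode only
            lo, hi = span_lo, span_hi
        composition = float(flags[lo:hi].mean())
        start = file_start + lo
        end = file_start + hi + (k - 1)
        if scaffold_length is not None:
            end = min(end, scaffold_length)
        intervals.append(RepeatInterval(scaffold, start, end, composition))
    return intervals
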