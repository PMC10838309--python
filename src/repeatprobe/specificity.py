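"""Per-probe on/off-target binding profiles over genome bins.

Each alignment hit carries a duplex probability; a hit is on-target when
its interval overlaps the target by at least 1 bp.  Hits are also
aggregated into fixed-size genome bins (a hit straddling two bins is
assigned to the bin containing its midpoint), and a probe is culled when
any bin that does not overlap the target accumulates more predicted
binding than ``off_bin_thresh``.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field

from .align import AlignmentHit
from .genome import BedInterval


@dataclass
class SpecificityProfile:
    """Predicted binding summary for one probe."""

    probe_id: str
    on_t: float
    off_t: float
    binding_prop: float | None  # None when on_t + off_t == 0 (invalid)
    bin_aggregates: dict[BedInterval, float] = field(default_factory=dict)

    @property
    def valid(self) -> bool:
        return self.binding_prop is not None


def make_windows(lengths: dict[str, int], bin_size: int) -> list[BedInterval]:
    """Tile every scaffold with consecutive bins; final bin truncated."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    bins: list[BedInterval] = []
    for scaffold, length in lengths.items():
        for start in range(0, length, bin_size):
            bins.append(BedInterval(scaffold, start, min(start + bin_size, length)))
    return bins


class _BinLocator:
    def __init__(self, bins: list[BedInterval]):
        self.by_scaffold: dict[str, tuple[list[int], list[BedInterval]]] = {}
        grouped: dict[str, list[BedInterval]] = {}
        for b in bins:
            grouped.setdefault(b.scaffold, []).append(b)
        for scaffold, group in grouped.items():
            group.sort(key=lambda b: b.start)
            self.by_scaffold[scaffold] = ([b.start for b in group], group)

    def locate(self, scaffold: str, position: int) -> BedInterval | None:
        if scaffold not in self.by_scaffold:
            return None
        starts, group = self.by_scaffold[scaffold]
        i = bisect_right(starts, position) - 1
        if i < 0:
            return None
        b = group[i]
        return b if b.start <= position < b.end else None


def profile(
    probe_id: str,
    hits_with_scores: list[tuple[AlignmentHit, float]],
    target: BedInterval,
    bins: list[BedInterval],
) -> SpecificityProfile:
    """Fold scored hits into On_T, Off_T, binding proportion, and bin sums."""
    locator = _BinLocator(bins)
    on_t = 0.0
    off_t = 0.0
    aggregates: dict[BedInterval, float] = {}
    for hit, p_dups in hits_with_scores:
        hit_iv = BedInterval(hit.scaffold, hit.start, hit.end)
        if hit_iv.overlaps(target):
            on_t += p_dups
        else:
            off_t += p_dups
        midpoint = (hit.start + hit.end) // 2
        b = locator.locate(hit.scaffold, midpoint)
        if b is not None:
            aggregates[b] = aggregates.get(b, 0.0) + p_dups
    total = on_t + off_t
    binding_prop = on_t / total if total > 0 else None
    return SpecificityProfile(
        probe_id=probe_id,
        on_t=on_t,
        off_t=off_t,
        binding_prop=binding_prop,
        bin_aggregates=aggregates,
    )


def off_bin_cull(
    prof: SpecificityProfile, target: BedInterval, off_bin_thresh: float
) -> bool:
    """True (pass) iff no non-target bin aggregate exceeds the threshold."""
    for b, aggregate in prof.bin_aggregates.items():
        if not b.overlaps(target) and aggregate > off_bin_thresh:
            return False
    return True
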