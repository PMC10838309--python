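"""Greedy probe selection by deep in silico specificity profiling.

Candidates are processed strictly in rank order.  Each is aligned to the
genome, every alignment site is scored with the two-state duplex model, and
the resulting profile is tested against the user criteria: a per-probe
on-target floor, a binding-proportion floor, the per-bin off-target cull,
and non-redundancy with every already-accepted probe (the best local
alignment between the two probe sequences, scored with the duplex model,
must not exceed ``max_pdups_binding``).  The loop stops when the aggregate
on-target sum reaches ``target_sum``, the accepted set reaches
``max_probe_return``, or the candidates are exhausted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .align import SeedIndex, align_probe, smith_waterman
from .genome import BedInterval, GenomeAssembly
from .rank import RankedProbe
from .specificity import SpecificityProfile, off_bin_cull, profile
from .thermo import ThermoModel, duplex_probability

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionCriteria:
    """Acceptance rules for the greedy selection loop (permissive defaults)."""

    target_sum: float = 25.0
    min_on_target: float = 5.0
    max_probe_return: int = 25
    min_binding_prop: float = 0.8
    max_pdups_binding: float = 0.8
    off_bin_thresh: float = 10.0

    def __post_init__(self):
        if self.max_probe_return < 1:
            raise ValueError("max_probe_return must be >= 1")
        for name in ("target_sum", "min_on_target", "min_binding_prop",
                     "max_pdups_binding", "off_bin_thresh"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class ProbeSet:
    """Outcome of the selection loop for one target interval."""

    accepted: list[tuple[RankedProbe, SpecificityProfile]] = field(default_factory=list)
    target: BedInterval | None = None
    termination_reason: str = "exhausted"  # target_sum_met | max_probes | exhausted
    decisions: list[tuple[str, str]] = field(default_factory=list)  # (probe_id, verdict)

    @property
    def aggregate_on_t(self) -> float:
        return sum(p.on_t for _, p in self.accepted)

    @property
    def aggregate_off_t(self) -> float:
        return sum(p.off_t for _, p in self.accepted)

    @property
    def binding_prop(self) -> float | None:
        total = self.aggregate_on_t + self.aggregate_off_t
        return self.aggregate_on_t / total if total > 0 else None


def probe_pair_pdups(a: str, b: str, model: ThermoModel) -> float:
    """Predicted duplexing between two probe sequences.

    The best local alignment of the two sequences (identity frame, matching
    the hit-pair convention) is scored with the two-state duplex model; no
    alignment means no predicted pairing.
    """
    result = smith_waterman(a, b)
    if result is None:
        return 0.0
    _, _, _, _, _, q_row, t_row = result
    return duplex_probability(q_row, t_row, model)


def select_probes(
    ranked: list[RankedProbe],
    assembly: GenomeAssembly,
    target: BedInterval,
    criteria: SelectionCriteria,
    model: ThermoModel,
    bins: list[BedInterval],
    seed_length: int = 15,
    max_alignments: int = 500_000,
    index: SeedIndex | None = None,
) -> ProbeSet:
    """Walk the rank-ordered candidates and build the final probe set."""
    if index is None:
        index = SeedIndex(assembly, seed_length)
    result = ProbeSet(target=target)
    for probe in ranked:
        probe_id = f"{probe.candidate.scaffold}:{probe.candidate.start}-{probe.candidate.end}"
        hits = align_probe(
            probe.sequence, assembly, seed_length=seed_length,
            max_alignments=max_alignments, index=index,
        )
        if not hits:
            result.decisions.append((probe_id, "reject:no_alignments"))
            continue
        scored = [
            (hit, duplex_probability(hit.probe_row, hit.target_row, model))
            for hit in hits
        ]
        prof = profile(probe_id, scored, target, bins)
        if not prof.valid or prof.on_t < criteria.min_on_target:
            result.decisions.append((probe_id, "reject:min_on_target"))
            continue
        if prof.binding_prop < criteria.min_binding_prop:
            result.decisions.append((probe_id, "reject:binding_prop"))
            continue
        if not off_bin_cull(prof, target, criteria.off_bin_thresh):
            result.decisions.append((probe_id, "reject:off_bin_thresh"))
            continue
        redundant = any(
            probe_pair_pdups(probe.sequence, acc.sequence, model)
            > criteria.max_pdups_binding
            for acc, _ in result.accepted
        )
        if redundant:
            result.decisions.append((probe_id, "reject:max_pdups_binding"))
            continue
        result.accepted.append((probe, prof))
        result.decisions.append((probe_id, "accept"))
        if result.aggregate_on_t >= criteria.target_sum:
            result.termination_reason = "target_sum_met"
            return result
        if len(result.accepted) >= criteria.max_probe_return:
            result.termination_reason = "max_probes"
            return result
    result.termination_reason = "exhausted"
    return result
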