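"""Candidate scoring and rank-ordering by target-specific k-mer enrichment.

For each candidate, R_m is the aggregate count of its constituent k-mers
inside the target interval and H_m the aggregate genome-wide count; their
ratio K_b = R_m / H_m is the k-mer enrichment of the probe toward its
target.  Candidates are ordered by the normalized rank score

    Nr = R_m / (max(R_m) * c1) + K_b / (max(K_b) * c2)

with maxima taken over the target's own candidate set.  A redundancy filter
then walks the ranked list and rejects any candidate whose k-mer set
overlaps the union of already-accepted candidates' k-mers by more than
``mer_cutoff`` (set semantics, no multiplicity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from .design import CandidateProbe
from .genome import BedInterval, GenomeAssembly
from .kmers import KmerCountTable, probe_kmer_counts, region_kmer_counter

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedProbe:
    candidate: CandidateProbe
    r_m: int
    h_m: int
    k_b: float
    nr: float = 0.0

    @property
    def sequence(self) -> str:
        return self.candidate.sequence


def probe_kmer_set(sequence: str, k: int) -> frozenset:
    return frozenset(sequence[i : i + k] for i in range(len(sequence) - k + 1))


def score_candidates(
    candidates: list[CandidateProbe],
    table: KmerCountTable,
    target: BedInterval,
    assembly: GenomeAssembly,
) -> list[RankedProbe]:
    """Compute R_m, H_m, and K_b for each candidate against its target."""
    if not candidates:
        return []
    counter = region_kmer_counter(assembly, target, table.k)
    scored: list[RankedProbe] = []
    for cand in candidates:
        r_m, h_m = probe_kmer_counts(
            table, cand.sequence, target, assembly, region_counter=counter
        )
        if h_m == 0:
            logger.warning(
                "dropping candidate %s:%d-%d with zero genome-wide k-mer count",
                cand.scaffold, cand.start, cand.end,
            )
            continue
        scored.append(RankedProbe(cand, r_m=r_m, h_m=h_m, k_b=r_m / h_m))
    return scored


def normalized_rank(
    probes: list[RankedProbe], c1: float = 1.0, c2: float = 1.0
) -> list[RankedProbe]:
    """Attach Nr scores and sort descending (stable; ties by start, sequence)."""
    if c1 <= 0 or c2 <= 0:
        raise ValueError("c1 and c2 must be positive")
    if not probes:
        return []
    max_rm = max(p.r_m for p in probes)
    max_kb = max(p.k_b for p in probes)
    rescored = [
        replace(p, nr=p.r_m / (max_rm * c1) + p.k_b / (max_kb * c2))
        for p in probes
    ]
    return sorted(
        rescored,
        key=lambda p: (-p.nr, p.candidate.start, p.sequence),
    )


def mer_cutoff_filter(
    ranked: list[RankedProbe], mer_cutoff: float, k: int
) -> list[RankedProbe]:
    """Drop rank-ordered candidates redundant with higher-ranked survivors.

    A candidate is rejected iff the proportion of its k-mers already present
    in the running union of accepted candidates' k-mers exceeds
    ``mer_cutoff``; otherwise it is accepted and its k-mers join the union.
    """
    survivors: list[RankedProbe] = []
    pool: set[str] = set()
    for probe in ranked:
        kmers = probe_kmer_set(probe.sequence, k)
        if not kmers:
            continue
        if len(kmers & pool) / len(kmers) > mer_cutoff:
            continue
        survivors.append(probe)
        pool |= kmers
    return survivors
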