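"""Candidate oligo probe mining under length / Tm / GC constraints.

A greedy left-to-right scan grows a window from ``min_length`` until the
formamide-adjusted melting temperature reaches ``min_temp`` (or the window
hits ``max_length``).  A window satisfying all five constraints is emitted
as a candidate and the scan resumes immediately after it (candidates do not
overlap); otherwise the scan advances by one base.  Windows containing N
are skipped past.  Probes are mined from the forward strand only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome import BedInterval, GenomeAssembly
from .thermo import melting_temperature


@dataclass(frozen=True)
class CandidateProbe:
    """A probe sequence with origin coordinates and thermodynamic attributes."""

    scaffold: str
    start: int
    end: int
    sequence: str
    tm: float
    gc_percent: float
    target: BedInterval

    @property
    def length(self) -> int:
        return self.end - self.start


def gc_percent(seq: str) -> float:
    return 100.0 * sum(1 for b in seq if b in "GC") / len(seq)


def mine_candidates(
    interval: BedInterval,
    assembly: GenomeAssembly,
    min_length: int = 25,
    max_length: int = 50,
    min_temp: float = 42.0,
    max_temp: float = 52.0,
    min_gc: float = 20.0,
    max_gc: float = 80.0,
    sodium_molar: float = 0.39,
    formamide_percent: float = 50.0,
) -> list[CandidateProbe]:
    """Mine candidate probes from an interval, in genomic order."""
    interval.validate(assembly)
    seq = assembly.slice(interval.scaffold, interval.start, interval.end)
    n = len(seq)
    candidates: list[CandidateProbe] = []
    pos = 0
    while pos + min_length <= n:
        window = seq[pos : pos + min_length]
        bad = window.rfind("N")
        if bad != -1:
            pos += bad + 1  # restart just past the last N in the window
            continue
        emitted = False
        length = min_length
        while length <= max_length and pos + length <= n:
            base = seq[pos + length - 1]
            if base == "N":
                break
            probe = seq[pos : pos + length]
            tm = melting_temperature(
                probe, sodium_molar=sodium_molar,
                formamide_percent=formamide_percent,
            )
            if tm >= min_temp:
                gc = gc_percent(probe)
                if tm <= max_temp and min_gc <= gc <= max_gc:
                    candidates.append(
                        CandidateProbe(
                            scaffold=interval.scaffold,
                            start=interval.start + pos,
                            end=interval.start + pos + length,
                            sequence=probe,
                            tm=tm,
                            gc_percent=gc,
                            target=interval,
                        )
                    )
                    pos += length
                    emitted = True
                break  # Tm reached but constraints failed: slide on
            length += 1
        if not emitted:
            pos += 1
    return candidates


def deduplicate(candidates: list[CandidateProbe]) -> list[CandidateProbe]:
    """Drop candidates whose exact sequence was already seen (order kept)."""
    seen: set[str] = set()
    unique: list[CandidateProbe] = []
    for cand in candidates:
        if cand.sequence not in seen:
            seen.add(cand.sequence)
            unique.append(cand)
    return unique
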