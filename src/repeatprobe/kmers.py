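"""Genome-wide k-mer counting and per-position / per-probe count queries.

Counting is strand-specific: k-mers are tallied exactly as written on the
forward strand, with no canonicalization, so a probe's genome-wide k-mer
aggregate (H_m) and its in-target aggregate (R_m) both refer to
forward-strand occurrences only.  Windows containing N contribute nothing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .genome import BedInterval, GenomeAssembly

DEFAULT_K = 18


class KmerError(ValueError):
    pass


@dataclass
class KmerCountTable:
    """Map from k-mer string to genome-wide occurrence count at fixed k."""

    k: int
    counts: Counter = field(default_factory=Counter)

    def __getitem__(self, kmer: str) -> int:
        return self.counts.get(kmer, 0)

    def __len__(self) -> int:
        return len(self.counts)

    def total(self) -> int:
        return sum(self.counts.values())

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"#k={self.k}\n")
            for kmer in sorted(self.counts):
                fh.write(f"{kmer}\t{self.counts[kmer]}\n")

    @classmethod
    def load(cls, path: str | Path) -> "KmerCountTable":
        counts: Counter = Counter()
        k = None
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#k="):
                    k = int(line[3:])
                    continue
                kmer, n = line.split("\t")
                counts[kmer] = int(n)
        if k is None:
            if not counts:
                raise KmerError(f"empty k-mer table: {path}")
            k = len(next(iter(counts)))
        return cls(k=k, counts=counts)


def _clean_segments(seq: str, k: int):
    """Yield (offset, segment) for maximal N-free stretches of length >= k."""
    start = 0
    for i, base in enumerate(seq):
        if base == "N":
            if i - start >= k:
                yield start, seq[start:i]
            start = i + 1
    if len(seq) - start >= k:
        yield start, seq[start:]


def count_kmers(assembly: GenomeAssembly, k: int = DEFAULT_K) -> KmerCountTable:
    """Count every N-free forward-strand k-mer of the assembly."""
    if k < 1:
        raise KmerError(f"k must be >= 1, got {k}")
    if all(len(seq) < k for seq in assembly.scaffolds.values()):
        raise KmerError(f"k={k} exceeds the length of every scaffold")
    counts: Counter = Counter()
    for seq in assembly.scaffolds.values():
        for _, segment in _clean_segments(seq, k):
            for i in range(len(segment) - k + 1):
                counts[segment[i : i + k]] += 1
    return KmerCountTable(k=k, counts=counts)


def position_counts(table: KmerCountTable, sequence: str) -> list[int]:
    """Genome-wide count of the k-mer starting at each position of ``sequence``.

    Positions whose k-mer contains N report 0.  A sequence shorter than k
    yields an empty stream.
    """
    k = table.k
    n = len(sequence) - k + 1
    if n <= 0:
        return []
    out = [0] * n
    get = table.counts.get
    for offset, segment in _clean_segments(sequence, k):
        for i in range(len(segment) - k + 1):
            out[offset + i] = get(segment[i : i + k], 0)
    return out


def region_kmer_counter(
    assembly: GenomeAssembly, region: BedInterval, k: int
) -> Counter:
    """Overlapping k-mer occurrence counts within a genomic interval."""
    seq = assembly.slice(region.scaffold, region.start, region.end)
    counts: Counter = Counter()
    for _, segment in _clean_segments(seq, k):
        for i in range(len(segment) - k + 1):
            counts[segment[i : i + k]] += 1
    return counts


def probe_kmer_counts(
    table: KmerCountTable,
    probe: str,
    region: BedInterval,
    assembly: GenomeAssembly,
    region_counter: Counter | None = None,
) -> tuple[int, int]:
    """Aggregate k-mer counts of a probe inside its target and genome-wide.

    Returns ``(r_m, h_m)``: the sum over the probe's constituent k-mers of
    occurrence counts within ``region`` (direct scan) and over the whole
    genome (from ``table``).  ``region_counter`` may be precomputed with
    :func:`region_kmer_counter` to amortize scans over many probes.
    """
    k = table.k
    if len(probe) < k:
        raise KmerError(f"probe length {len(probe)} is shorter than k={k}")
    if region_counter is None:
        region_counter = region_kmer_counter(assembly, region, k)
    r_m = 0
    h_m = 0
    for i in range(len(probe) - k + 1):
        kmer = probe[i : i + k]
        r_m += region_counter.get(kmer, 0)
        h_m += table[kmer]
    return r_m, h_m
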