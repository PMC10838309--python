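"""Genome assemblies, genomic intervals, and the plain-text formats that carry them.

All coordinates in this package are 0-based, half-open (BED convention).
Sequences are normalized on input: uppercased, U mapped to T, and any
character outside {A, C, G, T} collapsed to N.  Soft-masked (lowercase)
sequence is treated as ordinary sequence, since probe design here is
performed on unmasked assemblies.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

_VALID = set("ACGTN")
_NORMALIZE = str.maketrans(
    {c: "N" for c in "BDEFHIJKLMOPQRSVWXYZ"} | {"U": "T"}
)

_COMPLEMENT = str.maketrans("ACGTN-", "TGCAN-")


def normalize_sequence(seq: str) -> str:
    """Uppercase, map U->T, and collapse all non-ACGT characters to N."""
    return seq.upper().translate(_NORMALIZE)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeIOError(ValueError):
    """Malformed or inconsistent genome input."""


@dataclass
class GenomeAssembly:
    """Named scaffolds with normalized sequences.

    ``scaffolds`` preserves input order; ``lengths`` always mirrors it.
    """

    scaffolds: dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.scaffolds.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.scaffolds

    def __len__(self) -> int:
        return len(self.scaffolds)

    def add(self, name: str, seq: str) -> None:
        if not name:
            raise GenomeIOError("scaffold name must be non-empty")
        if name in self.scaffolds:
            raise GenomeIOError(f"duplicate scaffold name: {name!r}")
        self.scaffolds[name] = normalize_sequence(seq)

    def slice(self, scaffold: str, start: int, end: int) -> str:
        return self.scaffolds[scaffold][start:end]


@dataclass(frozen=True)
class BedInterval:
    """A scaffold-anchored half-open interval."""

    scaffold: str
    start: int
    end: int
    name: str | None = None

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise GenomeIOError(
                f"invalid interval {self.scaffold}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "BedInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and min(self.end, other.end) - max(self.start, other.start) >= 1
        )

    def validate(self, assembly: GenomeAssembly) -> None:
        if self.scaffold not in assembly:
            raise GenomeIOError(f"unknown scaffold: {self.scaffold!r}")
        if self.end > len(assembly.scaffolds[self.scaffold]):
            raise GenomeIOError(
                f"interval {self.scaffold}:{self.start}-{self.end} exceeds "
                f"scaffold length {len(assembly.scaffolds[self.scaffold])}"
            )


def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a multi-record FASTA into a :class:`GenomeAssembly`.

    Scaffold names are the first whitespace-delimited token of each header.
    Raises :class:`GenomeIOError` on missing/empty files or duplicate names.
    """
    path = Path(path)
    if not path.exists():
        raise GenomeIOError(f"FASTA file not found: {path}")
    assembly = GenomeAssembly()
    try:
        for record in SeqIO.parse(str(path), "fasta"):
            assembly.add(record.id, str(record.seq))
    except ValueError as exc:
        raise GenomeIOError(f"malformed FASTA in {path}: {exc}") from None
    if len(assembly) == 0:
        raise GenomeIOError(f"no FASTA records in {path}")
    return assembly


def write_fasta(assembly: GenomeAssembly, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in assembly.scaffolds.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a two-column (scaffold, length) tab-separated table."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise GenomeIOError(f"{path}:{lineno}: expected 2 columns")
            name, length = fields
            try:
                n = int(length)
            except ValueError:
                raise GenomeIOError(
                    f"{path}:{lineno}: non-integer length {length!r}"
                ) from None
            if n <= 0:
                raise GenomeIOError(f"{path}:{lineno}: non-positive length {n}")
            sizes[name] = n
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, n in sizes.items():
            fh.write(f"{name}\t{n}\n")


def read_bed(path: str | Path, assembly: GenomeAssembly | None = None) -> list[BedInterval]:
    """Read BED3+ intervals; validated against ``assembly`` when given."""
    intervals: list[BedInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GenomeIOError(f"{path}:{lineno}: expected >=3 columns")
            try:
                iv = BedInterval(
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[3] if len(fields) > 3 else None,
                )
            except (ValueError, GenomeIOError) as exc:
                raise GenomeIOError(f"{path}:{lineno}: {exc}") from None
            if assembly is not None:
                iv.validate(assembly)
            intervals.append(iv)
    return intervals


def write_bed(intervals: Iterable[BedInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.scaffold, str(iv.start), str(iv.end)]
            if iv.name is not None:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")
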