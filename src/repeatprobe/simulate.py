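"""Deterministic synthetic genomes with planted tandem-repeat arrays.

The generator emulates a satellite-like target: a random monomer (171 bp by
default, the alpha-satellite monomer length) is concatenated ``copies``
times, each copy independently mutated at a per-base substitution rate, and
the array is embedded in i.i.d. random background of configurable GC
content.  An optional decoy array with a stated identity to the first
monomer exercises off-target discrimination.  Ground-truth intervals
exactly delimit the planted arrays.  All randomness flows from the seed;
identical specs produce byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .genome import BedInterval, GenomeAssembly, write_chrom_sizes, write_fasta

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic genome.

    Defaults plant a 171-bp monomer in 30 copies with 2% per-copy
    divergence inside ~50 kb of 42% GC background.
    """

    monomer_length: int = 171
    copies: int = 30
    divergence: float = 0.02
    flank_length: int = 22_000
    gc_percent: float = 42.0
    decoy_identity: float | None = None
    decoy_copies: int | None = None
    seed: int = 0
    scaffold_name: str = "sim1"

    def __post_init__(self):
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must lie in [0, 1)")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.decoy_identity is not None and not 0.0 < self.decoy_identity <= 1.0:
            raise ValueError("decoy_identity must lie in (0, 1]")


def _random_background(rng: np.random.Generator, length: int, gc: float) -> str:
    p_gc = gc / 200.0
    p = [0.5 - p_gc, p_gc, p_gc, 0.5 - p_gc]  # A, C, G, T
    return "".join(rng.choice(BASES, size=length, p=p))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    mask = rng.random(len(arr)) < rate
    for i in np.flatnonzero(mask):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def _array_sequence(
    rng: np.random.Generator, monomer: str, copies: int, divergence: float
) -> str:
    return "".join(_mutate(rng, monomer, divergence) for _ in range(copies))


def generate(spec: FixtureSpec) -> tuple[GenomeAssembly, list[BedInterval], list[str]]:
    """Build the synthetic assembly, truth intervals, and monomer sequences."""
    rng = np.random.default_rng(spec.seed)
    monomer = _random_background(rng, spec.monomer_length, spec.gc_percent)
    monomers = [monomer]
    segments: list[str] = []
    truth: list[BedInterval] = []
    pos = 0

    flank = _random_background(rng, spec.flank_length, spec.gc_percent)
    segments.append(flank)
    pos += len(flank)

    array = _array_sequence(rng, monomer, spec.copies, spec.divergence)
    truth_start = pos
    segments.append(array)
    pos += len(array)

    if spec.decoy_identity is not None:
        decoy_monomer = _mutate(rng, monomer, 1.0 - spec.decoy_identity)
        monomers.append(decoy_monomer)
        spacer = _random_background(rng, spec.flank_length, spec.gc_percent)
        segments.append(spacer)
        pos += len(spacer)
        decoy = _array_sequence(
            rng, decoy_monomer, spec.decoy_copies or spec.copies, spec.divergence
        )
        decoy_start = pos
        segments.append(decoy)
        pos += len(decoy)

    segments.append(_random_background(rng, spec.flank_length, spec.gc_percent))

    assembly = GenomeAssembly()
    assembly.add(spec.scaffold_name, "".join(segments))
    truth.append(
        BedInterval(spec.scaffold_name, truth_start, truth_start + len(array),
                    name="array_1")
    )
    if spec.decoy_identity is not None:
        truth.append(
            BedInterval(spec.scaffold_name, decoy_start, decoy_start + len(decoy),
                        name="array_2")
        )
    return assembly, truth, monomers


def write_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + chrom.sizes + truth BED + spec record for a fixture."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    assembly, truth, monomers = generate(spec)
    paths = {
        "fasta": outdir / "genome.fa",
        "chrom_sizes": outdir / "genome.chrom.sizes",
        "truth_bed": outdir / "truth.bed",
        "spec": outdir / "fixture_spec.json",
    }
    write_fasta(assembly, paths["fasta"])
    write_chrom_sizes(assembly.lengths, paths["chrom_sizes"])
    with open(paths["truth_bed"], "w") as fh:
        for iv in truth:
            fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{iv.name}\n")
    record = asdict(spec) | {"monomers": monomers}
    paths["spec"].write_text(json.dumps(record, indent=2) + "\n")
    return paths
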