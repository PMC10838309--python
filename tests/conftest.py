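import random

import pytest

from repeatprobe.genome import GenomeAssembly
from repeatprobe.kmers import count_kmers
from repeatprobe.simulate import FixtureSpec, generate


def random_dna(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def fixture_genome():
    """Standard planted-array fixture: 171 bp x 30 copies in ~50 kb."""
    spec = FixtureSpec(seed=1)
    assembly, truth, monomers = generate(spec)
    return assembly, truth[0], monomers[0]


@pytest.fixture(scope="session")
def fixture_table(fixture_genome):
    assembly, _, _ = fixture_genome
    return count_kmers(assembly, 18)


@pytest.fixture()
def tiny_assembly():
    assembly = GenomeAssembly()
    assembly.add("s1", "ACGTACGTAC" * 10)
    assembly.add("s2", "TTTTTTTTTT")
    return assembly


def jaccard(a, b) -> float:
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    union = (a.end - a.start) + (b.end - b.start) - inter
    return inter / union if union else 0.0
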