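import random

import pytest

from repeatprobe.design import CandidateProbe
from repeatprobe.genome import BedInterval, GenomeAssembly
from repeatprobe.kmers import count_kmers
from repeatprobe.rank import (
    RankedProbe,
    mer_cutoff_filter,
    normalized_rank,
    probe_kmer_set,
    score_candidates,
)

from .conftest import random_dna


def make_candidate(seq, start=0, scaffold="s1"):
    target = BedInterval(scaffold, 0, max(len(seq), start + len(seq)))
    return CandidateProbe(scaffold, start, start + len(seq), seq, 45.0, 50.0, target)


def ranked(seq, r_m, h_m, start=0):
    return RankedProbe(make_candidate(seq, start), r_m=r_m, h_m=h_m, k_b=r_m / h_m)


class TestScoreCandidates:
    def test_target_unique_probe_has_kb_one(self):
        rng = random.Random(80)
        core = random_dna(rng, 200)
        asm = GenomeAssembly()
        asm.add("s1", core + "T" * 1000)
        table = count_kmers(asm, 18)
        target = BedInterval("s1", 0, 200)
        cand = make_candidate(core[50:90], start=50)
        (scored,) = score_candidates([cand], table, target, asm)
        assert scored.r_m == scored.h_m and scored.k_b == 1.0

    def test_half_enrichment(self):
        rng = random.Random(81)
        block = random_dna(rng, 40)
        asm = GenomeAssembly()
        asm.add("s1", block + "T" * 500 + block)
        table = count_kmers(asm, 18)
        target = BedInterval("s1", 0, 40)
        cand = make_candidate(block)
        (scored,) = score_candidates([cand], table, target, asm)
        assert scored.k_b == pytest.approx(0.5)

    def test_matches_counting_oracle_on_fixture(self, fixture_genome, fixture_table):
        assembly, truth, _ = fixture_genome
        seq = assembly.scaffolds[truth.scaffold]
        region_seq = seq[truth.start : truth.end]
        rng = random.Random(82)
        cands = []
        for _ in range(10):
            start = rng.randrange(truth.start, truth.end - 40)
            cands.append(make_candidate(seq[start : start + 40], start=start))
        for scored in score_candidates(cands, fixture_table, truth, assembly):
            probe = scored.sequence
            kmers = [probe[i : i + 18] for i in range(len(probe) - 17)]

            def naive(hay, needle):
                return sum(
                    1 for i in range(len(hay) - len(needle) + 1)
                    if hay[i : i + len(needle)] == needle
                )

            assert scored.h_m == sum(naive(seq, km) for km in kmers)
            assert scored.r_m == sum(naive(region_seq, km) for km in kmers)


class TestNormalizedRank:
    def test_single_probe_scores_own_maxima(self):
        (out,) = normalized_rank([ranked("A" * 40, 10, 20)], c1=2.0, c2=4.0)
        assert out.nr == pytest.approx(1 / 2 + 1 / 4)

    def test_two_probe_ordering_and_values(self):
        a = ranked("A" * 30, 10, 20, start=0)
        b = ranked("C" * 30, 5, 10, start=100)
        out = normalized_rank([b, a], c1=1.0, c2=1.0)
        assert [p.r_m for p in out] == [10, 5]
        assert out[0].nr == pytest.approx(2.0)
        assert out[1].nr == pytest.approx(1.5)

    def test_ordering_matches_formula_oracle(self):
        rng = random.Random(83)
        probes = [
            ranked(random_dna(rng, 30), rng.randrange(1, 100), 100, start=i * 40)
            for i in range(50)
        ]
        out = normalized_rank(probes, c1=1.3, c2=0.7)
        max_rm = max(p.r_m for p in probes)
        max_kb = max(p.k_b for p in probes)
        oracle = sorted(
            probes,
            key=lambda p: (
                -(p.r_m / (max_rm * 1.3) + p.k_b / (max_kb * 0.7)),
                p.candidate.start,
                p.sequence,
            ),
        )
        assert [p.sequence for p in out] == [p.sequence for p in oracle]

    def test_scale_free_in_rm(self):
        rng = random.Random(84)
        probes = [
            ranked(random_dna(rng, 30), rng.randrange(1, 50), 60, start=i * 40)
            for i in range(20)
        ]
        scaled = [
            RankedProbe(p.candidate, p.r_m * 7, p.h_m * 7, p.k_b) for p in probes
        ]
        a = [p.sequence for p in normalized_rank(probes)]
        b = [p.sequence for p in normalized_rank(scaled)]
        assert a == b

    def test_invalid_constants(self):
        with pytest.raises(ValueError):
            normalized_rank([ranked("A" * 30, 1, 1)], c1=0.0)


class TestMerCutoffFilter:
    def test_duplicate_of_accepted_probe_is_rejected(self):
        rng = random.Random(85)
        seq = random_dna(rng, 40)
        probes = [ranked(seq, 10, 10), ranked(seq, 10, 10, start=200)]
        assert len(mer_cutoff_filter(probes, 0.99, 18)) == 1

    def test_cutoff_of_one_rejects_nothing(self):
        rng = random.Random(86)
        probes = [ranked(random_dna(rng, 40), 5, 10, start=i * 50) for i in range(10)]
        probes += [probes[0]]
        assert mer_cutoff_filter(probes, 1.0, 18) == probes

    def test_survivors_are_an_order_preserving_subsequence(self):
        rng = random.Random(87)
        monomer = random_dna(rng, 60)
        probes = []
        for i in range(30):
            mutated = list(monomer[:40])
            for j in rng.sample(range(40), rng.randrange(0, 4)):
                mutated[j] = rng.choice("ACGT")
            probes.append(ranked("".join(mutated), 10, 20, start=i * 45))
        survivors = mer_cutoff_filter(probes, 0.5, 18)
        it = iter(probes)
        assert all(s in it for s in survivors)  # subsequence check

    def test_running_union_overlap_verified_by_set_oracle(self):
        rng = random.Random(88)
        probes = [ranked(random_dna(rng, 35), 8, 16, start=i * 40) for i in range(40)]
        cutoff = 0.3
        survivors = mer_cutoff_filter(probes, cutoff, 12)
        pool = set()
        expected = []
        for p in probes:
            kmers = probe_kmer_set(p.sequence, 12)
            if len(kmers & pool) / len(kmers) > cutoff:
                continue
            expected.append(p)
            pool |= kmers
        assert survivors == expected

    def test_lower_cutoff_never_increases_survivors(self):
        rng = random.Random(89)
        monomer = random_dna(rng, 80)
        probes = []
        for i in range(25):
            mutated = list(monomer[i % 30 : (i % 30) + 40])
            for j in rng.sample(range(len(mutated)), 2):
                mutated[j] = rng.choice("ACGT")
            probes.append(ranked("".join(mutated), 5, 10, start=i * 45))
        counts = [
            len(mer_cutoff_filter(probes, cutoff, 14))
            for cutoff in (1.0, 0.8, 0.5, 0.2, 0.0)
        ]
        assert counts == sorted(counts, reverse=True)
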