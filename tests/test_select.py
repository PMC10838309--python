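import random

import pytest

from repeatprobe.design import CandidateProbe
from repeatprobe.genome import BedInterval, GenomeAssembly
from repeatprobe.rank import RankedProbe
from repeatprobe.select import (
    SelectionCriteria,
    probe_pair_pdups,
    select_probes,
)
from repeatprobe.simulate import FixtureSpec, generate
from repeatprobe.specificity import make_windows
from repeatprobe.thermo import ThermoModel

from .conftest import random_dna


def as_ranked(assembly, scaffold, start, length, target):
    seq = assembly.slice(scaffold, start, start + length)
    cand = CandidateProbe(scaffold, start, start + length, seq, 45.0, 50.0, target)
    return RankedProbe(cand, r_m=1, h_m=1, k_b=1.0, nr=1.0)


@pytest.fixture(scope="module")
def tandem_setup():
    rng = random.Random(90)
    monomer = random_dna(rng, 100)
    left, right = random_dna(rng, 5000), random_dna(rng, 5000)
    assembly = GenomeAssembly()
    assembly.add("s1", left + monomer * 15 + right)
    target = BedInterval("s1", 5000, 5000 + 1500)
    bins = make_windows(assembly.lengths, 1000)
    return assembly, target, bins


class TestSelectProbes:
    def test_single_probe_meets_target_sum(self, tandem_setup):
        assembly, target, bins = tandem_setup
        ranked = [as_ranked(assembly, "s1", 5010, 40, target),
                  as_ranked(assembly, "s1", 5060, 40, target)]
        criteria = SelectionCriteria(target_sum=10.0, min_on_target=1.0)
        result = select_probes(ranked, assembly, target, criteria,
                               ThermoModel(), bins)
        assert len(result.accepted) == 1
        assert result.termination_reason == "target_sum_met"
        assert result.aggregate_on_t >= 10.0

    def test_duplicate_of_accepted_probe_is_rejected(self, tandem_setup):
        assembly, target, bins = tandem_setup
        probe = as_ranked(assembly, "s1", 5010, 40, target)
        criteria = SelectionCriteria(
            target_sum=1e9, min_on_target=1.0, max_pdups_binding=0.9,
            max_probe_return=10,
        )
        result = select_probes([probe, probe], assembly, target, criteria,
                               ThermoModel(), bins)
        assert len(result.accepted) == 1
        assert ("s1:5010-5050", "reject:max_pdups_binding") in result.decisions

    def test_rerun_is_bit_identical(self, tandem_setup):
        assembly, target, bins = tandem_setup
        ranked = [as_ranked(assembly, "s1", 5010 + i * 110, 40, target)
                  for i in range(4)]
        criteria = SelectionCriteria(target_sum=1e9, min_on_target=1.0,
                                     max_probe_return=4)
        a = select_probes(ranked, assembly, target, criteria, ThermoModel(), bins)
        b = select_probes(ranked, assembly, target, criteria, ThermoModel(), bins)
        assert a.decisions == b.decisions
        assert [(p.sequence, prof.on_t) for p, prof in a.accepted] == [
            (p.sequence, prof.on_t) for p, prof in b.accepted
        ]

    def test_empty_outcome_when_no_candidate_qualifies(self, tandem_setup):
        assembly, target, bins = tandem_setup
        ranked = [as_ranked(assembly, "s1", 100, 40, target)]  # off-target probe
        criteria = SelectionCriteria(min_binding_prop=0.99, min_on_target=0.5)
        result = select_probes(ranked, assembly, target, criteria,
                               ThermoModel(), bins)
        assert result.accepted == [] and result.termination_reason == "exhausted"

    def test_relaxing_filter_criteria_never_shrinks_accepted_set(self):
        """With a decoy array sharing 80% identity, the stricter binding
        proportion floor accepts a subset of what the relaxed floor accepts."""
        spec = FixtureSpec(copies=12, flank_length=4000, decoy_identity=0.8,
                           decoy_copies=12, seed=5)
        assembly, truth, _ = generate(spec)
        target = truth[0]
        bins = make_windows(assembly.lengths, 1000)
        rng = random.Random(91)
        ranked = [
            as_ranked(assembly, target.scaffold,
                      rng.randrange(target.start, target.end - 40), 40, target)
            for _ in range(8)
        ]
        base = dict(target_sum=1e9, min_on_target=1.0, max_probe_return=8,
                    max_pdups_binding=1.0, off_bin_thresh=1e9)
        strict = select_probes(
            ranked, assembly, target,
            SelectionCriteria(min_binding_prop=0.95, **base),
            ThermoModel(), bins,
        )
        relaxed = select_probes(
            ranked, assembly, target,
            SelectionCriteria(min_binding_prop=0.5, **base),
            ThermoModel(), bins,
        )
        strict_seqs = {p.sequence for p, _ in strict.accepted}
        relaxed_seqs = {p.sequence for p, _ in relaxed.accepted}
        assert strict_seqs <= relaxed_seqs

    def test_accepted_probes_respect_binding_floor_on_decoy_fixture(self):
        spec = FixtureSpec(copies=12, flank_length=4000, decoy_identity=0.8,
                           decoy_copies=12, seed=6)
        assembly, truth, _ = generate(spec)
        target = truth[0]
        bins = make_windows(assembly.lengths, 1000)
        rng = random.Random(92)
        ranked = [
            as_ranked(assembly, target.scaffold,
                      rng.randrange(target.start, target.end - 40), 40, target)
            for _ in range(6)
        ]
        criteria = SelectionCriteria(target_sum=1e9, min_on_target=1.0,
                                     min_binding_prop=0.7, max_probe_return=6,
                                     max_pdups_binding=1.0, off_bin_thresh=1e9)
        result = select_probes(ranked, assembly, target, criteria,
                               ThermoModel(), bins)
        for _, prof in result.accepted:
            # flat re-summation oracle on the recorded bin aggregates
            assert prof.binding_prop >= 0.7
            total = sum(prof.bin_aggregates.values())
            assert prof.on_t + prof.off_t == pytest.approx(total, abs=1e-9)


class TestProbePairPdups:
    def test_self_pairing_is_maximal(self):
        rng = random.Random(93)
        seq = random_dna(rng, 40)
        other = random_dna(rng, 40)
        model = ThermoModel()
        self_p = probe_pair_pdups(seq, seq, model)
        assert self_p > 0.9
        assert probe_pair_pdups(seq, other, model) < self_p

    def test_unrelated_probes_do_not_pair(self):
        rng = random.Random(94)
        model = ThermoModel()
        assert probe_pair_pdups(random_dna(rng, 40), random_dna(rng, 40), model) < 0.5
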