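"""Generators: chimeric loci, repeat arrays, consensus calling, fingerprints."""

import numpy as np
import pytest

from ambiscan import (
    AmbiguousSequence,
    ChimeraModel,
    PeakCallModel,
    RepeatArrayModel,
    call_consensus,
    detect_blocks,
    distinct_patterns,
    enumerate_haplotypes,
    evolve_repeat_array,
    haplotype_in_space,
    min_allele_count,
    pul4_like,
    scan_alignment,
    scan_sequence,
    simulate_chimera,
    simulate_fingerprints,
    substitution_type,
)


class TestSimulateChimera:
    def test_zero_divergence_identical_alleles(self):
        result = simulate_chimera(ChimeraModel(allele_divergence=0.0, seed=1), 100)
        assert result.allele_strings[0] == result.allele_strings[1]
        assert result.planted == []

    def test_exact_hamming_distance_two_alleles(self):
        for k in (1, 7, 25):
            result = simulate_chimera(ChimeraModel(seed=k), 200, n_sites=k)
            a, b = result.allele_strings
            assert sum(x != y for x, y in zip(a, b)) == k

    def test_transition_bias_one_plants_only_transitions(self):
        result = simulate_chimera(
            ChimeraModel(transition_bias=1.0, seed=9), 300, n_sites=40
        )
        for site in result.planted:
            assert substitution_type({site.reference, site.alternative}) == "transition"

    def test_block_confinement(self):
        blocks = [(20, 40), (110, 130)]
        result = simulate_chimera(
            ChimeraModel(block_spec=blocks, seed=3), 200, n_sites=25
        )
        for site in result.planted:
            assert any(lo <= site.position <= hi for lo, hi in blocks)

    def test_infeasible_block_spec_rejected(self):
        with pytest.raises(ValueError):
            simulate_chimera(ChimeraModel(block_spec=[(10, 12)], seed=0), 100, n_sites=10)

    def test_seed_reproducibility(self):
        a = simulate_chimera(ChimeraModel(seed=77), 150, n_sites=12)
        b = simulate_chimera(ChimeraModel(seed=77), 150, n_sites=12)
        assert a.allele_strings == b.allele_strings and a.planted == b.planted


class TestEvolveRepeatArray:
    def test_zero_generations_unchanged(self):
        ancestors = ["ACGTACGT", "ACGTACGA"]
        model = RepeatArrayModel(generations=0, seed=5)
        assert evolve_repeat_array(model, ancestors) == ancestors

    def test_zero_mutation_keeps_ancestral_set(self):
        ancestors = ["ACGTACGT", "TTTTACGA"]
        model = RepeatArrayModel(
            mutation_rate=0.0, homogenisation_rate=0.5, regime="homogenise",
            generations=50, seed=8,
        )
        final = evolve_repeat_array(model, ancestors)
        assert set(final) <= set(ancestors)

    def test_high_conversion_fixes_the_array(self):
        """Gene conversion without mutation drives diversity to zero."""
        ancestors = ["ACGTACGTAC", "GTACGTACGT"]
        fixed = 0
        for seed in range(100):
            model = RepeatArrayModel(
                mutation_rate=0.0, duplication_rate=0.0, deletion_rate=0.0,
                homogenisation_rate=0.9, regime="homogenise",
                generations=60, seed=seed,
            )
            final = evolve_repeat_array(model, ancestors)
            if len(set(final)) == 1:
                fixed += 1
        assert fixed >= 95  # fixation is near-certain after 60 conversion rounds

    def test_floor_of_one_repeat(self):
        model = RepeatArrayModel(
            mutation_rate=0.0, duplication_rate=0.0, deletion_rate=1.0,
            generations=10, seed=2,
        )
        assert len(evolve_repeat_array(model, ["ACGT"])) == 1


class TestCallConsensus:
    def test_equal_weights_show_ambiguity(self):
        cons, flags = call_consensus(["ACGT", "ACGA"], PeakCallModel(minor_call_threshold=0.3))
        assert cons.residues == "ACGW"
        assert flags == [False, False, False, False]

    def test_minor_peak_suppressed_and_flagged(self):
        cons, flags = call_consensus(
            ["ACGT", "ACGA"], PeakCallModel(allele_weights=(0.9, 0.1), minor_call_threshold=0.3)
        )
        assert cons.residues == "ACGT"
        assert flags == [False, False, False, True]

    def test_single_repeat_identity(self):
        cons, flags = call_consensus(["ACGT"])
        assert cons.residues == "ACGT" and not any(flags)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            call_consensus(["ACGT", "ACG"])

    def test_three_way_site_gets_snt_code(self):
        cons, _ = call_consensus(["AAAA", "CAAA", "GAAA"])
        assert cons.residues[0] == "V"  # {A,C,G}


class TestSimulateFingerprints:
    def test_flip_zero_recovers_groups(self):
        m, labels = simulate_fingerprints(12, 24, 4, 0.0, seed=6)
        out = distinct_patterns(m)
        assert out.n_patterns == 4
        # strains with equal labels have identical rows
        by_class = {frozenset(c) for c in out.classes}
        truth = {
            frozenset(m.strain_ids[i] for i in range(12) if labels[i] == g)
            for g in range(4)
        }
        assert by_class == truth

    def test_all_groups_distinct_prototypes(self):
        m, _ = simulate_fingerprints(6, 30, 6, 0.0, seed=13)
        assert distinct_patterns(m).n_patterns == 6

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_fingerprints(5, 0, 2)
        with pytest.raises(ValueError):
            simulate_fingerprints(3, 10, 4)
        with pytest.raises(ValueError):
            simulate_fingerprints(5, 10, 2, within_group_flip_prob=0.5)


class TestEndToEnd:
    def test_two_allele_recovery_small(self):
        """Planted dimorphisms come back as SNDs; both alleles sit in the
        haplotype space; the allele-count bound is exactly two."""
        for seed, k in [(1, 3), (2, 8), (3, 15)]:
            result = simulate_chimera(ChimeraModel(seed=seed), 120, n_sites=k)
            cons, _ = call_consensus(result.allele_strings)
            _, census = scan_sequence(cons)
            assert census.n_SND == k and census.n_SNT == 0 and census.n_SNP == 0
            assert min_allele_count(cons) == 2
            for allele in result.allele_strings:
                assert haplotype_in_space(cons, allele)
            space = enumerate_haplotypes(cons)
            for allele in result.allele_strings:
                assert allele in space.haplotypes

    def test_planted_block_recovery(self):
        blocks = [(30, 45), (140, 160)]
        result = simulate_chimera(
            ChimeraModel(block_spec=blocks, seed=21), 250, n_sites=16
        )
        cons, _ = call_consensus(result.allele_strings)
        records, _ = scan_sequence(cons)
        found = detect_blocks(records, max_gap=20, min_block_sites=2)
        covered = set()
        for b in found:
            assert any(lo <= b.start and b.end <= hi for lo, hi in blocks)
            covered.update(range(b.start, b.end + 1))
        assert {s.position for s in result.planted} <= covered


class TestPul4Like:
    def test_union_census_matches_planted_truth(self, pul4_fixture):
        records, census = scan_alignment(list(pul4_fixture.consensus.values()))
        assert census.n_variable == len(pul4_fixture.union_positions)
        assert [r.position for r in records] == pul4_fixture.union_positions
        assert census.n_SNT == 0 and census.n_SNP == 0

    def test_every_strain_is_dimorphic_with_two_alleles(self, pul4_fixture):
        for sid, cons in pul4_fixture.consensus.items():
            assert min_allele_count(cons) == 2
            a, b = pul4_fixture.alleles[sid]
            assert haplotype_in_space(cons, a) and haplotype_in_space(cons, b)

    def test_transitions_dominate(self, pul4_fixture):
        _, census = scan_alignment(list(pul4_fixture.consensus.values()))
        assert census.n_transitions > census.n_transversions

    def test_byte_identical_for_same_seed(self):
        a = pul4_like(seed=99, n_strains=5, n_union_sites=12)
        b = pul4_like(seed=99, n_strains=5, n_union_sites=12)
        assert {k: v.residues for k, v in a.consensus.items()} == {
            k: v.residues for k, v in b.consensus.items()
        }
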