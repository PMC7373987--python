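"""Positional entropy: closed forms, mixtures, simulation-oracle agreement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phaseq import (
    NucleotideFrequencyMatrix,
    PhiXModel,
    analytic_freq_matrix,
    condition_components,
    entropy_profile,
    filter_window_summary,
    freq_matrix_from_reads,
    mix_with_phix,
    shannon_entropy,
    simulate_run,
)


def brute_entropy(p):
    return -sum(x * math.log2(x) for x in p if x > 0)


class TestShannonEntropy:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((0.25, 0.25, 0.25, 0.25), 2.0),
            ((1, 0, 0, 0), 0.0),
            ((0.5, 0.5, 0, 0), 1.0),
            # 75% fixed base / 25% uniform mixture row
            ((0.8125, 0.0625, 0.0625, 0.0625), brute_entropy((0.8125,) + (0.0625,) * 3)),
        ],
    )
    def test_known_values(self, p, expected):
        assert shannon_entropy(p) == pytest.approx(expected, abs=1e-9)

    def test_mixture_row_value_matches_printed_precision(self):
        assert shannon_entropy((0.8125, 0.0625, 0.0625, 0.0625)) == pytest.approx(
            0.9934, abs=5e-5
        )

    def test_rejects_negative_and_unnormalized(self):
        with pytest.raises(ValueError):
            shannon_entropy((-0.1, 0.5, 0.3, 0.3))
        with pytest.raises(ValueError):
            shannon_entropy((0.5, 0.5, 0.5, 0.5))

    @given(
        st.lists(st.floats(0.001, 1.0), min_size=4, max_size=4).map(
            lambda v: tuple(x / sum(v) for x in v)
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_bounds_and_brute_force_agreement(self, p):
        h = shannon_entropy(p)
        assert 0.0 <= h <= 2.0 + 1e-12
        assert h == pytest.approx(brute_entropy(p), abs=1e-9)


class TestFreqMatrix:
    def test_uniform_reads_give_uniform_rows(self):
        m = freq_matrix_from_reads(["AA", "CC", "GG", "TT"])
        assert np.allclose(m.probs, 0.25)

    def test_single_read_gives_unit_rows(self):
        m = freq_matrix_from_reads(["ACGT"])
        assert np.allclose(m.probs.max(axis=1), 1.0)

    def test_ragged_reads_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            freq_matrix_from_reads(["ACGT", "ACG"])

    def test_ambiguous_bases_excluded_with_renormalization(self):
        m = freq_matrix_from_reads(["AN", "AN", "AC"])
        assert m.probs[1] == pytest.approx([0, 1, 0, 0])  # only the C counts

    def test_rows_must_sum_to_one(self):
        with pytest.raises(ValueError):
            NucleotideFrequencyMatrix(np.full((2, 4), 0.3))


class TestAnalyticFreqMatrix:
    def test_single_concrete_component_is_indicator_matrix(self):
        m = analytic_freq_matrix([("ACGT", 1.0)], 4)
        assert np.allclose(np.sort(m.probs, axis=1)[:, -1], 1.0)

    def test_all_n_component_is_uniform(self):
        m = analytic_freq_matrix([("N" * 10, 1.0)], 10)
        assert np.allclose(m.probs, 0.25)

    def test_simulation_converges_to_analytic(self, template, inserts, layout):
        comps = condition_components(template, inserts, layout)
        analytic = analytic_freq_matrix(comps, 150)
        reads = simulate_run(template, inserts, layout, None, 0.0, 200_000, seed=9)
        sim = freq_matrix_from_reads(reads)
        ha = entropy_profile(analytic).h
        hs = entropy_profile(sim).h
        assert np.abs(ha - hs).max() < 0.01


class TestMixWithPhix:
    def test_linear_mixture_of_constant_row(self):
        m = NucleotideFrequencyMatrix(np.array([[1.0, 0, 0, 0]]))
        mixed = mix_with_phix(m, PhiXModel(0.25))
        assert mixed.probs[0] == pytest.approx([0.8125, 0.0625, 0.0625, 0.0625])

    def test_zero_fraction_is_identity_and_one_is_uniform(self):
        m = NucleotideFrequencyMatrix(np.array([[1.0, 0, 0, 0]]))
        assert np.allclose(mix_with_phix(m, PhiXModel(0.0)).probs, m.probs)
        full = mix_with_phix(m, PhiXModel(1.0))
        assert entropy_profile(full).mean == pytest.approx(2.0)

    def test_fraction_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            PhiXModel(1.5)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_entropy_nondecreasing_in_fraction_for_constant_row(self, f1, f2):
        lo, hi = sorted((f1, f2))
        m = NucleotideFrequencyMatrix(np.array([[0, 0, 1.0, 0]]))
        h_lo = entropy_profile(mix_with_phix(m, PhiXModel(lo))).mean
        h_hi = entropy_profile(mix_with_phix(m, PhiXModel(hi))).mean
        assert h_hi >= h_lo - 1e-12

    def test_genome_mode_uses_genome_composition(self):
        m = NucleotideFrequencyMatrix(np.full((2, 4), 0.25))
        mixed = mix_with_phix(m, PhiXModel(1.0, mode="genome", genome="AACC"))
        # windows of length 2 over AACC: positions sample the genome, not uniform
        assert not np.allclose(mixed.probs, 0.25)
        assert np.allclose(mixed.probs.sum(axis=1), 1.0)


class TestEntropyProfile:
    def test_control_library_mean_and_sd(self, template, layout):
        # 150 cycles, 6 uniform-random positions, the rest fixed
        m = analytic_freq_matrix(condition_components(template, None, layout), 150)
        prof = entropy_profile(m)
        assert prof.mean == pytest.approx(6 * 2 / 150, abs=1e-12)
        assert prof.sd == pytest.approx(0.39, abs=0.005)

    def test_phix_only_mean_and_sd(self, template, layout):
        m = analytic_freq_matrix(condition_components(template, None, layout), 150)
        prof = entropy_profile(mix_with_phix(m, PhiXModel(0.25)))
        assert prof.mean == pytest.approx(1.03, abs=0.005)
        assert prof.sd == pytest.approx(0.20, abs=0.005)

    def test_uniform_matrix_is_two_bits_everywhere(self):
        prof = entropy_profile(NucleotideFrequencyMatrix(np.full((150, 4), 0.25)))
        assert prof.mean == 2.0
        assert prof.sd == 0.0


class TestSimulateRun:
    def test_identical_seeds_are_byte_identical(self, template, inserts, layout):
        a = simulate_run(template, inserts, layout, PhiXModel(0.1), 0.2, 500, seed=3)
        b = simulate_run(template, inserts, layout, PhiXModel(0.1), 0.2, 500, seed=3)
        assert np.array_equal(a.codes, b.codes)
        assert a.to_strings() == b.to_strings()

    def test_different_seeds_differ(self, template, inserts, layout):
        a = simulate_run(template, inserts, layout, None, 0.0, 500, seed=3)
        b = simulate_run(template, inserts, layout, None, 0.0, 500, seed=4)
        assert not np.array_equal(a.codes, b.codes)

    def test_seed_is_mandatory(self, template, inserts, layout):
        with pytest.raises(ValueError, match="seed"):
            simulate_run(template, inserts, layout, None, 0.0, 10, seed=None)

    def test_zero_cleaved_fraction_reads_carry_full_transcript(self, template, inserts, layout):
        reads = simulate_run(template, inserts, layout, None, 0.0, 50, seed=1)
        leader = template.leader
        for s in reads.to_strings():
            prefixes = [
                ins + inserts.anchor
                for ins in inserts.inserts
                if s.startswith(ins + inserts.anchor)
            ]
            assert len(prefixes) == 1  # every read demultiplexes uniquely
            assert s[len(prefixes[0]):].startswith(leader)  # leader present


class TestFilterWindow:
    def test_balanced_inserts_max_out_first_nine_cycles(self, template, inserts, layout):
        m = analytic_freq_matrix(condition_components(template, inserts, layout), 150)
        s = filter_window_summary(entropy_profile(m), window=9)
        assert s.min == pytest.approx(2.0, abs=1e-9)
        assert s.mean == pytest.approx(2.0, abs=1e-9)

    def test_control_has_zero_entropy_cycles_in_window(self, template, layout):
        m = analytic_freq_matrix(condition_components(template, None, layout), 150)
        s = filter_window_summary(entropy_profile(m), window=25)
        assert s.min == pytest.approx(0.0, abs=1e-12)
        assert len(s.flagged_cycles) > 0

    def test_zero_threshold_flags_nothing(self, template, layout):
        m = analytic_freq_matrix(condition_components(template, None, layout), 150)
        s = filter_window_summary(entropy_profile(m), window=25, threshold=0.0)
        assert s.flagged_cycles == ()
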