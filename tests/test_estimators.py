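"""Mutation-frequency, independent-event, and rescue statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sefscreen import (
    AlleleSignature,
    F1_CLONAL_SCREEN,
    F2_SELECTION,
    GeneticsError,
    RescueAssay,
    ScreenCounts,
    ScreenDesign,
    count_independent_events,
    effective_genomes,
    estimate_f_combined,
    estimate_f_independent,
    rescue_ratio,
    rescue_significance,
    transmission_rate,
)


class TestEffectiveGenomes:
    def test_clonal_screen_counts_two_genomes_per_f1(self):
        assert effective_genomes(ScreenDesign(F1_CLONAL_SCREEN, F1=5128)) == 10_256

    def test_selection_recessive_is_half_f2(self):
        design = ScreenDesign(F2_SELECTION, F1=1, F2=68_000)
        assert effective_genomes(design, "recessive") == 34_000

    def test_selection_dominant_is_three_halves_f2(self):
        design = ScreenDesign(F2_SELECTION, F1=1, F2=1000)
        assert effective_genomes(design, "dominant") == 1500


class TestFrequencyEstimates:
    def test_zero_isolates_gives_zero_estimate_with_interval(self):
        est = estimate_f_combined(0, 5128, 8000)
        assert est.f_hat == 0.0
        assert est.ci_low == 0.0 and est.ci_high > 0.0

    @pytest.mark.parametrize("n,F1,F2,expected", [
        (4, 5128, 8000, 4 / 14_256),
        (2, 0, 16, 0.25),
    ])
    def test_combined_estimator_arithmetic(self, n, F1, F2, expected):
        est = estimate_f_combined(n, F1, F2)
        assert est.f_hat == pytest.approx(expected)
        assert est.ci_low <= est.f_hat <= est.ci_high

    @pytest.mark.parametrize("n_i,G,expected", [
        (2, 10_256, 2 / 10_256),     # ~1.95e-4
        (0, 10_256, 0.0),
        (4, 27_256, 4 / 27_256),     # ~1.468e-4, combined-design exposure
    ])
    def test_independent_estimator_arithmetic(self, n_i, G, expected):
        assert estimate_f_independent(n_i, G).f_hat == pytest.approx(expected)

    def test_poisson_interval_covers_the_count(self):
        # Garwood interval: P(X >= n | G*ci_low) = alpha/2 at the boundary
        est = estimate_f_independent(4, 10_000)
        from scipy import stats
        assert stats.poisson.sf(3, est.ci_low * est.G) == pytest.approx(0.025, abs=1e-9)
        assert stats.poisson.cdf(4, est.ci_high * est.G) == pytest.approx(0.025, abs=1e-9)

    def test_zero_exposure_rejected(self):
        with pytest.raises(GeneticsError):
            estimate_f_combined(1, 0, 0)
        with pytest.raises(GeneticsError):
            estimate_f_independent(1, 0.0)

    def test_screen_counts_invariants(self):
        with pytest.raises(GeneticsError):
            ScreenCounts(n=2, n_i=3)


class TestIndependentEvents:
    def test_five_isolates_with_one_shared_signature_make_four_events(self):
        sigs = [
            AlleleSignature("cfi-1(a)", frozenset({"v1", "v2"})),
            AlleleSignature("cfi-1(b)", frozenset({"v1", "v2"})),  # re-isolation
            AlleleSignature("cfi-1(c)", frozenset({"v3"})),
            AlleleSignature("cfi-1(d)", frozenset({"v4", "v5"})),
            AlleleSignature("cfi-1(e)", frozenset({"v6"})),
        ]
        assert count_independent_events(sigs) == 4

    def test_three_isolates_two_sharing_make_two_events(self):
        sigs = [
            AlleleSignature("dod-6(a)", frozenset({"w1"})),
            AlleleSignature("dod-6(b)", frozenset({"w1"})),
            AlleleSignature("dod-6(c)", frozenset({"w2", "w3"})),
        ]
        assert count_independent_events(sigs) == 2

    def test_all_distinct_signatures_count_isolates(self):
        sigs = [AlleleSignature(f"i{k}", frozenset({f"v{k}"})) for k in range(6)]
        assert count_independent_events(sigs) == 6

    def test_empty_inputs_rejected(self):
        with pytest.raises(GeneticsError):
            count_independent_events([])
        with pytest.raises(GeneticsError):
            AlleleSignature("x", frozenset())

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.sets(st.sampled_from("abcdef"), min_size=1), min_size=1, max_size=8),
           st.randoms(use_true_random=False))
    def test_permutation_invariant_and_idempotent(self, raw, shuffler):
        sigs = [AlleleSignature(f"i{k}", frozenset(s)) for k, s in enumerate(raw)]
        shuffled = list(sigs)
        shuffler.shuffle(shuffled)
        assert count_independent_events(sigs) == count_independent_events(shuffled)
        assert count_independent_events(sigs) <= len(sigs)


class TestTransmissionRate:
    @pytest.mark.parametrize("k,N,t,se", [
        (50, 100, 0.5, 0.05),
        (30, 60, 0.5, math.sqrt(0.25 / 60)),
        (0, 100, 0.0, 0.0),
    ])
    def test_binomial_point_and_se(self, k, N, t, se):
        t_hat, se_hat = transmission_rate(k, N)
        assert t_hat == pytest.approx(t)
        assert se_hat == pytest.approx(se)

    def test_zero_total_rejected(self):
        with pytest.raises(GeneticsError):
            transmission_rate(0, 0)


class TestRescueRatio:
    def test_equal_fractions_give_unit_ratio(self):
        est = rescue_ratio(RescueAssay(N_D=80, k_D=20, N_H=120, k_H=30))
        assert est.r == pytest.approx(1.0)

    def test_worked_example_quarter_vs_half(self):
        est = rescue_ratio(RescueAssay(N_D=100, k_D=25, N_H=100, k_H=50))
        assert est.r == pytest.approx(1 / 3)
        expected_sem = (1 / 3) * math.sqrt(1 / (100 * 0.1875) + 1 / (100 * 0.25))
        assert est.sem_r == pytest.approx(expected_sem)
        assert est.sem_r == pytest.approx(0.1018, abs=2e-4)

    def test_reciprocal_orientation_inverts(self):
        assay = RescueAssay(N_D=100, k_D=25, N_H=100, k_H=50)
        assert rescue_ratio(assay, orientation="reciprocal").r == pytest.approx(3.0)

    def test_boundary_fraction_refused_unless_corrected(self):
        assay = RescueAssay(N_D=50, k_D=0, N_H=100, k_H=50)
        with pytest.raises(GeneticsError, match="continuity"):
            rescue_ratio(assay)
        est = rescue_ratio(assay, continuity_correction=True)
        assert 0 < est.r < 1

    def test_rescue_direction_gives_r_below_one(self):
        # transgenic animals depleted among escapers on restrictive food
        est = rescue_ratio(RescueAssay(N_D=200, k_D=20, N_H=200, k_H=100))
        assert est.r < 1


class TestRescueSignificance:
    def test_identical_fractions_give_zero_statistic(self):
        chi2, p, p_adj = rescue_significance(RescueAssay(N_D=100, k_D=30, N_H=100, k_H=30))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_pearson_statistic(self):
        # (10/90 vs 50/50): expected 30/70 per row, chi2 = 2*(400/30 + 400/70)
        chi2, p, _ = rescue_significance(RescueAssay(N_D=100, k_D=10, N_H=100, k_H=50))
        assert chi2 == pytest.approx(2 * (400 / 30 + 400 / 70))
        assert chi2 == pytest.approx(38.1, abs=0.05)
        assert p < 1e-9

    def test_bonferroni_multiplies_and_caps(self):
        _, p_raw, p_adj = rescue_significance(
            RescueAssay(N_D=100, k_D=35, N_H=100, k_H=50, m=8))
        assert p_adj == pytest.approx(min(1.0, 8 * p_raw))

    def test_zero_margin_rejected(self):
        with pytest.raises(GeneticsError):
            rescue_significance(RescueAssay(N_D=50, k_D=0, N_H=50, k_H=0))
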