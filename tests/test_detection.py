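"""Binned detection-function fitting, selection, ESW and goodness of fit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import erf

from nestdensity.detection import (
    BinnedDistances,
    SelectionError,
    bin_distances,
    binned_log_likelihood,
    detection_probability,
    effective_strip_width,
    fit_detection,
    fit_six_models,
    gof_chisquare,
    select_best_model,
)


class TestBinning:
    def test_hand_binned_fixture(self):
        b = bin_distances([0.5, 3.9, 4.0, 39.9, 41.2])
        assert b.counts[0] == 2  # [0, 4): 0.5, 3.9
        assert b.counts[1] == 1  # [4, 8): 4.0
        assert b.counts[9] == 1  # [36, 40): 39.9
        assert b.n_discarded == 1

    def test_empty_input_all_zero(self):
        b = bin_distances([])
        assert b.total == 0 and b.n_discarded == 0

    def test_default_settings_give_ten_bins(self):
        assert bin_distances([1.0]).n_bins == 10

    def test_boundary_distance_discarded(self):
        assert bin_distances([40.0]).n_discarded == 1

    def test_nonpositive_bin_width_rejected(self):
        with pytest.raises(ValueError):
            bin_distances([1.0], bin_width_m=0)

    @given(st.lists(st.floats(0, 80), max_size=60))
    @settings(max_examples=50, deadline=None)
    def test_counts_plus_discarded_conserve_input(self, xs):
        b = bin_distances(xs)
        assert b.total + b.n_discarded == len(xs)


class TestDetectionProbability:
    def test_g_at_zero_is_one(self):
        assert detection_probability("half_normal", [12.0], 0.0, 40.0) == 1.0
        assert detection_probability("hazard_rate", [10.0, 2.5], 0.0, 40.0) == 1.0

    def test_half_normal_closed_form(self):
        g = detection_probability("half_normal", [12.0], 12.0, 40.0)
        assert g == pytest.approx(math.exp(-0.5), rel=1e-12)

    def test_uniform_is_one_everywhere(self):
        x = np.linspace(0, 40, 7)
        assert np.allclose(detection_probability("uniform", [], x, 40.0), 1.0)

    def test_adjusted_g_rescaled_to_one_at_origin(self):
        g0 = detection_probability(
            "half_normal", [12.0, 0.3], 0.0, 40.0, "cosine", 1
        )
        assert g0 == pytest.approx(1.0, abs=1e-12)

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            detection_probability("half_normal", [-1.0], 1.0, 40.0)
        with pytest.raises(ValueError):
            detection_probability("hazard_rate", [10.0, 0.0], 1.0, 40.0)


class TestLikelihood:
    def test_uniform_no_adjustment_closed_form(self):
        b = bin_distances([1, 5, 9, 13, 17], bin_width_m=4, truncation_w_m=20)
        ll = binned_log_likelihood(b, "uniform", "none", [])
        pi = np.diff(b.bin_edges_m) / 20.0
        assert ll == pytest.approx(np.sum(b.counts * np.log(pi)), rel=1e-12)

    @given(st.floats(math.log(2.0), math.log(60.0)))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_on_three_bin_toy(self, log_sigma):
        """At any σ, the likelihood equals an independent log Π π_i^{n_i}."""
        from scipy.integrate import quad

        sigma = math.exp(log_sigma)
        b = BinnedDistances(np.array([0.0, 5.0, 10.0, 15.0]), np.array([7, 3, 1]), 15.0, 0)
        ll = binned_log_likelihood(b, "half_normal", "none", [sigma])
        g = lambda x: math.exp(-(x**2) / (2 * sigma**2))
        total = quad(g, 0, 15)[0]
        pis = [quad(g, lo, hi)[0] / total for lo, hi in [(0, 5), (5, 10), (10, 15)]]
        brute = math.log(pis[0] ** 7 * pis[1] ** 3 * pis[2] ** 1)
        assert ll == pytest.approx(brute, abs=1e-10)


class TestEffectiveStripWidth:
    def test_uniform_esw_equals_truncation(self):
        b = bin_distances(np.linspace(0.1, 39.9, 50))
        fit = fit_detection(b, "uniform", "none")
        assert fit.esw_m == pytest.approx(40.0, rel=1e-10)

    def test_half_normal_closed_form(self, half_normal_binned):
        b, _ = half_normal_binned
        fit = fit_detection(b, "half_normal", "none")
        sigma = fit.params[0]
        expected = sigma * math.sqrt(math.pi / 2) * erf(40.0 / (sigma * math.sqrt(2)))
        assert fit.esw_m == pytest.approx(expected, rel=1e-6)

    def test_esw_never_exceeds_truncation(self, half_normal_binned):
        b, _ = half_normal_binned
        for fit in fit_six_models(b):
            if fit.converged and fit.monotone_ok:
                assert 0 < fit.esw_m <= 40.0 + 1e-9

    def test_esw_invariant_to_count_rescaling(self, half_normal_binned):
        b, _ = half_normal_binned
        scaled = BinnedDistances(b.bin_edges_m, b.counts * 3, b.truncation_w_m, 0)
        f1 = fit_detection(b, "half_normal", "none")
        f2 = fit_detection(scaled, "half_normal", "none")
        assert f1.esw_m == pytest.approx(f2.esw_m, rel=1e-6)

    def test_large_truncation_approaches_sigma_sqrt_pi_over_two(self):
        sigma = 10.0
        rng = np.random.default_rng(7)
        x = np.abs(rng.normal(0, sigma, 2000))
        b = bin_distances(x, bin_width_m=10.0, truncation_w_m=120.0)
        fit = fit_detection(b, "half_normal", "none")
        limit = fit.params[0] * math.sqrt(math.pi / 2)
        assert fit.esw_m == pytest.approx(limit, rel=1e-4)


class TestFitDetection:
    def test_half_normal_scale_recovery(self, half_normal_binned):
        b, sigma = half_normal_binned
        fit = fit_detection(b, "half_normal", "none")
        assert fit.converged
        assert fit.params[0] == pytest.approx(sigma, rel=0.10)

    def test_aic_identity(self, half_normal_binned):
        b, _ = half_normal_binned
        fit = fit_detection(b, "half_normal", "cosine")
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2 * fit.n_params)

    def test_single_occupied_bin_flagged_at_boundary(self):
        b = bin_distances([1.0, 2.0, 3.0])
        fit = fit_detection(b, "half_normal", "none")
        assert fit.at_boundary

    def test_needs_at_least_one_observation(self):
        with pytest.raises(ValueError):
            fit_detection(bin_distances([]), "half_normal")

    def test_hermite_with_uniform_key_rejected(self):
        with pytest.raises(ValueError):
            fit_detection(bin_distances([1.0]), "uniform", "hermite")


class TestSelection:
    def _fit(self, aic, n_params, key="half_normal"):
        from nestdensity.detection import DetectionFit

        return DetectionFit(
            key=key, adjustment="none", n_adj_terms=0, params=np.array([10.0]),
            log_likelihood=-aic / 2, n_params=n_params, aic=aic, esw_m=12.0,
            truncation_w_m=40.0,
        )

    def test_minimum_aic_wins(self):
        best = select_best_model([self._fit(100.0, 2), self._fit(102.3, 2)])
        assert best.aic == 100.0

    def test_tie_broken_by_fewest_parameters(self):
        best = select_best_model([self._fit(100.0, 3), self._fit(100.0, 2)])
        assert best.n_params == 2

    def test_tie_broken_by_key_order(self):
        fits = [self._fit(100.0, 2, "hazard_rate"), self._fit(100.0, 2, "uniform")]
        assert select_best_model(fits).key == "uniform"

    def test_no_valid_fit_raises(self):
        bad = self._fit(100.0, 2)
        bad = bad.__class__(**{**vars(bad), "monotone_ok": False})
        with pytest.raises(SelectionError):
            select_best_model([bad])

    def test_selected_esw_tracks_truth_from_half_normal_data(self):
        """Whatever model wins, its ESW stays near the generating truth."""
        sigma, w = 12.4, 40.0
        true_esw = sigma * math.sqrt(math.pi / 2) * erf(w / (sigma * math.sqrt(2)))
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            x = rng.uniform(0, 60, 40000)
            kept = x[rng.uniform(size=len(x)) < np.exp(-(x**2) / (2 * sigma**2))][:1000]
            best = select_best_model(fit_six_models(bin_distances(kept)))
            if abs(best.esw_m - true_esw) / true_esw < 0.10:
                hits += 1
        assert hits >= int(0.9 * n_rep)


class TestGoodnessOfFit:
    def test_perfect_fit_gives_zero(self):
        b = bin_distances(np.repeat(np.arange(0.5, 40, 4), 5))
        fit = fit_detection(b, "uniform", "none")
        chi2, df, p = gof_chisquare(fit, b)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_bin_fixture(self):
        b = BinnedDistances(np.array([0.0, 20.0, 40.0]), np.array([10, 5]), 40.0, 0)
        fit = fit_detection(b, "uniform", "none")
        chi2, df, p = gof_chisquare(fit, b)
        # expected 7.5 per bin: (2.5²/7.5)·2
        assert chi2 == pytest.approx(2 * 2.5**2 / 7.5, rel=1e-9)
        assert df == 1
        assert 0 <= p <= 1

    def test_small_expected_bins_merged(self, half_normal_binned):
        b, _ = half_normal_binned
        fit = fit_detection(b, "half_normal", "none")
        chi2, df, p = gof_chisquare(fit, b)
        assert df >= 1 and 0 <= p <= 1
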