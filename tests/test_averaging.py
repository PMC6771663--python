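"""Multimodel machinery: standardisation, screening, AICc averaging.

The averaged coefficients are checked against an independent brute-force
oracle that enumerates subsets explicitly, fits each by raw least
squares and applies the weight and zero-substitution formulas directly.
"""

import math

import numpy as np
import pandas as pd
import pytest

from nestdensity.averaging import (
    PredictorMatrix,
    akaike_weights,
    average_coefficients,
    collinearity_screen,
    cooks_distance,
    enumerate_models,
    fit_all_models,
    fit_linear_model,
    standardize_predictors,
)


def _matrix(y, columns: dict, factor_blocks=None):
    return PredictorMatrix(np.asarray(y, float), pd.DataFrame(columns),
                           factor_blocks or {})


class TestStandardise:
    def test_gelman_rule_hand_computed(self):
        m = standardize_predictors(_matrix([0, 0, 0], {"x": [1.0, 2.0, 3.0]}))
        assert m.predictors["x"].tolist() == pytest.approx([-0.5, 0.0, 0.5])
        assert np.std(m.predictors["x"], ddof=1) == pytest.approx(0.5)

    def test_idempotent(self):
        m = standardize_predictors(_matrix([0] * 4, {"x": [-0.6, -0.2, 0.2, 0.6]}))
        m2 = standardize_predictors(m)
        assert np.allclose(m.predictors["x"], m2.predictors["x"], atol=1e-12)

    def test_binary_dummy_centred_not_rescaled(self):
        m = standardize_predictors(
            _matrix([0, 0, 0], {"d": [0.0, 1.0, 1.0]}, {"f": ["d"]})
        )
        assert m.predictors["d"].tolist() == pytest.approx([-2 / 3, 1 / 3, 1 / 3])

    def test_constant_predictor_named_in_error(self):
        with pytest.raises(ValueError, match="bad_col"):
            standardize_predictors(_matrix([0, 0], {"bad_col": [1.0, 1.0]}))


class TestCollinearityScreen:
    def test_duplicated_column_flagged(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        m = _matrix(rng.normal(size=50), {"a": x, "b": x.copy(), "c": rng.normal(size=50)})
        screen = collinearity_screen(m)
        assert ("a", "b") in screen.excluded_pairs

    def test_below_threshold_pair_not_flagged(self):
        # construct r ≈ 0.69 exactly below the strict 0.7 cut
        rng = np.random.default_rng(1)
        n = 2000
        a = rng.normal(size=n)
        b = 0.69 * a + math.sqrt(1 - 0.69**2) * rng.normal(size=n)
        r = np.corrcoef(a, b)[0, 1]
        assume_ok = abs(r) < 0.7
        m = _matrix(np.zeros(n), {"a": a, "b": b})
        screen = collinearity_screen(m)
        assert assume_ok and screen.excluded_pairs == []

    def test_independent_predictors_no_flags(self):
        rng = np.random.default_rng(2)
        m = _matrix(
            np.zeros(1000),
            {f"x{i}": rng.normal(size=1000) for i in range(4)},
        )
        screen = collinearity_screen(m)
        assert screen.excluded_pairs == []
        assert all(v < 5 for v in screen.gvif.values())

    def test_gvif_reduces_to_vif_for_single_columns(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=300)
        b = 0.9 * a + 0.1 * rng.normal(size=300)
        m = _matrix(np.zeros(300), {"a": a, "b": b})
        screen = collinearity_screen(m)
        r2 = np.corrcoef(a, b)[0, 1] ** 2
        assert screen.gvif["a"] == pytest.approx(1 / (1 - r2), rel=1e-6)


class TestEnumerate:
    def test_three_free_predictors_eight_models(self):
        assert len(enumerate_models(["a", "b", "c"])) == 8

    def test_seven_predictors_one_exclusion_96(self):
        terms = list("abcdefg")
        models = enumerate_models(terms, [("a", "b")])
        # brute force: 2⁷ minus subsets containing both a and b (2⁵)
        assert len(models) == 2**7 - 2**5 == 96

    def test_intercept_only_always_present(self):
        assert () in enumerate_models(["a", "b"], [("a", "b")])

    def test_unknown_exclusion_rejected(self):
        with pytest.raises(ValueError):
            enumerate_models(["a"], [("a", "zzz")])


class TestLinearFit:
    def test_exact_fit_recovers_slope(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        m = _matrix(2 * x, {"x": x})
        fit = fit_linear_model(m, ("x",))
        assert fit.coefficients["x"] == pytest.approx(2.0, rel=1e-10)
        assert fit.sigma2_ml == pytest.approx(0.0, abs=1e-16)

    def test_intercept_only_is_mean(self):
        y = [1.0, 4.0, 7.0, 8.0]
        fit = fit_linear_model(_matrix(y, {"x": [0.0, 1.0, 2.0, 3.0]}), ())
        assert fit.coefficients["intercept"] == pytest.approx(np.mean(y))

    def test_aicc_exceeds_aic(self):
        rng = np.random.default_rng(4)
        m = _matrix(rng.normal(size=20), {"x": rng.normal(size=20)})
        fit = fit_linear_model(m, ("x",))
        assert fit.aicc > fit.aic

    def test_singular_design_rejected(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        m = _matrix(x, {"a": x, "b": 2 * x})
        with pytest.raises(ValueError):
            fit_linear_model(m, ("a", "b"))


class TestAkaikeWeights:
    def test_two_model_closed_form(self):
        w = akaike_weights([100.0, 102.0])
        assert w.tolist() == pytest.approx([0.731, 0.269], abs=5e-4)

    def test_single_model_weight_one(self):
        assert akaike_weights([123.4]).tolist() == [1.0]

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            w = akaike_weights(rng.uniform(50, 500, size=rng.integers(1, 40)))
            assert w.sum() == pytest.approx(1.0, rel=1e-12)


from _oracles import brute_force_average as _brute_force_average


class TestAveraging:
    def test_matches_brute_force_oracle_on_three_predictor_toy(self):
        rng = np.random.default_rng(11)
        n = 30
        X = pd.DataFrame({c: rng.normal(size=n) for c in ("a", "b", "c")})
        y = 1.0 + 0.8 * X["a"].to_numpy() + rng.normal(size=n)
        m = _matrix(y, X)
        fits = fit_all_models(m)
        table = average_coefficients(fits, m).set_index("coefficient")
        oracle = _brute_force_average(y, X)
        for col, (bbar, se, imp) in oracle.items():
            assert table.loc[col, "estimate"] == pytest.approx(bbar, abs=1e-10)
            assert table.loc[col, "se"] == pytest.approx(se, abs=1e-10)
            assert table.loc[col, "importance"] == pytest.approx(imp, abs=1e-10)

    def test_two_model_zero_substitution_hand_case(self):
        """Weights {.5, .5}, predictor only in the first with β = 4 → β̄ = 2."""
        from nestdensity.averaging import ModelFit

        fits = [
            ModelFit(("x",), {"intercept": 0.0, "x": 4.0}, {"intercept": 0.0, "x": 0.0},
                     1.0, 0.0, 3, 0.0, 0.0, akaike_weight=0.5),
            ModelFit((), {"intercept": 0.0}, {"intercept": 0.0},
                     1.0, 0.0, 2, 0.0, 0.0, akaike_weight=0.5),
        ]
        m = _matrix([0.0, 0.0], {"x": [0.0, 1.0]})
        table = average_coefficients(fits, m).set_index("coefficient")
        assert table.loc["x", "estimate"] == pytest.approx(2.0)
        assert table.loc["x", "importance"] == pytest.approx(0.5)

    def test_single_model_average_is_that_model(self):
        rng = np.random.default_rng(12)
        n = 25
        X = pd.DataFrame({"a": rng.normal(size=n)})
        y = 2.0 - 1.5 * X["a"].to_numpy() + 0.1 * rng.normal(size=n)
        m = _matrix(y, X)
        fit = fit_linear_model(m, ("a",))
        fit.akaike_weight = 1.0
        table = average_coefficients([fit], m).set_index("coefficient")
        assert table.loc["a", "estimate"] == pytest.approx(fit.coefficients["a"])
        assert table.loc["a", "importance"] == 1.0

    def test_removing_zero_weight_model_changes_nothing(self):
        rng = np.random.default_rng(13)
        n = 40
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = X["a"].to_numpy() + rng.normal(size=n)
        m = _matrix(y, X)
        fits = fit_all_models(m)
        # force one model's weight to exactly zero without renormalising:
        # the average must then be identical with or without it
        victim = min(fits, key=lambda f: f.akaike_weight)
        scale = 1.0 / (1.0 - victim.akaike_weight)
        for f in fits:
            f.akaike_weight = 0.0 if f is victim else f.akaike_weight * scale
        t_with = average_coefficients(fits, m)
        t_without = average_coefficients([f for f in fits if f is not victim], m)
        merged = t_with.merge(t_without, on="coefficient", suffixes=("_a", "_b"))
        for col in ("estimate", "se", "importance"):
            assert np.allclose(merged[f"{col}_a"], merged[f"{col}_b"], atol=1e-12)

    def test_ci_contains_estimate(self):
        rng = np.random.default_rng(14)
        n = 30
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = 0.5 * X["a"].to_numpy() + rng.normal(size=n)
        m = _matrix(y, X)
        table = average_coefficients(fit_all_models(m), m)
        assert ((table["ci_lower"] <= table["estimate"])
                & (table["estimate"] <= table["ci_upper"])).all()

    def test_null_effects_ci_coverage_near_95pct(self):
        """With zero true effects the averaged 95% CIs should cover 0 for
        roughly 95% of predictors over repeated simulations."""
        rng = np.random.default_rng(15)
        n, n_sim = 40, 200
        covered = total = 0
        for _ in range(n_sim):
            X = pd.DataFrame({c: rng.normal(size=n) for c in ("a", "b", "c")})
            y = rng.normal(size=n)
            m = _matrix(y, X)
            table = average_coefficients(fit_all_models(m), m)
            sub = table[table["coefficient"] != "intercept"]
            covered += int(((sub["ci_lower"] <= 0) & (0 <= sub["ci_upper"])).sum())
            total += len(sub)
        assert covered / total == pytest.approx(0.95, abs=0.05)


class TestCooksDistance:
    def test_balanced_design_no_influential_rows(self):
        rng = np.random.default_rng(16)
        n = 50
        X = pd.DataFrame({"x": np.linspace(-1, 1, n)})
        y = X["x"].to_numpy() + 0.1 * rng.normal(size=n)
        m = _matrix(y, X)
        cd = cooks_distance(fit_linear_model(m, ("x",)))
        assert (cd["cooks_d"] >= 0).all()
        assert not cd["flagged"].any()

    def test_gross_outlier_at_high_leverage_flagged(self):
        x = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 5.0])
        y = np.array([0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 30.0])
        m = _matrix(y, pd.DataFrame({"x": x}))
        cd = cooks_distance(fit_linear_model(m, ("x",)))
        assert bool(cd.loc[6, "flagged"])
        # verified against the direct formula D_i = r_i² h_i / (p·(1−h_i))
        X = np.column_stack([np.ones(7), x])
        H = X @ np.linalg.inv(X.T @ X) @ X.T
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        s2 = resid @ resid / (7 - 2)
        h = np.diag(H)
        d6 = resid[6] ** 2 / (2 * s2) * h[6] / (1 - h[6]) ** 2
        assert cd.loc[6, "cooks_d"] == pytest.approx(d6, rel=1e-10)
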