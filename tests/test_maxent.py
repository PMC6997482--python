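"""Feature construction, L1-regularized fitting, prediction, evaluation,
model selection, and variable importance of the maximum-entropy model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq, minimize
from scipy.special import logsumexp

import popsdm as p


@pytest.fixture(scope="module")
def six_var_background():
    rng = np.random.default_rng(0)
    return pd.DataFrame(rng.random((300, 6)), columns=[f"v{i}" for i in range(6)])


def _tilted_sample(rng, bg, beta, m):
    """Presences drawn from density proportional to exp(beta . x) over bg cells."""
    w = np.exp(bg.to_numpy() @ np.atleast_1d(beta))
    w = w / w.sum()
    idx = rng.choice(len(bg), size=m, replace=True, p=w)
    return bg.iloc[idx]


# ---------------------------------------------------------------------------
# Feature construction
# ---------------------------------------------------------------------------

class TestBuildFeatures:
    @pytest.mark.parametrize("fc,expected", [
        ("L", 6), ("LQ", 12), ("LQH", 12 + 2 * 20 * 6),
        ("LQHP", 6 + 6 + 15 + 2 * 20 * 6), ("LQHPT", 267 + 20 * 6), ("H", 240)])
    def test_feature_counts_by_construction_rule(self, six_var_background, fc, expected):
        fs = p.build_features(six_var_background, fc=fc, n_knots=20)
        assert len(fs) == expected

    def test_features_scaled_to_unit_interval_on_background(self, six_var_background):
        fs = p.build_features(six_var_background, fc="LQHPT", n_knots=10)
        F = fs.evaluate(six_var_background)
        assert F.min() >= 0.0 and F.max() <= 1.0 + 1e-12

    def test_constant_variable_keeps_only_linear(self):
        rng = np.random.default_rng(1)
        bg = pd.DataFrame({"a": rng.random(50), "b": np.ones(50)})
        fs = p.build_features(bg, fc="LQH", n_knots=5)
        kinds_b = [f.kind for f in fs.features if "b" in f.vars]
        assert kinds_b == ["linear"]

    def test_unknown_combo_rejected(self, six_var_background):
        with pytest.raises(ValueError):
            p.build_features(six_var_background, fc="LQT")


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

class TestFitMaxent:
    def test_uninformative_feature_gives_uniform_model(self):
        rng = np.random.default_rng(2)
        bg = pd.DataFrame({"x": np.ones(40)})
        pres = pd.DataFrame({"x": np.ones(10)})
        m = p.fit_maxent(pres, bg, rm=1.0, fc="L")
        assert np.all(m.lam == 0)
        raw = p.predict(m, bg, output="raw")
        np.testing.assert_allclose(raw, 1 / 40, atol=1e-12)

    def test_huge_rm_shrinks_all_coefficients_to_zero(self, six_var_background):
        rng = np.random.default_rng(3)
        pres = _tilted_sample(rng, six_var_background, [2, 0, 0, 0, 0, 0], 50)
        m = p.fit_maxent(pres, six_var_background, rm=1e4, fc="LQ")
        assert np.all(m.lam == 0.0)

    def test_background_raw_normalization_after_fit(self, six_var_background):
        rng = np.random.default_rng(4)
        pres = _tilted_sample(rng, six_var_background, [1.5, -1, 0, 0, 0.5, 0], 60)
        for fc in ("L", "LQ", "LQH"):
            m = p.fit_maxent(pres, six_var_background, rm=0.5, fc=fc, n_knots=8)
            raw = p.predict(m, six_var_background, output="raw", clamp=False)
            assert raw.sum() == pytest.approx(1.0, abs=1e-6)

    def test_exponential_tilt_coefficient_recovery(self):
        # presences from density ~ exp(2x) over a uniform 1-D background;
        # the fitted linear coefficient must match the exponential-family
        # MLE solved independently from the mean constraint
        rng = np.random.default_rng(42)
        x_bg = np.linspace(0, 1, 201)
        bg = pd.DataFrame({"x": x_bg})
        pres = _tilted_sample(rng, bg, [2.0], 2000)
        m = p.fit_maxent(pres, bg, rm=0.01, fc="L")
        mean_p = pres["x"].mean()
        lam_oracle = brentq(
            lambda lam: (x_bg * np.exp(lam * x_bg)).sum() / np.exp(lam * x_bg).sum()
            - mean_p, -10, 10)
        assert m.lam[0] == pytest.approx(lam_oracle, abs=0.05)
        assert m.lam[0] == pytest.approx(2.0, abs=0.2)

    def test_unregularized_fit_matches_bfgs_likelihood_oracle(self):
        # <= 50-cell landscape, 3 linear features, RM = 0: proximal-gradient
        # solution vs an independent BFGS minimization of the same likelihood
        rng = np.random.default_rng(7)
        bg = pd.DataFrame(rng.random((50, 3)), columns=list("abc"))
        pres = _tilted_sample(rng, bg, [1.5, -2.0, 0.7], 20)
        fs = p.build_features(bg, fc="L")
        m = p.fit_maxent(pres, bg, feature_space=fs, rm=0.0,
                         max_iter=5000, tol=1e-14)
        assert m.rm_floored
        F = fs.evaluate(bg)
        Fp = fs.evaluate(pres).mean(axis=0)
        res = minimize(lambda lam: -Fp @ lam + logsumexp(F @ lam),
                       np.zeros(3), method="BFGS",
                       options={"gtol": 1e-12, "maxiter": 10000})
        np.testing.assert_allclose(m.lam, res.x, atol=1e-3)

    def test_negative_rm_rejected(self, six_var_background):
        with pytest.raises(ValueError):
            p.fit_maxent(six_var_background.iloc[:5], six_var_background, rm=-1)

    def test_nonfinite_features_rejected(self):
        bg = pd.DataFrame({"x": [0.0, 1.0, np.nan]})
        with pytest.raises(ValueError):
            p.fit_maxent(bg.iloc[:2], bg, rm=1.0, fc="L")


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

class TestPredict:
    def test_uniform_model_transform_algebra(self):
        bg = pd.DataFrame({"x": np.ones(25)})
        m = p.fit_maxent(bg.iloc[:5], bg, rm=1.0, fc="L")
        assert m.entropy == pytest.approx(np.log(25), abs=1e-9)
        np.testing.assert_allclose(p.predict(m, bg, output="raw"), 1 / 25, atol=1e-12)
        np.testing.assert_allclose(p.predict(m, bg, output="logistic"), 0.5, atol=1e-9)

    def test_ranking_invariant_across_transforms(self, six_var_background):
        rng = np.random.default_rng(5)
        pres = _tilted_sample(rng, six_var_background, [2, -1, 0, 0, 0, 0], 40)
        m = p.fit_maxent(pres, six_var_background, rm=0.5, fc="LQ")
        X = six_var_background.iloc[:100]
        orders = [np.argsort(p.predict(m, X, output=o))
                  for o in ("raw", "logistic", "cloglog")]
        np.testing.assert_array_equal(orders[0], orders[1])
        np.testing.assert_array_equal(orders[0], orders[2])

    def test_clamping_freezes_prediction_beyond_training_range(self, six_var_background):
        rng = np.random.default_rng(6)
        pres = _tilted_sample(rng, six_var_background, [2, 0, 0, 0, 0, 0], 40)
        m = p.fit_maxent(pres, six_var_background, rm=0.5, fc="LQ")
        at_max = six_var_background.iloc[:1].copy()
        beyond = at_max.copy()
        at_max["v0"] = m.feature_space.var_max[0]
        beyond["v0"] = m.feature_space.var_max[0] + 10
        assert p.predict(m, beyond)[0] == pytest.approx(p.predict(m, at_max)[0], rel=1e-12)

    def test_unknown_output_rejected(self, six_var_background):
        m = p.fit_maxent(six_var_background.iloc[:5], six_var_background, rm=1, fc="L")
        with pytest.raises(ValueError):
            p.predict(m, six_var_background, output="sigmoid")

    def test_raster_stack_prediction_preserves_nodata(self, grid_factory):
        vals = np.array([[0.1, 0.9], [np.nan, 0.5]])
        stack = p.RasterStack({"x": grid_factory(vals)})
        bg = pd.DataFrame({"x": np.linspace(0, 1, 30)})
        m = p.fit_maxent(bg.iloc[[25, 28]], bg, rm=1.0, fc="L")
        out = p.predict(m, stack)
        assert np.isnan(out.values[1, 0]) and np.isfinite(out.values[0, 0])


# ---------------------------------------------------------------------------
# AUC and AICc
# ---------------------------------------------------------------------------

class TestAuc:
    def test_hand_counted_example(self):
        assert p.auc([0.9, 0.7], [0.8, 0.2, 0.1]) == pytest.approx(5 / 6)

    def test_perfect_separation(self):
        assert p.auc([0.9, 0.8], [0.5, 0.2]) == 1.0

    def test_identical_sets_give_half(self):
        assert p.auc([0.3, 0.6], [0.3, 0.6]) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20),
           st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_antisymmetry(self, a, b):
        assert p.auc(a, b) == pytest.approx(1 - p.auc(b, a), abs=1e-12)


class TestAicc:
    def test_arithmetic_example(self):
        # K = 3, lnL = -100, m = 30 -> 206 + 24/26
        m = _uniform_model(5)
        m.lam = np.array([1.0, 2.0, 3.0, 0.0, 0.0])
        value = 2 * 3 - 2 * (-100) + 2 * 3 * 4 / (30 - 3 - 1)
        assert value == pytest.approx(206.923076923)

    def test_small_sample_guard(self, six_var_background):
        rng = np.random.default_rng(8)
        pres = _tilted_sample(rng, six_var_background, [3, 2, -2, 0, 0, 0], 5)
        m = p.fit_maxent(pres, six_var_background, rm=0.1, fc="LQ")
        if m.n_parameters >= len(pres) - 1:
            assert p.aicc(m, pres, six_var_background)["AICc"] == np.inf

    def test_uniform_model_loglik_closed_form(self):
        bg = pd.DataFrame({"x": np.ones(40)})
        pres = bg.iloc[:6]
        m = p.fit_maxent(pres, bg, rm=1.0, fc="L")
        out = p.aicc(m, pres, bg)
        assert out["lnL"] == pytest.approx(-6 * np.log(40), abs=1e-9)
        assert out["K"] == 0


def _uniform_model(n_feat):
    bg = pd.DataFrame({"x": np.ones(30)})
    m = p.fit_maxent(bg.iloc[:5], bg, rm=1.0, fc="L")
    m.lam = np.zeros(n_feat)
    return m


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

class TestModelSelect:
    def test_single_setting_grid_returns_it(self, six_var_background):
        rng = np.random.default_rng(9)
        pres = _tilted_sample(rng, six_var_background, [2, 0, 0, 0, 0, 0], 30)
        sel = p.model_select(pres, six_var_background, rm_grid=(1.5,),
                             fc_combos=("LQ",), n_eval_splits=2, seed=0)
        assert (sel.rm, sel.fc) == (1.5, "LQ")

    def test_scores_grid_covers_every_setting(self, six_var_background):
        rng = np.random.default_rng(10)
        pres = _tilted_sample(rng, six_var_background, [2, -1, 0, 0, 0, 0], 30)
        sel = p.model_select(pres, six_var_background, rm_grid=(0.5, 1.0),
                             fc_combos=("L", "LQ"), n_eval_splits=2, seed=1)
        assert len(sel.scores) == 4
        assert sel.scores["mean_test_auc"].between(0, 1).all()

    def test_deterministic_given_seed(self, six_var_background):
        rng = np.random.default_rng(11)
        pres = _tilted_sample(rng, six_var_background, [2, 0, 0, 0, 0, 0], 24)
        a = p.model_select(pres, six_var_background, rm_grid=(0.5, 1.0),
                           fc_combos=("L",), n_eval_splits=3, seed=5)
        b = p.model_select(pres, six_var_background, rm_grid=(0.5, 1.0),
                           fc_combos=("L",), n_eval_splits=3, seed=5)
        pd.testing.assert_frame_equal(a.scores, b.scores)


# ---------------------------------------------------------------------------
# Importance and response curves
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def informative_fit(six_var_background):
    rng = np.random.default_rng(12)
    pres = _tilted_sample(rng, six_var_background, [4, 0, 0, 0, 0, 0], 60)
    return pres, p.fit_maxent(pres, six_var_background, rm=0.5, fc="LQ")


class TestImportance:
    def test_single_informative_variable_dominates(self, six_var_background,
                                                   informative_fit):
        pres, m = informative_fit
        imp = p.permutation_importance(m, pres, six_var_background, seed=0)
        assert imp["v0"] > 80

    def test_percentages_sum_to_100(self, six_var_background, informative_fit):
        pres, m = informative_fit
        imp = p.permutation_importance(m, pres, six_var_background, seed=1)
        assert imp.sum() == pytest.approx(100.0)

    def test_zero_coefficient_variable_has_zero_drop(self, six_var_background,
                                                     informative_fit):
        pres, m = informative_fit
        # silence every feature touching v5
        for i, f in enumerate(m.feature_space.features):
            if "v5" in f.vars:
                m.lam[i] = 0.0
        imp = p.permutation_importance(m, pres, six_var_background, seed=2)
        assert imp["v5"] == 0.0

    def test_jackknife_identifies_generative_variable(self, six_var_background):
        rng = np.random.default_rng(13)
        pres = _tilted_sample(rng, six_var_background, [4, 0, 0, 0, 0, 0], 50)
        jk = p.jackknife_importance(pres, six_var_background, rm=0.5, fc="L",
                                    n_splits=3, seed=0)
        assert jk["only"].idxmax() == "v0"
        # uninformative variables alone are near-chance discriminators
        assert jk.loc["v3", "only"] == pytest.approx(0.5, abs=0.12)
        # dropping the only informative variable collapses discrimination
        assert jk.loc["v0", "without"] == pytest.approx(0.5, abs=0.12)


class TestResponseCurve:
    def test_gaussian_niche_peak_recovers_optimum(self):
        rng = np.random.default_rng(14)
        bg = pd.DataFrame({"x": rng.random(400), "y": rng.random(400)})
        mu = 0.6
        w = np.exp(-0.5 * ((bg["x"] - mu) / 0.1) ** 2)
        idx = rng.choice(400, size=100, replace=False, p=(w / w.sum()).to_numpy())
        pres = bg.iloc[idx]
        m = p.fit_maxent(pres, bg, rm=1.0, fc="LQ")
        grid, curve = p.response_curve(m, "x")
        peak = grid[np.argmax(curve)]
        assert abs(peak - mu) / np.ptp(bg["x"]) < 0.05

    def test_cutoff_above_curve_max_gives_empty_range(self):
        grid = np.linspace(0, 1, 50)
        assert p.threshold_range(grid, np.full(50, 0.1), cutoff=0.2) is None

    def test_threshold_range_brackets_suitable_interval(self):
        grid = np.linspace(0, 10, 101)
        curve = np.exp(-0.5 * ((grid - 5) / 1.0) ** 2)
        lo, hi = p.threshold_range(grid, curve, cutoff=0.2)
        assert lo < 5 < hi
        assert np.all(curve[(grid > lo) & (grid < hi)] > 0.15)

    def test_unknown_variable_rejected(self, six_var_background):
        m = p.fit_maxent(six_var_background.iloc[:10], six_var_background,
                         rm=1.0, fc="L")
        with pytest.raises(KeyError):
            p.response_curve(m, "nope")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, six_var_background, tmp_path):
        rng = np.random.default_rng(15)
        pres = _tilted_sample(rng, six_var_background, [2, -1, 0, 0, 0, 0], 40)
        m = p.fit_maxent(pres, six_var_background, rm=0.5, fc="LQH", n_knots=5)
        p.save_model(m, tmp_path / "m.json")
        back = p.load_model(tmp_path / "m.json")
        np.testing.assert_allclose(p.predict(back, six_var_background),
                                   p.predict(m, six_var_background), rtol=1e-12)
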