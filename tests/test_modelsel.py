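import math

import numpy as np
import pandas as pd
import pytest

import picrisk as pk
from picrisk.modelsel import AICcModelSelection, OriginRegression

# Published model-comparison table this machinery must reproduce from its
# own bookkeeping: (slopes, log-likelihood, printed AICc) for the eight
# candidate models on each of the two tree topologies, n = 19 contrasts.
PUBLISHED_MODEL_SETS = {
    "tree1": [
        (2, -1.53, 10.67), (2, -1.80, 11.20), (3, -0.52, 11.90),
        (1, -3.59, 11.94), (1, -4.16, 13.06), (2, -3.11, 13.81),
        (1, -4.57, 13.90), (0, -5.88, 13.99),
    ],
    "tree2": [
        (2, -1.40, 10.40), (3, 0.00, 10.85), (2, -1.68, 10.95),
        (1, -3.36, 11.47), (2, -2.82, 13.24), (1, -4.25, 13.26),
        (0, -5.89, 14.02), (1, -4.64, 14.02),
    ],
}


class TestStandardize:
    def test_two_points(self):
        assert pk.standardize([1, 3]) == pytest.approx(
            [-1 / math.sqrt(2), 1 / math.sqrt(2)])

    def test_three_points(self):
        assert pk.standardize([2, 4, 6]) == pytest.approx([-1, 0, 1])

    def test_idempotent(self, rng):
        x = rng.standard_normal(25)
        z = pk.standardize(x)
        assert pk.standardize(z) == pytest.approx(z, abs=1e-12)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            pk.standardize([3.0, 3.0, 3.0])


class TestAicc:
    def test_small_sample_formula(self):
        assert pk.aicc(-3.59, 2, 19) == pytest.approx(11.93, abs=0.005)
        assert pk.aicc(-5.88, 1, 19) == pytest.approx(13.995, abs=0.005)
        assert pk.aicc(-1.53, 3, 19) == pytest.approx(10.66, abs=0.005)

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            pk.aicc(-1.0, 3, 4)

    def test_monotone_in_k_and_limits_to_aic(self):
        lls = -2.5
        values = [pk.aicc(lls, k, 50) for k in (1, 2, 3, 4)]
        assert values == sorted(values)
        assert pk.aicc(lls, 2, 10**7) == pytest.approx(-2 * lls + 4, abs=1e-5)

    @pytest.mark.parametrize("tree", sorted(PUBLISHED_MODEL_SETS))
    def test_published_bookkeeping_chain(self, tree):
        """The printed AICc values follow from the printed log-likelihoods
        with k = slopes + 1 and n = 19 (to rounding of the log-likelihood)."""
        for slopes, loglik, printed in PUBLISHED_MODEL_SETS[tree]:
            assert pk.aicc(loglik, slopes + 1, 19) == pytest.approx(
                printed, abs=0.02)


class TestAkaikeWeights:
    def test_single_and_tied_models(self):
        assert pk.akaike_weights([5.0]) == pytest.approx([1.0])
        assert pk.akaike_weights([3.3, 3.3]) == pytest.approx([0.5, 0.5])

    def test_published_top_weight(self):
        aiccs = [a for _, _, a in PUBLISHED_MODEL_SETS["tree1"]]
        w = pk.akaike_weights(aiccs)
        assert w[0] == pytest.approx(0.27, abs=0.01)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)

    def test_shift_invariance(self, rng):
        a = rng.normal(20, 3, size=6)
        assert pk.akaike_weights(a) == pytest.approx(
            pk.akaike_weights(a + 100.0), abs=1e-12)


class TestAllSubsets:
    @pytest.mark.parametrize("p,count", [(5, 32), (3, 8), (1, 2)])
    def test_counts_include_null(self, p, count):
        subs = pk.all_subsets([f"x{i}" for i in range(p)])
        assert len(subs) == count and subs[0] == ()

    def test_deterministic_order(self):
        assert pk.all_subsets(["a", "b"]) == [(), ("a",), ("b",), ("a", "b")]

    def test_duplicates_rejected(self):
        with pytest.raises(ValueError):
            pk.all_subsets(["a", "a"])


class TestOriginRegression:
    def test_exact_fit(self):
        x = np.arange(1.0, 11.0)
        m = OriginRegression().fit(x[:, None], 2 * x)
        assert m.coef_[0] == pytest.approx(2.0)
        assert m.rss_ == pytest.approx(0.0, abs=1e-20)
        assert m.r2_ == pytest.approx(1.0)

    def test_null_model_closed_form_loglik(self, rng):
        y = rng.standard_normal(19)
        m = OriginRegression().fit(np.empty((19, 0)), y)
        s = float(y @ y) / 19
        expected = -19 / 2 * (math.log(2 * math.pi * s) + 1)
        assert m.loglik_ == pytest.approx(expected, rel=1e-12)
        assert m.k_ == 1 and m.adj_r2_ == 0.0

    def test_no_intercept_is_fit(self, rng):
        x = rng.standard_normal(30)
        y = 5.0 + 0.0 * x + rng.standard_normal(30) * 0.1
        m = OriginRegression().fit(x[:, None], y)
        # prediction at x=0 must be 0, not the data mean
        assert m.predict(np.array([[0.0]]))[0] == 0.0

    def test_rank_deficiency_rejected(self, rng):
        x = rng.standard_normal(20)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(ValueError, match="rank"):
            OriginRegression().fit(X, x)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match="n > p"):
            OriginRegression().fit(np.ones((2, 1)), np.ones(2))

    def test_slope_test_matches_manual_t(self, rng):
        x = rng.standard_normal(25)
        y = 0.4 * x + rng.standard_normal(25)
        m = OriginRegression().fit(x[:, None], y)
        tt = m.slope_test()
        se = math.sqrt(m.rss_ / (25 - 1) / float(x @ x))
        assert tt["se"].iloc[0] == pytest.approx(se, rel=1e-12)
        assert tt["df"].iloc[0] == 24


class TestModelSelection:
    @pytest.fixture
    def fitted(self, rng):
        X, y = pk.simulate_contrast_regression(
            19, {"A": 0.8, "B": 0.0, "C": 0.3}, sigma=0.5, seed=rng)
        return AICcModelSelection().fit(X, y)

    def test_weights_sum_to_one_and_best_delta_zero(self, fitted):
        assert fitted.table_["weight"].sum() == pytest.approx(1.0, abs=1e-10)
        assert fitted.table_["delta"].iloc[0] == 0.0
        assert len(fitted.table_) == 8

    def test_rvi_complement_identity(self, fitted):
        for name in "ABC":
            inc = fitted.variable_importance(name)
            exc = fitted.table_.loc[
                fitted.table_["predictors"].apply(lambda s: name not in s),
                "weight"].sum()
            assert inc == pytest.approx(1 - exc, abs=1e-12)
            assert 0 <= inc <= 1

    def test_strong_predictor_outranks_noise(self, fitted):
        assert fitted.variable_importance("A") > fitted.variable_importance("B")

    def test_single_containing_model_average_is_wald(self, rng):
        X, y = pk.simulate_contrast_regression(19, {"A": 0.5}, seed=rng)
        sel = AICcModelSelection().fit(X, y)
        beta, se, lo, hi = sel.average_coefficient("A")
        m = sel.fits_[("A",)]
        assert beta == pytest.approx(m.coef_[0], rel=1e-12)
        assert se == pytest.approx(math.sqrt(m.coef_var_[0]), rel=1e-12)
        assert (lo, hi) == pytest.approx(
            (beta - 1.96 * se, beta + 1.96 * se), rel=1e-12)

    def test_between_model_spread_enters_se(self):
        """Hand evaluation: two equally weighted models with slopes 1 and 3
        and no within-model variance average to 2 with SE 1."""
        sel = AICcModelSelection()
        sel.feature_names_in_ = np.array(["A", "B"], dtype=object)
        sel.table_ = pd.DataFrame({
            "predictors": [("A",), ("A", "B")], "weight": [0.5, 0.5]})
        m1, m2 = OriginRegression(), OriginRegression()
        m1.coef_, m1.coef_var_ = np.array([1.0]), np.array([0.0])
        m2.coef_, m2.coef_var_ = np.array([3.0, 0.0]), np.array([0.0, 0.0])
        sel.fits_ = {("A",): m1, ("A", "B"): m2}
        beta, se, lo, hi = sel.average_coefficient("A")
        assert beta == pytest.approx(2.0)
        assert se == pytest.approx(1.0)
        assert (lo, hi) == pytest.approx((2 - 1.96, 2 + 1.96))

    def test_unknown_predictor_rejected(self, fitted):
        with pytest.raises(KeyError):
            fitted.variable_importance("D")
        with pytest.raises(KeyError):
            fitted.average_coefficient("D")


class TestTwoStageScreen:
    def test_true_signal_ranks_first(self, rng):
        hits = 0
        for _ in range(25):
            X, y = pk.simulate_contrast_regression(
                19, {"A": 1.0, "B": 0.0, "C": 0.0, "D": 0.0, "E": 0.0},
                sigma=0.5, seed=rng)
            screen = pk.two_stage_screen(y, X)
            hits += screen.stage1_rvi_.index[0] == "A"
            assert len(screen.stage1_.table_) == 32
            assert len(screen.selection_.table_) == 8
        assert hits >= 24  # strong signal: first-ranked nearly always

    def test_all_noise_often_prefers_null(self, rng):
        null_best = 0
        for _ in range(40):
            X, y = pk.simulate_contrast_regression(
                19, {"A": 0.0, "B": 0.0, "C": 0.0}, sigma=0.5, seed=rng)
            sel = AICcModelSelection().fit(X, y)
            null_best += sel.table_["model"].iloc[0] == "Null"
        # the null is the plurality winner among the 8 candidates
        assert null_best >= 14

    def test_functional_wrapper_equivalence(self, rng):
        X, y = pk.simulate_contrast_regression(
            19, {"A": 0.7, "B": 0.0}, seed=1234)
        a = pk.two_stage_screen(y, X, top_k=1)
        b = pk.TwoStageModelSelection(top_k=1).fit(X, y)
        pd.testing.assert_series_equal(a.stage1_rvi_, b.stage1_rvi_)
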