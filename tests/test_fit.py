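"""Model fitting: least squares, logistic ML, FP selection, estimator facade."""

import math

import numpy as np
import pytest
from scipy import stats

import covadjust as ca
from covadjust.basis import CovariateBasis
from covadjust.fit import TreatmentEffectEstimator


def _random_trial(rng, n=120, binary=False):
    arm = (rng.random(n) < 0.5).astype(float)
    x = rng.standard_normal(n)
    lin = 0.3 * arm + 0.5 * x
    if binary:
        y = (lin + rng.logistic(0, 1, n) > 0).astype(float)
    else:
        y = lin + rng.standard_normal(n)
    return y, arm, x


class TestOls:
    def test_two_group_difference_in_means(self):
        res = ca.fit_ols([0.0, 1.0, 1.0, 2.0], [0, 0, 1, 1])
        assert res.beta_T_hat == pytest.approx(1.0)
        assert res.method == "unadjusted"

    def test_noise_free_fit_is_exact(self, rng):
        arm = (rng.random(60) < 0.5).astype(float)
        cols = rng.standard_normal((60, 3))
        y = 1.5 + 0.8 * arm + cols @ np.array([0.2, -0.4, 1.1])
        res = ca.fit_ols(y, arm, CovariateBasis("linear", cols))
        assert res.beta_T_hat == pytest.approx(0.8, abs=1e-8)
        assert res.deviance < 1e-16 * np.sum(y**2) + 1e-20

    def test_agrees_with_pseudoinverse_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(20, 60))
            d = int(rng.integers(0, 4))
            y, arm, _ = _random_trial(rng, n)
            cols = rng.standard_normal((n, d)) if d else None
            basis = CovariateBasis("linear", cols) if d is not None and d else None
            res = ca.fit_ols(y, arm, basis)
            X = np.column_stack([np.ones(n), arm] + ([cols] if d else []))
            beta = np.linalg.pinv(X) @ y
            resid = y - X @ beta
            sigma2 = resid @ resid / (n - X.shape[1])
            se = math.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            t = beta[1] / se
            p = 2 * stats.t.sf(abs(t), n - X.shape[1])
            assert res.beta_T_hat == pytest.approx(beta[1], abs=1e-8)
            assert res.se == pytest.approx(se, abs=1e-8)
            assert res.p_value == pytest.approx(p, abs=1e-8)

    def test_invariant_to_constant_column_shift(self, rng):
        y, arm, x = _random_trial(rng)
        a = ca.fit_ols(y, arm, CovariateBasis("linear", x[:, None]))
        b = ca.fit_ols(y, arm, CovariateBasis("linear", x[:, None] + 57.0))
        assert a.beta_T_hat == pytest.approx(b.beta_T_hat, abs=1e-10)
        assert a.se == pytest.approx(b.se, abs=1e-10)

    def test_rank_deficient_basis_dropped_with_warning(self, rng):
        y, arm, x = _random_trial(rng)
        dup = np.column_stack([x, x])  # identical columns
        with pytest.warns(UserWarning, match="rank deficient"):
            res = ca.fit_ols(y, arm, CovariateBasis("linear", dup))
        ref = ca.fit_ols(y, arm, CovariateBasis("linear", x[:, None]))
        assert res.n_dropped == 1
        assert res.beta_T_hat == pytest.approx(ref.beta_T_hat, abs=1e-10)


class TestLogistic:
    def test_two_by_two_closed_form(self):
        # arm 0: 30 events / 20 non-events; arm 1: 20 events / 30 non-events
        arm = np.repeat([0.0, 1.0], 50)
        y = np.concatenate([np.ones(30), np.zeros(20), np.ones(20), np.zeros(30)])
        res = ca.fit_logistic(y, arm)
        assert res.beta_T_hat == pytest.approx(math.log(400 / 900), abs=1e-6)
        se = math.sqrt(1 / 30 + 1 / 20 + 1 / 20 + 1 / 30)
        assert res.se == pytest.approx(se, abs=1e-6)

    def test_null_estimate_near_zero(self, rng):
        n = 4000
        arm = (rng.random(n) < 0.5).astype(float)
        y = (rng.random(n) < 0.5).astype(float)
        res = ca.fit_logistic(y, arm)
        assert abs(res.beta_T_hat) < 3 * res.se

    def test_agrees_with_generic_optimiser_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(50):
            n = int(rng.integers(60, 150))
            d = int(rng.integers(0, 3))
            arm = (rng.random(n) < 0.5).astype(float)
            cols = rng.standard_normal((n, d))
            eta = -0.2 + 0.5 * arm + (cols @ rng.normal(0, 0.5, d) if d else 0.0)
            y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
            if y.min() == y.max() or arm.min() == arm.max():
                continue
            basis = CovariateBasis("linear", cols) if d else None
            res = ca.fit_logistic(y, arm, basis)
            X = np.column_stack([np.ones(n), arm] + ([cols] if d else []))
            oracle = sm.Logit(y, X).fit(disp=0)
            assert res.deviance == pytest.approx(-2 * oracle.llf, abs=1e-6)
            assert res.beta_T_hat == pytest.approx(oracle.params[1], abs=1e-6)
            assert res.se == pytest.approx(oracle.bse[1], rel=1e-5)

    def test_perfect_separation_flagged_not_raised(self):
        arm = np.repeat([0.0, 1.0], 25)
        res = ca.fit_logistic(arm.copy(), arm)
        assert not res.converged

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            ca.fit_logistic(np.ones(40), np.tile([0.0, 1.0], 20))


class TestFpSelection:
    def test_true_linear_model_selects_power_one(self, rng):
        arm = (rng.random(200) < 0.5).astype(float)
        x = rng.standard_normal(200)
        y = 0.5 * arm + 0.8 * x + rng.normal(0, 1e-7, 200)
        res = ca.fit_fp(y, arm, x, order=1, family="continuous")
        assert res.selected_powers == (1.0,)

    @pytest.mark.parametrize("binary", [False, True])
    def test_nesting_fp2_fp1_linear(self, binary, rng):
        y, arm, x = _random_trial(rng, n=200, binary=binary)
        family = "binary" if binary else "continuous"
        fp1 = ca.fit_fp(y, arm, x, order=1, family=family)
        fp2 = ca.fit_fp(y, arm, x, order=2, family=family)
        lin = (ca.fit_logistic if binary else ca.fit_ols)(
            y, arm, ca.build_basis(x, "linear")
        )
        assert fp2.deviance <= fp1.deviance + 1e-9
        assert fp1.deviance <= lin.deviance + 1e-9

    def test_linear_equals_fp1_when_power_one_selected(self, rng):
        arm = (rng.random(150) < 0.5).astype(float)
        x = rng.standard_normal(150)
        y = 0.4 * arm + 0.9 * x + rng.normal(0, 1e-6, 150)
        fp1 = ca.fit_fp(y, arm, x, order=1, family="continuous")
        assert fp1.selected_powers == (1.0,)
        lin = ca.fit_ols(y, arm, ca.build_basis(x, "linear"))
        assert fp1.beta_T_hat == pytest.approx(lin.beta_T_hat, abs=1e-10)
        assert fp1.se == pytest.approx(lin.se, abs=1e-10)

    def test_bad_order_rejected(self, rng):
        y, arm, x = _random_trial(rng)
        with pytest.raises(ValueError):
            ca.fit_fp(y, arm, x, order=3, family="continuous")


class TestAnalyzeAllMethods:
    def test_seven_distinct_methods(self, rng):
        y, arm, x = _random_trial(rng, n=100)
        results = ca.analyze_all_methods(ca.TrialData(arm, x, y), "continuous")
        assert [r.method for r in results] == list(ca.METHODS)

    def test_low_noise_linear_all_methods_near_truth(self, rng):
        arm = (rng.random(400) < 0.5).astype(float)
        x = rng.standard_normal(400)
        y = 1.0 * arm + 0.5 * x + rng.normal(0, 0.05, 400)
        results = ca.analyze_all_methods(ca.TrialData(arm, x, y), "continuous")
        for r in results:
            assert abs(r.beta_T_hat - 1.0) < 3 * r.se, r.method

    def test_failures_flagged_not_raised(self, rng):
        arm = (rng.random(60) < 0.5).astype(float)
        x = np.ones(60)  # constant covariate breaks several methods
        y = arm + rng.standard_normal(60)
        with pytest.warns(UserWarning):
            results = ca.analyze_all_methods(ca.TrialData(arm, x, y), "continuous")
        assert len(results) == 7
        assert any(r.error for r in results)

    def test_p_values_uniform_under_null(self):
        # Wald p of the linear-adjusted OLS over null replicates is Uniform(0,1)
        from covadjust._engine import analyze_batch, simulate_batch

        spec = ca.make_scenario("continuous", "linear", effect="null", reps=5000, seed=77)
        arm, x, y = simulate_batch(spec)
        res = analyze_batch(arm, x, y, "continuous", methods=("linear",))["linear"]
        ks = stats.kstest(res.p_value, "uniform")
        assert ks.pvalue > 0.001


class TestEstimatorFacade:
    def test_sklearn_protocol(self):
        from sklearn.base import clone

        est = TreatmentEffectEstimator(method="rcs3", family="binary")
        assert clone(est).get_params() == {"method": "rcs3", "family": "binary"}
        est.set_params(method="linear")
        assert est.method == "linear"

    def test_matches_functional_api(self, rng):
        y, arm, x = _random_trial(rng, n=150)
        est = TreatmentEffectEstimator(method="categorised").fit(
            np.column_stack([arm, x]), y
        )
        ref = ca.fit_ols(y, arm, ca.build_basis(x, "categorised"))
        assert est.effect_ == ref.beta_T_hat
        assert est.p_value_ == ref.p_value
        lo, hi = est.conf_int()
        assert lo < est.effect_ < hi

    def test_unadjusted_binary_matches_cross_product_ratio(self):
        arm = np.repeat([0.0, 1.0], 50)
        y = np.concatenate([np.ones(30), np.zeros(20), np.ones(20), np.zeros(30)])
        x = np.linspace(-1, 1, 100)
        est = TreatmentEffectEstimator(method="unadjusted", family="binary").fit(
            np.column_stack([arm, x]), y
        )
        assert est.effect_ == pytest.approx(math.log(400 / 900), abs=1e-6)
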