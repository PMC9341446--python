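"""Threshold Poisson dose-response models: likelihood, fitting, comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import poisson

import heatrisk as hr
from heatrisk.dose_response import MODEL_KINDS, N_FREE, ThresholdPoissonRegressor

HOCKEY = hr.ModelParams(kind="hockey", beta1=1.0, beta2=4.4, tw=27.9)
TWO_STEP = hr.ModelParams(
    kind="two_step", beta1=0.6, beta2=1.4, beta3=9.0, tw1=25.5, tw2=30.5
)
EXP = hr.ModelParams(kind="exponential", beta1=0.4, r=0.4, tw=22.7)


def cases(wbgt, counts, population=1e6) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "wbgt_c": np.asarray(wbgt, dtype=float),
            "count": np.asarray(counts),
            "population": population,
        }
    )


class TestPredictRisk:
    def test_constant_below_threshold(self):
        assert hr.predict_risk(HOCKEY, 20.0) == 1.0
        assert hr.predict_risk(EXP, 20.0) == 0.4

    def test_hockey_linear_rise(self):
        # beta1 + beta2*(30 - 27.9)
        assert hr.predict_risk(HOCKEY, 30.0) == pytest.approx(1.0 + 4.4 * 2.1)

    def test_exponential_at_threshold_equals_baseline(self):
        assert hr.predict_risk(EXP, 22.7) == pytest.approx(0.4)

    def test_two_step_middle_and_upper_segments(self):
        assert hr.predict_risk(TWO_STEP, 28.0) == pytest.approx(0.6 + 1.4 * 2.5)
        assert hr.predict_risk(TWO_STEP, 32.0) == pytest.approx(
            0.6 + 1.4 * 5.0 + 9.0 * 1.5
        )

    def test_unknown_model_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown model"):
            hr.ModelParams(kind="spline", beta1=1.0)

    @pytest.mark.parametrize("params", [HOCKEY, TWO_STEP, EXP], ids=lambda p: p.kind)
    def test_continuity_at_thresholds(self, params):
        thresholds = [t for t in (params.tw, params.tw1, params.tw2) if t is not None]
        for tw in thresholds:
            left = hr.predict_risk(params, tw - 1e-11)
            right = hr.predict_risk(params, tw + 1e-11)
            assert abs(left - right) < 1e-9

    def test_two_step_with_equal_gradients_nests_hockey(self):
        ts = hr.ModelParams(
            kind="two_step", beta1=1.0, beta2=4.4, beta3=4.4, tw1=27.9, tw2=30.0
        )
        T = np.linspace(20, 35, 301)
        np.testing.assert_allclose(
            hr.predict_risk(ts, T), hr.predict_risk(HOCKEY, T), rtol=0, atol=1e-12
        )

    def test_exponential_with_vanishing_rate_tends_to_constant(self):
        flat = hr.ModelParams(kind="exponential", beta1=0.4, r=1e-8, tw=22.7)
        T = np.linspace(10, 40, 50)
        np.testing.assert_allclose(hr.predict_risk(flat, T), 0.4, rtol=1e-6)


class TestPoissonLoglik:
    def test_unit_mean_zero_count(self):
        assert hr.poisson_loglik(HOCKEY, cases([20.0], [0])) == pytest.approx(-1.0)

    def test_additive_over_disjoint_subsets(self):
        rng = np.random.default_rng(0)
        d1 = cases(rng.uniform(20, 33, 8), rng.integers(0, 5, 8))
        d2 = cases(rng.uniform(20, 33, 6), rng.integers(0, 5, 6))
        both = pd.concat([d1, d2], ignore_index=True)
        assert hr.poisson_loglik(HOCKEY, both) == pytest.approx(
            hr.poisson_loglik(HOCKEY, d1) + hr.poisson_loglik(HOCKEY, d2)
        )

    def test_matches_scipy_mass_function(self):
        data = cases([21.0, 26.0, 29.0, 31.5, 33.0], [0, 1, 4, 9, 20], 2.5e6)
        lam = hr.predict_risk(HOCKEY, data["wbgt_c"].to_numpy()) * 2.5
        oracle = float(np.sum(poisson.logpmf(data["count"].to_numpy(), lam)))
        assert hr.poisson_loglik(HOCKEY, data) == pytest.approx(oracle)

    def test_zero_mean_positive_count_is_neg_inf(self):
        zero = hr.ModelParams(kind="hockey", beta1=0.0, beta2=1.0, tw=28.0)
        assert hr.poisson_loglik(zero, cases([20.0], [3])) == -np.inf

    def test_zero_mean_zero_count_contributes_nothing(self):
        zero = hr.ModelParams(kind="hockey", beta1=0.0, beta2=1.0, tw=28.0)
        assert hr.poisson_loglik(zero, cases([20.0], [0])) == 0.0


class TestFit:
    def test_mle_beats_brute_force_grid(self):
        """Profiled MLE must dominate a coarse (threshold x beta) box search."""
        data = cases([22.0, 24.0, 26.0, 28.0, 30.0], [1, 0, 2, 5, 9], 1e6)
        est = ThresholdPoissonRegressor(model="hockey", grid_step=0.5)
        est.fit(data["wbgt_c"], data["count"], population=1e6)
        best_grid = -np.inf
        for tw in np.arange(23.0, 29.5, 0.5):
            for b1 in np.arange(0.1, 3.1, 0.1):
                for b2 in np.arange(0.0, 6.0, 0.2):
                    p = hr.ModelParams(kind="hockey", beta1=b1, beta2=b2, tw=tw)
                    best_grid = max(best_grid, hr.poisson_loglik(p, data))
        assert est.loglik_ >= best_grid - 1e-9

    def test_superset_model_never_fits_worse(self, tokyo_cases):
        hockey = hr.fit_model(tokyo_cases, "hockey", grid_step=0.5, age_group="65+")
        two = hr.fit_model(tokyo_cases, "two_step", grid_step=0.5, age_group="65+")
        assert two.loglik >= hockey.loglik - 1e-6

    def test_aic_identity(self, elderly_exp_fit):
        fit = elderly_exp_fit
        assert fit.aic == 2 * fit.k - 2 * fit.loglik
        assert fit.k == N_FREE["exponential"] == 3

    def test_vcov_symmetric_psd(self, elderly_exp_fit):
        V = elderly_exp_fit.vcov
        assert np.allclose(V, V.T)
        assert np.all(np.linalg.eigvalsh(V) >= -1e-12)

    def test_recovers_simulation_truth(self, elderly_exp_fit):
        """Point estimates land near the generating parameters (single run)."""
        truth = hr.tokyo_like_truth().params["65+"]
        p = elderly_exp_fit.params
        assert p.tw == pytest.approx(truth.tw, abs=0.5)
        assert p.r == pytest.approx(truth.r, abs=0.05)
        assert p.beta1 == pytest.approx(truth.beta1, abs=0.1)

    def test_no_admissible_threshold_rejected(self):
        data = cases([25.0, 25.0, 25.0], [1, 2, 1])
        with pytest.raises(ValueError, match="threshold"):
            ThresholdPoissonRegressor(model="hockey").fit(
                data["wbgt_c"], data["count"]
            )

    def test_sklearn_param_interface(self):
        est = ThresholdPoissonRegressor(model="hockey", grid_step=0.25)
        assert est.get_params()["grid_step"] == 0.25
        est.set_params(model="exponential")
        assert est.model == "exponential"


class TestCompareModels:
    def _fit(self, kind, aic):
        params = {"hockey": HOCKEY, "two_step": TWO_STEP, "exponential": EXP}[kind]
        return hr.FitResult(
            params=params, loglik=-aic / 2, aic=aic, vcov=np.eye(2), n_obs=10
        )

    def test_smallest_aic_wins(self):
        fits = [
            self._fit("hockey", 2493.8),
            self._fit("two_step", 2467.3),
            self._fit("exponential", 2456.0),
        ]
        assert hr.compare_models(fits).params.kind == "exponential"

    def test_single_fit_returns_itself(self):
        fit = self._fit("hockey", 100.0)
        assert hr.compare_models([fit]) is fit

    def test_tie_broken_by_fewest_parameters(self):
        fits = [self._fit("two_step", 100.0), self._fit("hockey", 100.0)]
        assert hr.compare_models(fits).params.kind == "hockey"

    def test_tie_broken_by_declaration_order(self):
        fits = [self._fit("exponential", 100.0), self._fit("hockey", 100.0)]
        assert hr.compare_models(fits).params.kind == "hockey"
        assert MODEL_KINDS.index("hockey") < MODEL_KINDS.index("exponential")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hr.compare_models([])


class TestMae:
    def test_perfect_predictions_have_zero_mae(self):
        fit = hr.FitResult(
            params=hr.ModelParams(kind="hockey", beta1=2.0, beta2=1.0, tw=28.0),
            loglik=0.0, aic=0.0, vcov=np.eye(2), n_obs=3,
        )
        T = np.array([24.0, 27.0, 30.0])
        counts = hr.predict_risk(fit.params, T).astype(int)  # 2, 2, 4: exact
        diag = hr.mae_by_wbgt(fit, cases(T, counts))
        assert np.all(diag.table["mae"].to_numpy() == 0.0)
        assert diag.max_mae == 0.0

    def test_group_mae_is_mean_absolute_error(self):
        fit = hr.FitResult(
            params=hr.ModelParams(kind="hockey", beta1=2.0, beta2=0.0, tw=30.0),
            loglik=0.0, aic=0.0, vcov=np.eye(2), n_obs=2,
        )
        # two days at the same WBGT, per-million obs 1 and 5 vs prediction 2
        data = cases([25.0, 25.0], [1, 5])
        diag = hr.mae_by_wbgt(fit, data)
        assert len(diag.table) == 1
        assert diag.max_mae == pytest.approx((1 + 3) / 2)
        assert diag.max_mae_wbgt == pytest.approx(25.0)

    def test_empty_data_rejected(self, elderly_exp_fit):
        with pytest.raises(ValueError):
            hr.mae_by_wbgt(elderly_exp_fit, pd.DataFrame(columns=["wbgt_c", "count", "population"]))


class TestBootstrap:
    def test_same_seed_reproduces_draws(self, elderly_exp_fit):
        a = hr.bootstrap_params(elderly_exp_fit, 50, seed=7)
        b = hr.bootstrap_params(elderly_exp_fit, 50, seed=7)
        assert all(x == y for x, y in zip(a, b))

    def test_nonpositive_b_rejected(self, elderly_exp_fit):
        with pytest.raises(ValueError):
            hr.bootstrap_params(elderly_exp_fit, 0, seed=1)

    def test_draw_mean_near_point_estimate(self, elderly_exp_fit):
        B = 5000
        draws = hr.bootstrap_params(elderly_exp_fit, B, seed=3)
        arr = np.array([d.free_values() for d in draws])
        center = elderly_exp_fit.params.free_values()
        se_mean = np.sqrt(np.diag(elderly_exp_fit.vcov) / B)
        # allow slack for constraint-truncation of the normal
        assert np.all(np.abs(arr.mean(axis=0) - center) < 4 * se_mean + 1e-4)

    def test_thresholds_held_fixed(self, elderly_exp_fit):
        draws = hr.bootstrap_params(elderly_exp_fit, 20, seed=5)
        assert {d.tw for d in draws} == {elderly_exp_fit.params.tw}

    def test_constraints_respected(self, elderly_exp_fit):
        draws = hr.bootstrap_params(elderly_exp_fit, 500, seed=9)
        assert all(d.beta1 >= 0 for d in draws)

    def test_case_resampling_mode(self, tokyo_cases, elderly_exp_fit):
        sub = tokyo_cases[tokyo_cases["age_group"] == "65+"]
        sub = sub[pd.to_datetime(sub["date"]).dt.month.isin([5, 6, 7, 8, 9])]
        draws = hr.bootstrap_params(
            elderly_exp_fit, 3, seed=2, data=sub, method="case", grid_step=0.5
        )
        assert len(draws) == 3
        assert all(d.kind == "exponential" for d in draws)
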