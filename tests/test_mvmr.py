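"""Multivariable MR: oracle equivalence, sensitivity variants, conditional F."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import statsmodels.api as sm

from mrmediate.datatypes import HarmonizedDataset
from mrmediate.errors import InsufficientInstrumentsError, SingularDesignError
from mrmediate.instruments import compute_instrument_strength, harmonize
from mrmediate.mvmr import conditional_f, mv_egger, mv_ivw, mv_lasso, mv_median
from mrmediate.simulate import SimulationConfig, simulate_study_triple
from mrmediate.uvmr import EstimatorOptions, ivw

from conftest import make_table


def mv_dataset(X, Gamma, se_Gamma, se_X=None, exposure_ids=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if se_X is None:
        se_X = np.full_like(X, 0.01)
    K = X.shape[1]
    return HarmonizedDataset(
        snp_ids=[f"rs{i}" for i in range(X.shape[0])],
        exposure_betas=X,
        exposure_ses=se_X,
        outcome_betas=np.asarray(Gamma, dtype=float),
        outcome_ses=np.asarray(se_Gamma, dtype=float),
        exposure_ids=exposure_ids or [f"x{k}" for k in range(K)],
    )


BLOCK_X = np.array([[0.1, 0.0], [0.2, 0.0], [0.0, 0.1], [0.0, 0.2]])
BLOCK_Y = np.array([0.05, 0.10, 0.02, 0.04])


class TestMvIvw:
    def test_block_design_decouples_exactly(self):
        data = mv_dataset(BLOCK_X, BLOCK_Y, [0.01] * 4)
        result = mv_ivw(data)
        betas = [e.beta for e in result.estimates]
        np.testing.assert_allclose(betas, [0.5, 0.2], atol=1e-12)

    def test_duplicated_exposure_is_singular(self):
        X = np.column_stack([BLOCK_X[:, 0], BLOCK_X[:, 0]])
        with pytest.raises(SingularDesignError):
            mv_ivw(mv_dataset(X, BLOCK_Y, [0.01] * 4))

    def test_k1_reduces_to_univariable_ivw(self, null_triple):
        _, exposure, _, outcome, _ = null_triple
        data = harmonize(exposure, outcome)
        uni = ivw(data)
        multi = mv_ivw(data)
        assert multi.estimates[0].beta == pytest.approx(uni.beta, abs=1e-12)
        assert multi.estimates[0].se == pytest.approx(uni.se, abs=1e-12)

    def test_j_not_greater_than_k_is_error(self):
        with pytest.raises(InsufficientInstrumentsError):
            mv_ivw(mv_dataset(np.eye(2) * 0.1, [0.05, 0.02], [0.01, 0.01]))

    def test_permuting_exposures_permutes_estimates(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0.1, 0.05, (10, 3))
        y = X @ [0.5, 0.2, -0.1] + rng.normal(0, 0.01, 10)
        d1 = mv_dataset(X, y, [0.01] * 10, exposure_ids=["a", "b", "c"])
        d2 = mv_dataset(X[:, [2, 0, 1]], y, [0.01] * 10, exposure_ids=["c", "a", "b"])
        r1 = mv_ivw(d1)
        r2 = mv_ivw(d2)
        for name in ("a", "b", "c"):
            assert r1.estimate_for(name).beta == pytest.approx(
                r2.estimate_for(name).beta, abs=1e-12
            )

    @given(st.integers(0, 5_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_wls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        J, K = 12, 3
        X = rng.normal(0.1, 0.05, (J, K))
        y = rng.normal(0, 0.05, J)
        se = rng.uniform(0.01, 0.05, J)
        result = mv_ivw(mv_dataset(X, y, se), EstimatorOptions(ivw_model="fixed"))
        res = sm.WLS(y, X, weights=1 / se**2).fit()
        for k in range(K):
            assert result.estimates[k].beta == pytest.approx(res.params[k], abs=1e-10)
            assert result.estimates[k].se == pytest.approx(
                res.bse[k] / np.sqrt(res.scale), abs=1e-10
            )

    def test_two_exposure_parameter_recovery(self):
        """Simulated 2-exposure model with true direct effects (0.5, 0.2):
        mean estimates within 0.03 over repeated draws."""
        rng = np.random.default_rng(99)
        est = np.zeros(2)
        n_rep = 60
        for _ in range(n_rep):
            J = 100
            X_true = rng.normal(0.0, 0.1, (J, 2))
            se_x = np.full((J, 2), 0.005)
            se_y = np.full(J, 0.005)
            X = X_true + rng.normal(0, se_x)
            y = X_true @ [0.5, 0.2] + rng.normal(0, se_y)
            result = mv_ivw(mv_dataset(X, y, se_y, se_x))
            est += [e.beta for e in result.estimates]
        est /= n_rep
        np.testing.assert_allclose(est, [0.5, 0.2], atol=0.03)


class TestMvEgger:
    def test_slope_equals_mv_ivw_when_intercept_exactly_zero(self):
        data = mv_dataset(BLOCK_X, BLOCK_Y, [0.01] * 4)
        # exact fit through the origin: fitted intercept is 0
        egger = mv_egger(data)
        ivw_r = mv_ivw(data)
        assert egger.egger_intercept == pytest.approx(0.0, abs=1e-12)
        for a, b in zip(egger.estimates, ivw_r.estimates):
            assert a.beta == pytest.approx(b.beta, abs=1e-10)

    def test_j_equal_k_plus_one_is_error(self):
        X = np.array([[0.1, 0.0], [0.0, 0.1], [0.1, 0.1]])
        with pytest.raises(InsufficientInstrumentsError):
            mv_egger(mv_dataset(X, [0.05, 0.02, 0.07], [0.01] * 3))

    def test_intercept_near_zero_on_clean_simulated_data(self):
        intercepts = []
        for s in range(20):
            rng = np.random.default_rng(700 + s)
            J = 80
            X_true = rng.normal(0.0, 0.1, (J, 2))
            X = X_true + rng.normal(0, 0.005, (J, 2))
            y = X_true @ [0.5, 0.2] + rng.normal(0, 0.005, J)
            egger = mv_egger(mv_dataset(X, y, np.full(J, 0.005)))
            intercepts.append(egger.egger_intercept)
        assert abs(np.median(intercepts)) < 0.002


class TestMvMedian:
    def test_exact_linear_fit_recovered(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0.1, 0.05, (12, 2))
        y = X @ [0.5, 0.2]
        result = mv_median(mv_dataset(X, y, [0.01] * 12), EstimatorOptions(median_bootstrap_B=500))
        betas = [e.beta for e in result.estimates]
        np.testing.assert_allclose(betas, [0.5, 0.2], atol=1e-6)

    def test_robust_to_contaminated_outcomes(self):
        rng = np.random.default_rng(8)
        J = 60
        X_true = rng.normal(0.0, 0.1, (J, 2))
        X = X_true + rng.normal(0, 0.005, (J, 2))
        y = X_true @ [0.5, 0.2] + rng.normal(0, 0.005, J)
        y[: J * 3 // 10] += 0.05  # 30% directional contamination
        data = mv_dataset(X, y, np.full(J, 0.005))
        med_b = mv_median(data, EstimatorOptions(median_bootstrap_B=500)).estimates[0].beta
        ivw_b = mv_ivw(data).estimates[0].beta
        assert abs(med_b - 0.5) < abs(ivw_b - 0.5)

    def test_k1_equal_weight_case_matches_weighted_median(self):
        # with constant gamma and constant outcome SE both estimators reduce
        # to the plain median of the Wald ratios
        from mrmediate.uvmr import weighted_median

        rng = np.random.default_rng(13)
        J = 21
        gamma = np.full(J, 0.1)
        y = 0.5 * gamma + rng.normal(0, 0.01, J)
        data = mv_dataset(gamma[:, None], y, np.full(J, 0.01), np.full((J, 1), 0.001))
        wm = weighted_median(data, EstimatorOptions(median_bootstrap_B=200, seed=0))
        mvm = mv_median(data, EstimatorOptions(median_bootstrap_B=500, seed=0))
        assert mvm.estimates[0].beta == pytest.approx(wm.beta, abs=1e-6)
        assert mvm.estimates[0].se == pytest.approx(wm.se, rel=0.5)


class TestMvLasso:
    def test_large_lambda_equals_mv_ivw_exactly(self):
        from mrmediate.estimators import MVLassoRegressor

        rng = np.random.default_rng(3)
        X = rng.normal(0.1, 0.05, (15, 2))
        y = X @ [0.5, 0.2] + rng.normal(0, 0.01, 15)
        se = np.full(15, 0.01)
        lasso = MVLassoRegressor(lam=1e9).fit(X, y, y_se=se)
        ref = mv_ivw(mv_dataset(X, y, se))
        assert lasso.valid_mask_.all()
        np.testing.assert_allclose(lasso.coef_, [e.beta for e in ref.estimates], atol=1e-10)

    def test_clean_data_retains_all_snps(self):
        rng = np.random.default_rng(4)
        J = 40
        X_true = rng.normal(0.0, 0.1, (J, 2))
        X = X_true + rng.normal(0, 0.005, (J, 2))
        y = X_true @ [0.5, 0.2] + rng.normal(0, 0.005, J)
        data = mv_dataset(X, y, np.full(J, 0.005))
        result = mv_lasso(data)
        assert len(result.retained_snp_ids) == J
        ref = mv_ivw(data)
        for a, b in zip(result.estimates, ref.estimates):
            assert a.beta == pytest.approx(b.beta, abs=1e-8)

    def test_pleiotropic_snp_excluded_and_estimate_improves(self):
        rng = np.random.default_rng(6)
        J = 40
        X_true = rng.normal(0.0, 0.1, (J, 2))
        X = X_true + rng.normal(0, 0.005, (J, 2))
        y = X_true @ [0.5, 0.2] + rng.normal(0, 0.005, J)
        y[7] += 10 * 0.005  # one 10-SE pleiotropic shift
        data = mv_dataset(X, y, np.full(J, 0.005))
        result = mv_lasso(data)
        assert "rs7" not in result.retained_snp_ids
        ref = mv_ivw(data)
        assert abs(result.estimates[0].beta - 0.5) < abs(ref.estimates[0].beta - 0.5)

    def test_retained_set_monotone_in_lambda(self):
        from mrmediate.estimators import MVLassoRegressor

        rng = np.random.default_rng(9)
        J = 30
        X = rng.normal(0.1, 0.05, (J, 2))
        y = X @ [0.5, 0.2] + rng.normal(0, 0.02, J)
        se = np.full(J, 0.02)
        masks = []
        for lam in [400.0, 200.0, 120.0, 80.0]:
            fit = MVLassoRegressor(lam=lam).fit(X, y, y_se=se)
            masks.append(set(np.flatnonzero(fit.valid_mask_)))
        for bigger, smaller in zip(masks, masks[1:]):
            assert smaller <= bigger


class TestConditionalF:
    def test_k1_matches_overall_instrument_f(self):
        # the summary-data statistic agrees with the R^2-based overall F in
        # the small-R^2 regime (each is ~ mean per-SNP chi-square there)
        cfg = SimulationConfig(
            seed=21, J=20, sigma_gamma=0.02, tau_direct=0.5, delta=0.0, beta2=0.0
        )
        exposure, _, outcome, _ = simulate_study_triple(cfg)
        data = harmonize(exposure, outcome)
        f_cond = conditional_f(data)[0]
        overall = compute_instrument_strength(exposure).overall_f
        assert f_cond == pytest.approx(overall, rel=0.02)

    def test_block_orthogonal_design_close_to_marginal(self):
        rng = np.random.default_rng(11)
        J = 60
        X_true = np.zeros((J, 2))
        X_true[: J // 2, 0] = rng.normal(0, 0.1, J // 2)
        X_true[J // 2 :, 1] = rng.normal(0, 0.1, J // 2)
        X = X_true + rng.normal(0, 0.005, (J, 2))
        data = mv_dataset(X, np.zeros(J), np.full(J, 0.005), np.full((J, 2), 0.005))
        f_cond = conditional_f(data)
        # marginal mean chi-square per exposure
        marginal = (X / 0.005) ** 2
        for k in range(2):
            assert f_cond[k] == pytest.approx(marginal[:, k].sum() / (J - 1), rel=0.10)

    def test_collinear_exposures_flagged_weak(self):
        rng = np.random.default_rng(12)
        J = 60
        x1 = rng.normal(0, 0.1, J)
        x2 = 0.99 * x1 + rng.normal(0, 0.002, J)
        X = np.column_stack([x1, x2]) + rng.normal(0, 0.005, (J, 2))
        data = mv_dataset(X, np.zeros(J), np.full(J, 0.005), np.full((J, 2), 0.005))
        f_cond = conditional_f(data)
        marginal = ((X / 0.005) ** 2).sum(axis=0) / J
        assert np.all(f_cond < 10)
        assert np.all(f_cond < marginal / 10)
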