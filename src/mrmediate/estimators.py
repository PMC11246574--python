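"""Mendelian randomization estimators with a scikit-learn interface.

Every estimator regresses SNP-outcome effects ``y`` (Gamma, length J) on
SNP-exposure effects ``X`` (gamma, J x K) with inverse-variance weights
``1 / y_se**2``, following the two-sample summary-data MR setup. They
follow scikit-learn conventions: hyper-parameters are set in ``__init__``,
``fit(X, y, y_se=...)`` computes trailing-underscore attributes, and
``predict(X)`` returns fitted SNP-outcome effects, so the classes compose
with ``sklearn.base.clone`` and pipeline machinery.

Fitted attributes common to the regression-based estimators:

``coef_`` (K,), ``se_`` (K,), ``ci_`` (K, 2), ``pval_`` (K,)
    Causal-effect estimates per exposure with 95% normal intervals.
``q_stat_``, ``q_df_``, ``q_pval_``, ``i2_``
    Cochran heterogeneity of the weighted fit.

Error model: by default standard errors use multiplicative random effects —
the weighted-regression standard error inflated by
``sqrt(max(1, Q / df))`` — which is never narrower than the fixed-effect
model; ``model="fixed"`` disables the inflation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import (
    ConfigurationError,
    EstimationError,
    InsufficientInstrumentsError,
    SingularDesignError,
)

Z95 = stats.norm.ppf(0.975)


def _as_design(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("X must be 1- or 2-dimensional")
    return X


def _check_inputs(X, y, y_se):
    X = _as_design(X)
    y = np.asarray(y, dtype=float).ravel()
    if y_se is None:
        raise ValueError("y_se (outcome standard errors) is required")
    y_se = np.asarray(y_se, dtype=float).ravel()
    if not (len(y) == X.shape[0] == len(y_se)):
        raise ValueError("X, y and y_se must agree in length")
    if np.any(y_se <= 0):
        raise ValueError("y_se entries must be > 0")
    if np.isnan(X).any() or np.isnan(y).any() or np.isnan(y_se).any():
        raise ValueError("missing values are not allowed")
    return X, y, y_se


def _name_collinear(D: np.ndarray) -> str:
    """Best-effort description of which design columns are collinear."""
    K = D.shape[1]
    with np.errstate(invalid="ignore"):
        c = np.corrcoef(D, rowvar=False)
    pairs = [
        (i, j)
        for i in range(K)
        for j in range(i + 1, K)
        if not np.isfinite(c[i, j]) or abs(c[i, j]) > 0.9999
    ]
    if pairs:
        return "collinear exposure columns: " + ", ".join(f"({i}, {j})" for i, j in pairs)
    return "rank-deficient exposure design"


def _wls(D: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares: coefficients, unit-scale covariance, Q, df."""
    sw = np.sqrt(w)
    A = D * sw[:, None]
    b = y * sw
    xtx = A.T @ A
    if np.linalg.matrix_rank(xtx, tol=1e-10 * max(1.0, np.abs(xtx).max())) < D.shape[1]:
        raise SingularDesignError(_name_collinear(D))
    cov_unit = np.linalg.inv(xtx)
    coef = cov_unit @ (A.T @ b)
    resid = y - D @ coef
    q = float(np.sum(w * resid**2))
    df = D.shape[0] - D.shape[1]
    return coef, cov_unit, q, df


def _finalize(coef, cov_unit, q, df, model):
    if model not in {"fixed", "multiplicative_random"}:
        raise ConfigurationError(f"unknown error model {model!r}")
    phi = max(1.0, q / df) if (model == "multiplicative_random" and df > 0) else 1.0
    se = np.sqrt(np.diag(cov_unit) * phi)
    pval = np.clip(2.0 * stats.norm.sf(np.abs(coef) / se), np.finfo(float).tiny, 1.0)
    ci = np.column_stack([coef - Z95 * se, coef + Z95 * se])
    q_pval = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    i2 = float(max(0.0, (q - df) / q)) if q > 0 else 0.0
    return se, pval, ci, q_pval, i2


class _BaseMRRegressor(RegressorMixin, BaseEstimator):
    """Shared predict/validation plumbing for the MR regressions."""

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coef_"):
            raise EstimationError("estimator is not fitted")
        X = _as_design(X)
        pred = X @ self.coef_
        intercept = getattr(self, "intercept_", 0.0)
        return pred + intercept


class IVWRegressor(_BaseMRRegressor):
    """Inverse-variance weighted regression through the origin.

    The primary MR estimator: with one exposure this is the classical IVW
    meta-analysis of Wald ratios; with K >= 2 exposures it is multivariable
    IVW, each coefficient the effect of one exposure conditional on the
    others.

    Parameters
    ----------
    model : {"multiplicative_random", "fixed"}
        Standard-error model (see module docstring).
    """

    def __init__(self, model: str = "multiplicative_random"):
        self.model = model

    def fit(self, X, y, y_se=None):
        X, y, y_se = _check_inputs(X, y, y_se)
        J, K = X.shape
        if K == 1 and J < 2:
            raise InsufficientInstrumentsError(
                "IVW needs at least 2 SNPs; use wald_ratio for a single SNP"
            )
        if J <= K:
            raise InsufficientInstrumentsError(
                f"multivariable IVW needs J > K (got J={J}, K={K})"
            )
        w = 1.0 / y_se**2
        coef, cov_unit, q, df = _wls(X, y, w)
        se, pval, ci, q_pval, i2 = _finalize(coef, cov_unit, q, df, self.model)
        self.coef_, self.se_, self.pval_, self.ci_ = coef, se, pval, ci
        self.q_stat_, self.q_df_, self.q_pval_, self.i2_ = q, df, q_pval, i2
        self.n_snp_ = J
        self.n_features_in_ = K
        return self


class EggerRegressor(_BaseMRRegressor):
    """MR-Egger: weighted regression with an unconstrained intercept.

    SNPs are first oriented so the (first) exposure's effects are
    non-negative, which makes the intercept interpretable as the average
    directional pleiotropic effect; the slope is the pleiotropy-adjusted
    causal estimate (consistent under the InSIDE assumption). The intercept
    test (``intercept_pval_``) is the standard check for directional
    horizontal pleiotropy.
    """

    def __init__(self, model: str = "multiplicative_random"):
        self.model = model

    def fit(self, X, y, y_se=None):
        X, y, y_se = _check_inputs(X, y, y_se)
        J, K = X.shape
        if J < K + 2:
            raise InsufficientInstrumentsError(
                f"Egger regression needs J >= K + 2 (got J={J}, K={K})"
            )
        flip = np.where(X[:, 0] < 0, -1.0, 1.0)
        Xo = X * flip[:, None]
        yo = y * flip
        D = np.column_stack([np.ones(J), Xo])
        w = 1.0 / y_se**2
        coef, cov_unit, q, df = _wls(D, yo, w)
        se, pval, ci, q_pval, i2 = _finalize(coef, cov_unit, q, df, self.model)
        self.intercept_ = float(coef[0])
        self.intercept_se_ = float(se[0])
        self.intercept_pval_ = float(pval[0])
        self.coef_, self.se_, self.pval_, self.ci_ = coef[1:], se[1:], pval[1:], ci[1:]
        self.q_stat_, self.q_df_, self.q_pval_, self.i2_ = q, df, q_pval, i2
        self.n_snp_ = J
        self.n_features_in_ = K
        return self


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the cumulative midpoints.

    Sort the values; with normalized weights w, the j-th sorted value sits at
    cumulative midpoint ``s_j = cum_j - w_j / 2``; the weighted median is the
    linear interpolation of value against s evaluated at s = 1/2.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    order = np.argsort(values, kind="mergesort")
    v = values[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, v))


class WeightedMedianRegressor(_BaseMRRegressor):
    """Weighted-median MR estimator (single exposure).

    Consistent when at least half the instrument weight comes from valid
    instruments. Per-SNP Wald ratios ``y_j / x_j`` are combined with weights
    ``x_j**2 / y_se_j**2``; the standard error comes from a parametric
    bootstrap (resampling y, and x when ``X_se`` is supplied, from their
    sampling distributions, ``B`` times with a fixed seed).
    """

    def __init__(self, B: int = 1000, seed: int = 0):
        self.B = B
        self.seed = seed

    def fit(self, X, y, y_se=None, X_se=None):
        if self.B < 100:
            raise ConfigurationError("bootstrap size B must be >= 100")
        X, y, y_se = _check_inputs(X, y, y_se)
        J, K = X.shape
        if K != 1:
            raise ValueError("weighted median is a single-exposure estimator")
        if J < 3:
            raise InsufficientInstrumentsError("weighted median needs at least 3 SNPs")
        x = X[:, 0]
        if np.any(x == 0):
            raise EstimationError("zero SNP-exposure effect makes a Wald ratio undefined")
        w = x**2 / y_se**2
        est = weighted_median(y / x, w)

        rng = np.random.default_rng(self.seed)
        xs = None if X_se is None else np.asarray(X_se, dtype=float).ravel()
        boots = np.empty(self.B)
        for b in range(self.B):
            yb = rng.normal(y, y_se)
            xb = x if xs is None else rng.normal(x, xs)
            xb = np.where(xb == 0, np.finfo(float).eps, xb)
            boots[b] = weighted_median(yb / xb, xb**2 / y_se**2)
        se = float(np.std(boots, ddof=1))

        self.coef_ = np.array([est])
        self.se_ = np.array([se])
        self.pval_ = np.clip(
            2.0 * stats.norm.sf(np.abs(self.coef_) / self.se_), np.finfo(float).tiny, 1.0
        )
        self.ci_ = np.column_stack([self.coef_ - Z95 * se, self.coef_ + Z95 * se])
        self.n_snp_ = J
        self.n_features_in_ = 1
        return self


class MRPressoRegressor(_BaseMRRegressor):
    """MR-PRESSO: residual-based global pleiotropy test, outlier removal,
    and distortion test (single exposure).

    The observed residual sum of squares is the sum over SNPs of the
    weighted squared residual of y_j against the leave-one-out IVW fit.
    Its null distribution is built from ``n_sim`` parametric simulations
    resampling both sides of the regression —
    ``x*_j ~ Normal(x_j, X_se_j**2)`` and
    ``y*_j ~ Normal(x_j * beta_loo(-j), y_se_j**2)`` — each refitted by the
    same leave-one-out procedure against the resampled exposures; omitting
    the exposure resampling (pass ``X_se=None``) makes the observed
    residuals over-dispersed relative to the null and the global test
    anti-conservative. Per-SNP outlier
    p-values compare each observed residual to its simulated distribution
    and are Bonferroni-adjusted; flagged SNPs are removed and the corrected
    estimate is IVW on the remainder. The distortion test compares the
    corrected-minus-raw shift to shifts from removing random subsets of the
    same size.

    Fitted attributes: ``global_pval_``, ``outlier_indices_``,
    ``outlier_pvals_``, ``distortion_pval_``, ``raw_coef_``; ``coef_`` etc.
    describe the outlier-corrected IVW fit.
    """

    def __init__(
        self,
        n_sim: int = 1000,
        outlier_alpha: float = 0.05,
        model: str = "multiplicative_random",
        seed: int = 0,
    ):
        self.n_sim = n_sim
        self.outlier_alpha = outlier_alpha
        self.model = model
        self.seed = seed

    def fit(self, X, y, y_se=None, X_se=None):
        if self.n_sim < 100:
            raise ConfigurationError("n_sim must be >= 100")
        X, y, y_se = _check_inputs(X, y, y_se)
        J, K = X.shape
        if K != 1:
            raise ValueError("MR-PRESSO is a single-exposure procedure")
        if J < 4:
            raise InsufficientInstrumentsError("MR-PRESSO needs at least 4 SNPs")
        x = X[:, 0]
        w = 1.0 / y_se**2

        s1 = float(np.sum(w * x * y))
        s2 = float(np.sum(w * x**2))
        denom = s2 - w * x**2
        if np.any(denom <= 0):
            raise EstimationError("leave-one-out IVW undefined (degenerate weights)")
        beta_loo = (s1 - w * x * y) / denom
        resid = y - x * beta_loo
        rss_obs = float(np.sum(w * resid**2))

        rng = np.random.default_rng(self.seed)
        if X_se is not None:
            xs = np.asarray(X_se, dtype=float).ravel()
            x_star = rng.normal(x, xs, size=(self.n_sim, J))
        else:
            x_star = np.broadcast_to(x, (self.n_sim, J))
        # outcomes simulated from the observed exposure effects but refitted
        # against the resampled ones: the simulated residuals then carry the
        # same se_y^2 + beta^2 se_x^2 spread as the observed ones
        y_star = rng.normal(x * beta_loo, y_se, size=(self.n_sim, J))
        s1_star = (w * x_star * y_star).sum(axis=1)
        s2_star = (w * x_star**2).sum(axis=1)
        denom_star = s2_star[:, None] - w * x_star**2
        beta_loo_star = (s1_star[:, None] - w * x_star * y_star) / denom_star
        resid_star = y_star - x_star * beta_loo_star
        wres_star = w * resid_star**2
        rss_star = wres_star.sum(axis=1)

        self.global_pval_ = float(
            (1 + np.sum(rss_star >= rss_obs)) / (self.n_sim + 1)
        )
        # per-SNP outlier p is the raw empirical fraction (no +1 smoothing):
        # a residual beyond every simulation must remain flaggable after the
        # Bonferroni adjustment
        per_snp = np.sum(wres_star >= w * resid**2, axis=0) / self.n_sim
        adjusted = np.minimum(per_snp * J, 1.0)
        outliers = np.flatnonzero(adjusted < self.outlier_alpha)
        self.outlier_indices_ = outliers
        self.outlier_pvals_ = adjusted

        raw = IVWRegressor(model=self.model).fit(X, y, y_se=y_se)
        self.raw_coef_ = raw.coef_.copy()
        keep = np.setdiff1d(np.arange(J), outliers)
        if len(outliers) and len(keep) >= 2:
            corrected = IVWRegressor(model=self.model).fit(X[keep], y[keep], y_se=y_se[keep])
            d_obs = float(corrected.coef_[0] - raw.coef_[0])
            n_out = len(outliers)
            d_null = np.empty(self.n_sim)
            for b in range(self.n_sim):
                drop = rng.choice(J, size=n_out, replace=False)
                mask = np.ones(J, dtype=bool)
                mask[drop] = False
                b_sub = np.sum(w[mask] * x[mask] * y[mask]) / np.sum(w[mask] * x[mask] ** 2)
                d_null[b] = b_sub - raw.coef_[0]
            self.distortion_pval_ = float(
                (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (self.n_sim + 1)
            )
            source = corrected
        else:
            self.distortion_pval_ = float("nan")
            source = raw
        for attr in ("coef_", "se_", "pval_", "ci_", "q_stat_", "q_df_", "q_pval_", "i2_"):
            setattr(self, attr, getattr(source, attr))
        self.n_snp_ = int(len(keep) if len(outliers) else J)
        self.n_features_in_ = 1
        return self


class MVMedianRegressor(_BaseMRRegressor):
    """Multivariable median regression through the origin.

    Minimizes the weighted L1 objective
    ``sum_j sqrt(w_j) * |y_j - sum_k theta_k x_jk|`` with
    ``w_j = 1 / y_se_j**2`` — median regression on sqrt(w)-scaled data —
    giving per-exposure estimates robust to up to half the (weighted)
    instruments being invalid. Standard errors come from a parametric
    bootstrap with a recorded seed.
    """

    def __init__(self, B: int = 200, seed: int = 0):
        self.B = B
        self.seed = seed

    @staticmethod
    def _l1_fit(D: np.ndarray, y: np.ndarray) -> np.ndarray:
        from statsmodels.regression.quantile_regression import QuantReg

        try:
            res = QuantReg(y, D).fit(q=0.5, max_iter=5000, p_tol=1e-8)
        except Exception as exc:  # IRLS failure
            raise EstimationError(f"weighted L1 solver failed: {exc}") from exc
        return np.asarray(res.params, dtype=float)

    def fit(self, X, y, y_se=None):
        if self.B < 100:
            raise ConfigurationError("bootstrap size B must be >= 100")
        X, y, y_se = _check_inputs(X, y, y_se)
        J, K = X.shape
        if J <= K:
            raise InsufficientInstrumentsError(f"median regression needs J > K (J={J}, K={K})")
        sw = 1.0 / y_se
        coef = self._l1_fit(X * sw[:, None], y * sw)

        rng = np.random.default_rng(self.seed)
        boots = np.empty((self.B, K))
        for b in range(self.B):
            yb = rng.normal(y, y_se)
            boots[b] = self._l1_fit(X * sw[:, None], yb * sw)
        se = boots.std(axis=0, ddof=1)

        self.coef_ = coef
        self.se_ = se
        self.pval_ = np.clip(2.0 * stats.norm.sf(np.abs(coef) / se), np.finfo(float).tiny, 1.0)
        self.ci_ = np.column_stack([coef - Z95 * se, coef + Z95 * se])
        self.n_snp_ = J
        self.n_features_in_ = K
        return self


class MVLassoRegressor(_BaseMRRegressor):
    """Multivariable MR with lasso-penalized per-SNP intercepts.

    Augments the IVW regression with one free intercept a_j per SNP,
    penalized by ``lambda * sum_j |a_j|``; SNPs whose fitted intercept is
    exactly zero are "valid". The penalty is tuned by the
    heterogeneity-stopping rule: descend a lambda grid from the smallest
    value that shrinks every intercept to zero and stop at the first lambda
    whose valid-SNP Cochran Q lies below its chi-square 5% critical value
    (the fewest exclusions consistent with homogeneity). The final estimate
    is IVW on the valid SNPs. Set ``lam`` to bypass the rule with a fixed
    penalty.
    """

    def __init__(
        self,
        lam: float | None = None,
        n_lambda: int = 50,
        model: str = "multiplicative_random",
    ):
        self.lam = lam
        self.n_lambda = n_lambda
        self.model = model

    @staticmethod
    def _fit_intercepts(X, y, w, lam, max_iter=500, tol=1e-12):
        """Alternating minimization of sum w_j (y_j - X theta - a_j)^2 + lam sum |a_j|."""
        a = np.zeros_like(y)
        theta = np.zeros(X.shape[1])
        for _ in range(max_iter):
            theta_new, _, _, _ = _wls(X, y - a, w)
            r = y - X @ theta_new
            thresh = lam / (2.0 * w)
            a_new = np.sign(r) * np.maximum(np.abs(r) - thresh, 0.0)
            if np.max(np.abs(a_new - a)) < tol and np.max(np.abs(theta_new - theta)) < tol:
                a, theta = a_new, theta_new
                break
            a, theta = a_new, theta_new
        return theta, a

    def fit(self, X, y, y_se=None):
        X, y, y_se = _check_inputs(X, y, y_se)
        J, K = X.shape
        if J <= K:
            raise InsufficientInstrumentsError(f"MV-lasso needs J > K (J={J}, K={K})")
        w = 1.0 / y_se**2

        def valid_mask(lam):
            _, a = self._fit_intercepts(X, y, w, lam)
            return a == 0.0

        if self.lam is not None:
            mask = valid_mask(self.lam)
            self.lambda_ = float(self.lam)
        else:
            theta0, _, _, _ = _wls(X, y, w)
            r0 = y - X @ theta0
            lam_max = float(np.max(2.0 * w * np.abs(r0))) * 1.0001
            grid = lam_max * np.power(0.85, np.arange(self.n_lambda))
            mask = np.ones(J, dtype=bool)
            self.lambda_ = float(grid[0])
            for lam in grid:
                m = valid_mask(lam)
                if m.sum() <= K:
                    break
                _, _, q, df = _wls(X[m], y[m], w[m])
                if df > 0 and q < stats.chi2.ppf(0.95, df):
                    mask, self.lambda_ = m, float(lam)
                    break
                mask, self.lambda_ = m, float(lam)
            else:
                pass
        if mask.sum() < K + 1:
            raise EstimationError("no valid instrument subset at any lambda")

        final = IVWRegressor(model=self.model).fit(X[mask], y[mask], y_se=y_se[mask])
        for attr in ("coef_", "se_", "pval_", "ci_", "q_stat_", "q_df_", "q_pval_", "i2_"):
            setattr(self, attr, getattr(final, attr))
        self.valid_mask_ = mask
        self.n_snp_ = int(mask.sum())
        self.n_features_in_ = K
        return self


def conditional_f_statistics(
    exposure_betas: np.ndarray, exposure_ses: np.ndarray
) -> np.ndarray:
    """Conditional instrument-strength F statistic per exposure.

    For exposure k, regress its SNP effects on the other exposures' SNP
    effects (weights ``1 / se_k**2``) and average the weighted squared
    residuals over J - K + 1 degrees of freedom: the Sanderson-Windmeijer-
    style summary-data statistic. With orthogonal instrument sets it
    approaches each exposure's marginal F; with near-collinear exposures it
    collapses toward zero, flagging conditionally weak instruments. With a
    single exposure it reduces to the mean per-SNP chi-square, which matches
    the overall instrument F at large n.
    """
    X = np.atleast_2d(np.asarray(exposure_betas, dtype=float))
    S = np.atleast_2d(np.asarray(exposure_ses, dtype=float))
    J, K = X.shape
    out = np.empty(K)
    for k in range(K):
        w = 1.0 / S[:, k] ** 2
        others = np.delete(X, k, axis=1)
        if others.shape[1] == 0:
            resid = X[:, k]
        else:
            coef, _, _, _ = _wls(others, X[:, k], w)
            resid = X[:, k] - others @ coef
        out[k] = float(np.sum(w * resid**2) / (J - K + 1))
    return out
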