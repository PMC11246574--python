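"""Univariable two-sample MR estimators and sensitivity analyses.

Operations take a single-exposure :class:`~mrmediate.datatypes.HarmonizedDataset`
and return :class:`MREstimate` records. The primary analysis is IVW;
MR-Egger (with its intercept test for directional pleiotropy), the weighted
median, Cochran's Q and MR-PRESSO serve as sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .datatypes import HarmonizedDataset
from .errors import ConfigurationError, UndefinedRatioError
from .estimators import (
    Z95,
    EggerRegressor,
    IVWRegressor,
    MRPressoRegressor,
    WeightedMedianRegressor,
)


@dataclass
class MREstimate:
    """One method's causal estimate with its diagnostics."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    i2: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pval: float | None = None
    exposure_id: str | None = None
    outcome_id: str | None = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class EstimatorOptions:
    """Shared tuning knobs for the stochastic and model-choice options."""

    ivw_model: str = "multiplicative_random"
    median_bootstrap_B: int = 1000
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.median_bootstrap_B < 100:
            raise ConfigurationError("median_bootstrap_B must be >= 100")
        if self.presso_n_sim < 100:
            raise ConfigurationError("presso_n_sim must be >= 100")


def _estimate_from(fitted, method: str, data: HarmonizedDataset) -> MREstimate:
    return MREstimate(
        method=method,
        beta=float(fitted.coef_[0]),
        se=float(fitted.se_[0]),
        ci_low=float(fitted.ci_[0, 0]),
        ci_high=float(fitted.ci_[0, 1]),
        pval=float(fitted.pval_[0]),
        n_snp=int(fitted.n_snp_),
        q_stat=getattr(fitted, "q_stat_", None),
        q_df=getattr(fitted, "q_df_", None),
        q_pval=getattr(fitted, "q_pval_", None),
        i2=getattr(fitted, "i2_", None),
        egger_intercept=getattr(fitted, "intercept_", None),
        egger_intercept_se=getattr(fitted, "intercept_se_", None),
        egger_intercept_pval=getattr(fitted, "intercept_pval_", None),
        exposure_id=data.exposure_ids[0],
        outcome_id=data.outcome_id,
    )


def wald_ratio(gamma: float, se_gamma: float, Gamma: float, se_Gamma: float) -> MREstimate:
    """Single-SNP causal estimate Gamma / gamma with first-order SE.

    The first-order standard error ``se_Gamma / |gamma|`` ignores the
    uncertainty in gamma, adequate for instruments passing the F > 10
    screen.
    """
    if gamma == 0:
        raise UndefinedRatioError("Wald ratio undefined for gamma = 0")
    beta = Gamma / gamma
    se = se_Gamma / abs(gamma)
    pval = max(2.0 * stats.norm.sf(abs(beta) / se), np.finfo(float).tiny)
    return MREstimate(
        method="wald_ratio",
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pval=float(pval),
        n_snp=1,
    )


def ivw(data: HarmonizedDataset, opts: EstimatorOptions | None = None) -> MREstimate:
    """Inverse-variance weighted estimate (primary analysis)."""
    opts = opts or EstimatorOptions()
    gamma, _ = data.single_exposure()
    fit = IVWRegressor(model=opts.ivw_model).fit(
        gamma, data.outcome_betas, y_se=data.outcome_ses
    )
    return _estimate_from(fit, "ivw", data)


def mr_egger(data: HarmonizedDataset) -> MREstimate:
    """MR-Egger slope and intercept (pleiotropy) test."""
    gamma, _ = data.single_exposure()
    fit = EggerRegressor().fit(gamma, data.outcome_betas, y_se=data.outcome_ses)
    return _estimate_from(fit, "egger", data)


def weighted_median(
    data: HarmonizedDataset, opts: EstimatorOptions | None = None
) -> MREstimate:
    """Weighted-median estimate with parametric-bootstrap SE."""
    opts = opts or EstimatorOptions()
    gamma, se_gamma = data.single_exposure()
    fit = WeightedMedianRegressor(B=opts.median_bootstrap_B, seed=opts.seed).fit(
        gamma, data.outcome_betas, y_se=data.outcome_ses, X_se=se_gamma
    )
    return _estimate_from(fit, "weighted_median", data)


def cochran_q(data: HarmonizedDataset) -> tuple[float, int, float, float]:
    """Cochran heterogeneity of the per-SNP Wald ratios around the IVW fit.

    Returns ``(q_stat, q_df, q_pval, i2)``. Q is computed as the weighted
    sum of squared ratio deviations with weights ``gamma^2 / se_Gamma^2``,
    which is algebraically the residual chi-square of the IVW regression.
    """
    fit_ivw = IVWRegressor(model="fixed").fit(
        data.single_exposure()[0], data.outcome_betas, y_se=data.outcome_ses
    )
    return fit_ivw.q_stat_, fit_ivw.q_df_, fit_ivw.q_pval_, fit_ivw.i2_


def mr_presso(
    data: HarmonizedDataset, opts: EstimatorOptions | None = None
) -> tuple[float, list[str], MREstimate, float]:
    """MR-PRESSO global test, outlier list, corrected estimate, distortion p.

    Returns ``(global_pval, outlier_snp_ids, corrected_estimate,
    distortion_pval)``; the corrected estimate is IVW on the non-outlying
    SNPs (the raw IVW when no outlier is flagged, in which case the
    distortion p-value is NaN).
    """
    opts = opts or EstimatorOptions()
    gamma, se_gamma = data.single_exposure()
    fit = MRPressoRegressor(
        n_sim=opts.presso_n_sim,
        outlier_alpha=opts.presso_outlier_alpha,
        model=opts.ivw_model,
        seed=opts.seed,
    ).fit(gamma, data.outcome_betas, y_se=data.outcome_ses, X_se=se_gamma)
    outlier_ids = [data.snp_ids[i] for i in fit.outlier_indices_]
    corrected = _estimate_from(fit, "presso_corrected", data)
    return fit.global_pval_, outlier_ids, corrected, fit.distortion_pval_


def all_uvmr_methods(
    data: HarmonizedDataset, opts: EstimatorOptions | None = None, presso: bool = True
) -> tuple[dict[str, MREstimate], dict | None]:
    """Run IVW plus the sensitivity battery.

    Returns ``(estimates, presso_diagnostics)``: estimates keyed by method
    name (egger/weighted_median need 3 SNPs, MR-PRESSO 4), and the PRESSO
    global/distortion tests with the flagged SNPs, or None when skipped.
    """
    opts = opts or EstimatorOptions()
    out = {"ivw": ivw(data, opts)}
    presso_diag = None
    if data.n_snps >= 3:
        out["egger"] = mr_egger(data)
        out["weighted_median"] = weighted_median(data, opts)
    if presso and data.n_snps >= 4:
        global_p, outlier_ids, corrected, distortion_p = mr_presso(data, opts)
        out["presso_corrected"] = corrected
        presso_diag = {
            "global_pval": global_p,
            "outlier_snp_ids": outlier_ids,
            "distortion_pval": distortion_p,
        }
    return out, presso_diag
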