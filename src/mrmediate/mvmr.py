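"""Multivariable MR: direct effects of each exposure conditional on the rest.

All operations take a multi-exposure :class:`~mrmediate.datatypes.HarmonizedDataset`
(J SNPs x K exposures). MV-IVW is the primary model; MVMR-Egger, MVMR-median
and MVMR-Lasso are its sensitivity variants, and the conditional F statistic
diagnoses instrument strength for each exposure given the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import HarmonizedDataset
from .errors import InsufficientInstrumentsError
from .estimators import (
    EggerRegressor,
    IVWRegressor,
    MVLassoRegressor,
    MVMedianRegressor,
    conditional_f_statistics,
)
from .uvmr import EstimatorOptions, MREstimate


@dataclass
class MvmrResult:
    """Per-exposure conditional estimates from one multivariable method."""

    method: str
    estimates: list[MREstimate]
    conditional_f: list[float] = field(default_factory=list)
    q_stat: float | None = None
    q_df: int | None = None
    q_pval: float | None = None
    retained_snp_ids: list[str] | None = None
    egger_intercept: float | None = None
    egger_intercept_pval: float | None = None

    def estimate_for(self, exposure_id: str) -> MREstimate:
        for est in self.estimates:
            if est.exposure_id == exposure_id:
                return est
        raise KeyError(exposure_id)


def _per_exposure(fitted, method: str, data: HarmonizedDataset) -> list[MREstimate]:
    out = []
    for k, exp_id in enumerate(data.exposure_ids):
        out.append(
            MREstimate(
                method=method,
                beta=float(fitted.coef_[k]),
                se=float(fitted.se_[k]),
                ci_low=float(fitted.ci_[k, 0]),
                ci_high=float(fitted.ci_[k, 1]),
                pval=float(fitted.pval_[k]),
                n_snp=int(fitted.n_snp_),
                q_stat=getattr(fitted, "q_stat_", None),
                q_df=getattr(fitted, "q_df_", None),
                q_pval=getattr(fitted, "q_pval_", None),
                i2=getattr(fitted, "i2_", None),
                egger_intercept=getattr(fitted, "intercept_", None),
                egger_intercept_se=getattr(fitted, "intercept_se_", None),
                egger_intercept_pval=getattr(fitted, "intercept_pval_", None),
                exposure_id=exp_id,
                outcome_id=data.outcome_id,
            )
        )
    return out


def _result(fitted, method: str, data: HarmonizedDataset, with_f: bool = True, **extra):
    cf = (
        list(conditional_f(data))
        if (with_f and data.n_exposures >= 2)
        else []
    )
    return MvmrResult(
        method=method,
        estimates=_per_exposure(fitted, method, data),
        conditional_f=cf,
        q_stat=getattr(fitted, "q_stat_", None),
        q_df=getattr(fitted, "q_df_", None),
        q_pval=getattr(fitted, "q_pval_", None),
        egger_intercept=getattr(fitted, "intercept_", None),
        egger_intercept_pval=getattr(fitted, "intercept_pval_", None),
        **extra,
    )


def mv_ivw(data: HarmonizedDataset, opts: EstimatorOptions | None = None) -> MvmrResult:
    """Multivariable IVW: weighted regression of Gamma on the gamma matrix."""
    opts = opts or EstimatorOptions()
    fit = IVWRegressor(model=opts.ivw_model).fit(
        data.exposure_betas, data.outcome_betas, y_se=data.outcome_ses
    )
    return _result(fit, "mv_ivw", data)


def mv_egger(data: HarmonizedDataset, opts: EstimatorOptions | None = None) -> MvmrResult:
    """MVMR-Egger: mv_ivw plus a common intercept, SNPs oriented to the
    first exposure's positive direction."""
    opts = opts or EstimatorOptions()
    fit = EggerRegressor(model=opts.ivw_model).fit(
        data.exposure_betas, data.outcome_betas, y_se=data.outcome_ses
    )
    return _result(fit, "mv_egger", data)


def mv_median(data: HarmonizedDataset, opts: EstimatorOptions | None = None) -> MvmrResult:
    """MVMR-median: weighted L1 regression through the origin."""
    opts = opts or EstimatorOptions()
    B = max(100, opts.median_bootstrap_B // 5)  # L1 refits are costlier than medians
    fit = MVMedianRegressor(B=B, seed=opts.seed).fit(
        data.exposure_betas, data.outcome_betas, y_se=data.outcome_ses
    )
    return _result(fit, "mv_median", data)


def mv_lasso(data: HarmonizedDataset, opts: EstimatorOptions | None = None) -> MvmrResult:
    """MVMR-Lasso: per-SNP pleiotropy intercepts with L1 shrinkage; the
    estimate is mv_ivw on the SNPs whose intercept shrinks to zero."""
    opts = opts or EstimatorOptions()
    fit = MVLassoRegressor(model=opts.ivw_model).fit(
        data.exposure_betas, data.outcome_betas, y_se=data.outcome_ses
    )
    retained = [s for s, keep in zip(data.snp_ids, fit.valid_mask_) if keep]
    return _result(fit, "mv_lasso", data, retained_snp_ids=retained)


def conditional_f(data: HarmonizedDataset) -> np.ndarray:
    """Conditional instrument-strength F per exposure (see
    :func:`mrmediate.estimators.conditional_f_statistics`)."""
    J, K = data.exposure_betas.shape
    if J <= K:
        raise InsufficientInstrumentsError(f"conditional F needs J > K (J={J}, K={K})")
    return conditional_f_statistics(data.exposure_betas, data.exposure_ses)


def all_mvmr_methods(
    data: HarmonizedDataset, opts: EstimatorOptions | None = None
) -> dict[str, MvmrResult]:
    """MV-IVW plus the MVMR sensitivity battery, keyed by method name."""
    opts = opts or EstimatorOptions()
    out = {"mv_ivw": mv_ivw(data, opts)}
    if data.n_snps > data.n_exposures + 1:
        out["mv_egger"] = mv_egger(data, opts)
    out["mv_median"] = mv_median(data, opts)
    out["mv_lasso"] = mv_lasso(data, opts)
    return out
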