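"""Decision layer: FDR control, causal calls, covariate selection,
mediator screening and two-step mediation with Delta-method intervals.

The two-step mediation logic follows the product-of-coefficients method on
MR estimates: step one estimates the exposure's effect on the mediator
(beta1, univariable MR); step two estimates the mediator's effect on the
outcome adjusted for the exposure (beta2, multivariable MR). The indirect
effect is beta1 * beta2, the mediated proportion is indirect / total
(total = univariable exposure-on-outcome effect), and its 95% interval
comes from first-order (Delta-method) variance propagation. A negative
point proportion is floored at 0% to signify absence of a mediating effect;
the raw value and interval are kept for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import math
import warnings

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, EstimationError
from .uvmr import MREstimate

Z95 = stats.norm.ppf(0.975)


def reconstruct_p_from_ci(beta: float, ci_low: float, ci_high: float) -> float:
    """Two-sided normal p-value implied by an estimate and its 95% CI.

    ``se = (ci_high - ci_low) / (2 * 1.96)``; warns when the interval is
    asymmetric about the estimate by more than 5% of its half-width (a sign
    the printed interval was not a normal Wald interval).
    """
    if not (ci_low < ci_high):
        raise EstimationError("confidence interval must have positive width")
    half = (ci_high - ci_low) / 2.0
    center = (ci_high + ci_low) / 2.0
    if abs(center - beta) > 0.05 * half:
        warnings.warn(
            f"CI ({ci_low}, {ci_high}) is asymmetric about beta={beta}; "
            "reconstructed p assumes a symmetric normal interval",
            stacklevel=2,
        )
    se = half / Z95
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def bh_fdr(pvals) -> list[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    pvals = list(pvals)
    if not pvals:
        return []
    arr = np.asarray(pvals, dtype=float)
    if np.any((arr <= 0) | (arr > 1)):
        raise ConfigurationError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(arr, method="fdr_bh")
    return [float(v) for v in q]


def select_mvmr_covariates(
    uvmr_results: list[MREstimate],
    beta_threshold: float = 0.5,
    alpha: float = 0.05,
) -> list[str]:
    """Exposures qualifying as adjustment covariates: |beta| > 0.5, p < 0.05.

    The magnitude rule is applied to the absolute effect, so strong
    protective exposures qualify too.
    """
    return [
        est.exposure_id
        for est in uvmr_results
        if abs(est.beta) > beta_threshold and est.pval < alpha
    ]


@dataclass
class RuleOutcome:
    rule: str
    passed: bool
    detail: str


@dataclass
class CausalCall:
    """Verdict of the decision predicate for one exposure-outcome pair.

    ``causal`` requires a significant primary (IVW) estimate that survives
    FDR, directionally consistent support from at least one significant
    sensitivity analysis, and no sign of directional pleiotropy from the
    Egger intercept. ``suggestive`` relaxes only the FDR rule;
    ``not_robust`` marks primary significance that fails a robustness rule;
    otherwise ``no_evidence``.
    """

    verdict: str
    reasons: list[RuleOutcome] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def call_causal(
    primary: MREstimate,
    sensitivity: list[MREstimate],
    q_value: float,
    alpha: float = 0.05,
) -> CausalCall:
    """Evaluate the causal-call decision rules (deterministic and total)."""
    if primary.method != "ivw":
        raise ConfigurationError("primary estimate must come from the IVW method")

    primary_sig = primary.pval < alpha
    fdr_pass = q_value < 0.05
    support = [
        s
        for s in sensitivity
        if s.pval < alpha and np.sign(s.beta) == np.sign(primary.beta) and s.beta != 0
    ]
    sens_pass = len(support) > 0
    intercept_ps = [
        s.egger_intercept_pval for s in sensitivity if s.egger_intercept_pval is not None
    ]
    pleio_pass = all(p >= alpha for p in intercept_ps) if intercept_ps else True

    reasons = [
        RuleOutcome("primary_significant", primary_sig, f"IVW p = {primary.pval:.3g}"),
        RuleOutcome("fdr", fdr_pass, f"q = {q_value:.3g}"),
        RuleOutcome(
            "sensitivity_support",
            sens_pass,
            f"{len(support)} sensitivity estimate(s) significant with consistent direction",
        ),
        RuleOutcome(
            "no_pleiotropy",
            pleio_pass,
            "Egger intercept p = "
            + (", ".join(f"{p:.3g}" for p in intercept_ps) if intercept_ps else "unavailable"),
        ),
    ]

    if primary_sig and fdr_pass and sens_pass and pleio_pass:
        verdict = "causal"
    elif primary_sig and sens_pass and pleio_pass:
        verdict = "suggestive"
    elif primary_sig:
        verdict = "not_robust"
    else:
        verdict = "no_evidence"
    return CausalCall(verdict=verdict, reasons=reasons)


@dataclass
class MediationResult:
    """Two-step mediation estimate for one exposure-mediator-outcome triple."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    total: float
    se_total: float
    indirect: float
    proportion: float
    raw_proportion: float
    proportion_se: float
    proportion_ci: tuple[float, float]
    floored: bool
    #: diagnostic variant treating the total effect as fixed (no se_total term)
    proportion_ci_total_fixed: tuple[float, float] = (float("nan"), float("nan"))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["proportion_ci"] = list(self.proportion_ci)
        d["proportion_ci_total_fixed"] = list(self.proportion_ci_total_fixed)
        return d


def two_step_mediation(
    beta1: float,
    se1: float,
    beta2: float,
    se2: float,
    total: float,
    se_total: float,
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
) -> MediationResult:
    """Product-of-coefficients mediation with a Delta-method interval.

    ``indirect = beta1 * beta2``; ``proportion = indirect / total``. The
    Delta variance treats beta1 and beta2 as independent (they come from
    non-overlapping samples / separate fits) and propagates the total-effect
    uncertainty:

    ``Var = (beta2/total)^2 se1^2 + (beta1/total)^2 se2^2
    + (beta1*beta2/total^2)^2 se_total^2``

    A negative point proportion is reported as 0 with ``floored=True``; the
    raw proportion and the interval are unaffected by flooring.
    """
    if total == 0:
        raise EstimationError("mediation proportion undefined for a zero total effect")
    for name, s in (("se1", se1), ("se2", se2), ("se_total", se_total)):
        if s <= 0:
            raise ConfigurationError(f"{name} must be > 0")

    beta1, beta2, total = float(beta1), float(beta2), float(total)
    se1, se2, se_total = float(se1), float(se2), float(se_total)
    indirect = beta1 * beta2
    raw = indirect / total
    var = (
        (beta2 / total) ** 2 * se1**2
        + (beta1 / total) ** 2 * se2**2
        + (indirect / total**2) ** 2 * se_total**2
    )
    se = math.sqrt(var)
    ci = (float(raw - Z95 * se), float(raw + Z95 * se))
    var_fixed = (beta2 / total) ** 2 * se1**2 + (beta1 / total) ** 2 * se2**2
    se_fixed = math.sqrt(var_fixed)
    ci_fixed = (float(raw - Z95 * se_fixed), float(raw + Z95 * se_fixed))

    floored = raw < 0
    return MediationResult(
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        beta1=beta1,
        se1=se1,
        beta2=beta2,
        se2=se2,
        total=total,
        se_total=se_total,
        indirect=indirect,
        proportion=0.0 if floored else raw,
        raw_proportion=raw,
        proportion_se=se,
        proportion_ci=ci,
        floored=floored,
        proportion_ci_total_fixed=ci_fixed,
    )


@dataclass
class MediatorScreen:
    """The three causal calls (and step-2 signs) screened per candidate."""

    mediator_id: str
    step1: CausalCall
    step2_unadjusted: CausalCall
    step2_adjusted: CausalCall
    step2_unadjusted_beta: float
    step2_adjusted_beta: float


_SUPPORTED = {"causal", "suggestive"}


def screen_mediators(candidates: list[MediatorScreen]) -> list[str]:
    """Accept mediators passing the two-step screening criteria.

    A candidate is accepted iff (1) the exposure causally affects it
    (step 1 verdict causal/suggestive) and (2) it causally affects the
    outcome both without and with adjustment for the exposure, with a
    consistent direction across the two step-2 analyses.
    """
    accepted = []
    for c in candidates:
        if c.step1.verdict not in _SUPPORTED:
            continue
        if c.step2_unadjusted.verdict not in _SUPPORTED:
            continue
        if c.step2_adjusted.verdict not in _SUPPORTED:
            continue
        if np.sign(c.step2_unadjusted_beta) != np.sign(c.step2_adjusted_beta):
            continue
        accepted.append(c.mediator_id)
    return accepted
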