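"""End-to-end orchestration of the two-stage analysis.

Stage 1 screens every exposure-outcome pair: instrument selection
(p-value threshold with a documented relaxed fallback, LD clumping,
confounder blocklist), harmonization, the univariable estimator battery,
BH-FDR across exposures within each outcome family, and the causal-call
decision rules; an optional bidirectional pass swaps the roles to probe
reverse causation. Stage 2 runs two-step mediation for every causally
called pair and candidate mediator: exposure-on-mediator UVMR (beta1),
mediator-on-outcome UVMR without adjustment and MVMR adjusted for the
exposure (beta2), mediator screening, and the Delta-method mediation
proportion.

Reports are machine-readable (JSON, deterministic for a fixed config and
seed) plus TSV tables.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import instruments as instr
from . import mediation as med
from . import mvmr as mv
from . import uvmr as uv
from .datatypes import LDMatrix, SummaryStatsTable
from .errors import InputError, MrMediateError
from .io import read_ld_matrix, read_summary_stats

_FDR_NOTE = (
    "q-values are Benjamini-Hochberg step-up, computed within each outcome "
    "across exposures; local-FDR tools can give different q-values"
)


@dataclass
class RunConfig:
    """Run configuration for :func:`run_pipeline`.

    ``exposures``/``outcomes``/``mediators`` map trait ids to summary-stat
    file paths. Thresholds default to the standard instrument-selection
    settings (p < 5e-8 with 5e-6 fallback, clump at r2 < 0.001 within
    10,000 kb, F > 10 advisory).
    """

    exposures: dict[str, str] = field(default_factory=dict)
    outcomes: dict[str, str] = field(default_factory=dict)
    mediators: dict[str, str] = field(default_factory=dict)
    ld_matrix: str | None = None
    blocklist: str | None = None
    column_maps: dict[str, dict] = field(default_factory=dict)
    pval_threshold: float = 5e-8
    fallback_threshold: float | None = 5e-6
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    palindrome_policy: str = "infer_by_eaf"
    eaf_ambiguity: float = 0.08
    alpha: float = 0.05
    ivw_model: str = "multiplicative_random"
    median_bootstrap_B: int = 1000
    presso: bool = True
    presso_n_sim: int = 1000
    bidirectional: bool = False
    seed: int = 0
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except OSError as exc:
            raise InputError(f"cannot read run configuration {path}: {exc}") from exc
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def options(self) -> uv.EstimatorOptions:
        return uv.EstimatorOptions(
            ivw_model=self.ivw_model,
            median_bootstrap_B=self.median_bootstrap_B,
            presso_n_sim=self.presso_n_sim,
            seed=self.seed,
        )


def _require_file(path: str, what: str) -> None:
    if not os.path.exists(path):
        raise InputError(f"{what} file not found: {path}")


def select_instruments(
    table: SummaryStatsTable,
    ld: LDMatrix | None = None,
    blocklist: str | None = None,
    pval_threshold: float = 5e-8,
    fallback_threshold: float | None = 5e-6,
    clump_r2: float = 0.001,
    clump_window_kb: int = 10_000,
) -> SummaryStatsTable:
    """Significance filter (with fallback), LD clump, blocklist removal."""
    try:
        selected = instr.select_by_pvalue(table, pval_threshold)
    except InputError:
        if fallback_threshold is None:
            raise
        selected = instr.select_by_pvalue(table, fallback_threshold)
    if ld is not None:
        selected = instr.ld_clump(selected, ld, clump_r2, clump_window_kb)
    if blocklist is not None:
        selected = instr.apply_blocklist(selected, blocklist)
    if selected.n_snps == 0:
        raise InputError(f"no instrument left for trait {table.trait_id!r}")
    return selected


def _estimates_dict(estimates: dict[str, uv.MREstimate]) -> dict:
    return {name: est.to_dict() for name, est in estimates.items()}


def _uvmr_block(
    exposure_instruments: SummaryStatsTable,
    outcome: SummaryStatsTable,
    cfg: RunConfig,
    presso: bool,
) -> tuple[dict[str, uv.MREstimate], dict | None, object]:
    data = instr.harmonize(
        exposure_instruments,
        outcome,
        palindrome_policy=cfg.palindrome_policy,
        eaf_ambiguity=cfg.eaf_ambiguity,
    )
    estimates, presso_diag = uv.all_uvmr_methods(data, cfg.options(), presso=presso)
    return estimates, presso_diag, data


def _call_for(
    estimates: dict[str, uv.MREstimate], q_value: float, alpha: float
) -> med.CausalCall:
    sens = [e for name, e in estimates.items() if name != "ivw"]
    return med.call_causal(estimates["ivw"], sens, q_value, alpha)


def _stage1_grid(
    exposures: dict[str, SummaryStatsTable],
    outcomes: dict[str, SummaryStatsTable],
    ld: LDMatrix | None,
    cfg: RunConfig,
) -> dict:
    """UVMR battery over the exposure-outcome grid with per-outcome FDR."""
    grid: dict = {}
    for out_id, out_tab in outcomes.items():
        per_exposure: dict = {}
        for exp_id, exp_tab in exposures.items():
            sel = select_instruments(
                exp_tab,
                ld,
                cfg.blocklist,
                cfg.pval_threshold,
                cfg.fallback_threshold,
                cfg.clump_r2,
                cfg.clump_window_kb,
            )
            estimates, presso_diag, data = _uvmr_block(sel, out_tab, cfg, cfg.presso)
            strength = instr.compute_instrument_strength(sel)
            per_exposure[exp_id] = {
                "estimates": estimates,
                "presso": presso_diag,
                "n_snp": data.n_snps,
                "overall_f": strength.overall_f,
                "overall_r2": strength.overall_r2,
            }
        ivw_ps = [per_exposure[e]["estimates"]["ivw"].pval for e in exposures]
        qs = med.bh_fdr(ivw_ps)
        for (exp_id, block), q in zip(per_exposure.items(), qs):
            block["q_value"] = q
            block["call"] = _call_for(block["estimates"], q, cfg.alpha)
        grid[out_id] = per_exposure
    return grid


def mediation_triple_analysis(
    exposure: SummaryStatsTable,
    mediator: SummaryStatsTable,
    outcome: SummaryStatsTable,
    ld: LDMatrix | None = None,
    cfg: RunConfig | None = None,
    total_estimate: uv.MREstimate | None = None,
) -> dict:
    """Two-step mediation for a single exposure/mediator/outcome triple.

    Runs the total-effect UVMR (unless a precomputed estimate is supplied),
    step 1 (exposure on mediator, UVMR over the exposure's instruments),
    step 2 without adjustment (mediator on outcome over the mediator's
    instruments) and with adjustment (MVMR of the outcome on mediator and
    exposure over the union of both instrument sets), screens the mediator,
    and — when accepted — returns the Delta-method mediation proportion.
    """
    cfg = cfg or RunConfig()
    opts = cfg.options()

    exp_sel = select_instruments(
        exposure, ld, cfg.blocklist, cfg.pval_threshold, cfg.fallback_threshold,
        cfg.clump_r2, cfg.clump_window_kb,
    )
    med_sel = select_instruments(
        mediator, ld, cfg.blocklist, cfg.pval_threshold, cfg.fallback_threshold,
        cfg.clump_r2, cfg.clump_window_kb,
    )

    if total_estimate is None:
        total_ests, _, _ = _uvmr_block(exp_sel, outcome, cfg, presso=False)
        total_estimate = total_ests["ivw"]

    # step 1: exposure -> mediator
    step1_ests, _, _ = _uvmr_block(exp_sel, mediator, cfg, presso=False)
    step1_call = _call_for(step1_ests, med.bh_fdr([step1_ests["ivw"].pval])[0], cfg.alpha)

    # step 2 unadjusted: mediator -> outcome
    step2u_ests, _, _ = _uvmr_block(med_sel, outcome, cfg, presso=False)
    step2u_call = _call_for(step2u_ests, med.bh_fdr([step2u_ests["ivw"].pval])[0], cfg.alpha)

    # step 2 adjusted: MVMR outcome ~ mediator + exposure on the instrument union
    union_ids = sorted(set(exp_sel.snp_ids) | set(med_sel.snp_ids))
    med_union = mediator.subset(union_ids)
    exp_union = exposure.subset(union_ids)
    mv_data = instr.harmonize(
        [med_union, exp_union],
        outcome,
        palindrome_policy=cfg.palindrome_policy,
        eaf_ambiguity=cfg.eaf_ambiguity,
    )
    mv_fit = mv.mv_ivw(mv_data, opts)
    mv_egger_fit = mv.mv_egger(mv_data, opts) if mv_data.n_snps > 3 else None
    beta2_est = mv_fit.estimate_for(mediator.trait_id)
    sens2 = [mv_egger_fit.estimate_for(mediator.trait_id)] if mv_egger_fit else []
    step2a_call = med.call_causal(
        _as_primary(beta2_est), sens2, med.bh_fdr([beta2_est.pval])[0], cfg.alpha
    )

    screen = med.MediatorScreen(
        mediator_id=mediator.trait_id,
        step1=step1_call,
        step2_unadjusted=step2u_call,
        step2_adjusted=step2a_call,
        step2_unadjusted_beta=step2u_ests["ivw"].beta,
        step2_adjusted_beta=beta2_est.beta,
    )
    accepted = med.screen_mediators([screen])

    result = med.two_step_mediation(
        beta1=step1_ests["ivw"].beta,
        se1=step1_ests["ivw"].se,
        beta2=beta2_est.beta,
        se2=beta2_est.se,
        total=total_estimate.beta,
        se_total=total_estimate.se,
        exposure_id=exposure.trait_id,
        mediator_id=mediator.trait_id,
        outcome_id=outcome.trait_id,
    )
    return {
        "total": total_estimate,
        "step1": {"estimates": step1_ests, "call": step1_call},
        "step2_unadjusted": {"estimates": step2u_ests, "call": step2u_call},
        "step2_adjusted": {
            "mv_ivw": mv_fit,
            "mv_egger": mv_egger_fit,
            "conditional_f": list(mv.conditional_f(mv_data)),
            "call": step2a_call,
        },
        "accepted": bool(accepted),
        "mediation": result,
    }


def _as_primary(est: uv.MREstimate) -> uv.MREstimate:
    """Present a multivariable IVW estimate as the primary for call_causal."""
    clone = uv.MREstimate(**est.to_dict())
    clone.method = "ivw"
    return clone


def _serialize(obj):
    if isinstance(obj, uv.MREstimate):
        return obj.to_dict()
    if isinstance(obj, mv.MvmrResult):
        return {
            "method": obj.method,
            "estimates": [e.to_dict() for e in obj.estimates],
            "conditional_f": list(obj.conditional_f),
            "q_stat": obj.q_stat,
            "q_df": obj.q_df,
            "q_pval": obj.q_pval,
            "retained_snp_ids": obj.retained_snp_ids,
            "egger_intercept": obj.egger_intercept,
            "egger_intercept_pval": obj.egger_intercept_pval,
        }
    if isinstance(obj, (med.CausalCall, med.MediationResult)):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {k: _serialize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_serialize(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _write_report(report: dict, output_dir: str) -> None:
    os.makedirs(output_dir, exist_ok=True)
    with open(os.path.join(output_dir, "report.json"), "w") as fh:
        json.dump(_serialize(report), fh, indent=2, sort_keys=True)
        fh.write("\n")

    rows = []
    for out_id, per_exp in report.get("stage1", {}).items():
        for exp_id, block in per_exp.items():
            for name, est in block["estimates"].items():
                rows.append(
                    {
                        "outcome": out_id,
                        "exposure": exp_id,
                        "method": name,
                        "beta": est.beta,
                        "se": est.se,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                        "pval": est.pval,
                        "n_snp": est.n_snp,
                        "q_stat": est.q_stat,
                        "i2": est.i2,
                        "egger_intercept": est.egger_intercept,
                        "egger_intercept_pval": est.egger_intercept_pval,
                        "q_value": block["q_value"] if name == "ivw" else None,
                        "verdict": block["call"].verdict if name == "ivw" else None,
                    }
                )
    if rows:
        pd.DataFrame(rows).to_csv(
            os.path.join(output_dir, "stage1_estimates.tsv"), sep="\t", index=False
        )
    med_rows = [m.to_dict() for m in report.get("mediation", [])]
    if med_rows:
        pd.DataFrame(med_rows).to_csv(
            os.path.join(output_dir, "mediation.tsv"), sep="\t", index=False
        )


def run_pipeline(config: RunConfig | str) -> dict:
    """Execute both stages and return (and optionally write) the report."""
    cfg = RunConfig.from_yaml(config) if isinstance(config, str) else config
    if not cfg.exposures or not cfg.outcomes:
        raise InputError("configuration must name at least one exposure and one outcome")

    for role, mapping in (
        ("exposure", cfg.exposures),
        ("outcome", cfg.outcomes),
        ("mediator", cfg.mediators),
    ):
        for trait_id, path in mapping.items():
            _require_file(path, f"{role} summary statistics ({trait_id})")
    if cfg.ld_matrix is not None:
        _require_file(cfg.ld_matrix, "LD matrix")
    if cfg.blocklist is not None:
        _require_file(cfg.blocklist, "blocklist")

    def _load(mapping: dict[str, str], role: str) -> dict[str, SummaryStatsTable]:
        return {
            tid: read_summary_stats(
                path, cfg.column_maps.get(tid), trait_id=tid, trait_role=role
            )
            for tid, path in mapping.items()
        }

    exposures = _load(cfg.exposures, "exposure")
    outcomes = _load(cfg.outcomes, "outcome")
    mediators = _load(cfg.mediators, "mediator")
    ld = read_ld_matrix(cfg.ld_matrix) if cfg.ld_matrix else None

    report: dict = {
        "header": {
            "seed": cfg.seed,
            "alpha": cfg.alpha,
            "pval_threshold": cfg.pval_threshold,
            "fallback_threshold": cfg.fallback_threshold,
            "clump_r2": cfg.clump_r2,
            "clump_window_kb": cfg.clump_window_kb,
            "ivw_model": cfg.ivw_model,
            "fdr_note": _FDR_NOTE,
        }
    }
    try:
        report["stage1"] = _stage1_grid(exposures, outcomes, ld, cfg)
    except MrMediateError as exc:
        _flush_partial(report, cfg)
        raise type(exc)(f"stage 1 failed: {exc}") from exc

    if cfg.bidirectional:
        try:
            reverse_exposures = {
                tid: SummaryStatsTable(tid, "exposure", t.data.copy(), dict(t.provenance))
                for tid, t in outcomes.items()
            }
            reverse_outcomes = {
                tid: SummaryStatsTable(tid, "outcome", t.data.copy(), dict(t.provenance))
                for tid, t in exposures.items()
            }
            report["reverse"] = _stage1_grid(reverse_exposures, reverse_outcomes, ld, cfg)
        except MrMediateError as exc:
            _flush_partial(report, cfg)
            raise type(exc)(f"bidirectional stage failed: {exc}") from exc

    called_pairs = [
        (exp_id, out_id)
        for out_id, per_exp in report["stage1"].items()
        for exp_id, block in per_exp.items()
        if block["call"].verdict in {"causal", "suggestive"}
    ]
    report["called_pairs"] = called_pairs

    stage2: dict = {}
    mediation_results: list[med.MediationResult] = []
    try:
        for exp_id, out_id in called_pairs:
            for med_id, med_tab in mediators.items():
                triple = mediation_triple_analysis(
                    exposures[exp_id],
                    med_tab,
                    outcomes[out_id],
                    ld=ld,
                    cfg=cfg,
                    total_estimate=report["stage1"][out_id][exp_id]["estimates"]["ivw"],
                )
                stage2.setdefault(out_id, {}).setdefault(exp_id, {})[med_id] = triple
                if triple["accepted"]:
                    mediation_results.append(triple["mediation"])
    except MrMediateError as exc:
        report["stage2"] = stage2
        _flush_partial(report, cfg)
        raise type(exc)(f"stage 2 failed: {exc}") from exc

    report["stage2"] = stage2
    report["mediation"] = mediation_results

    if cfg.output_dir:
        _write_report(report, cfg.output_dir)
    return report


def _flush_partial(report: dict, cfg: RunConfig) -> None:
    if cfg.output_dir:
        os.makedirs(cfg.output_dir, exist_ok=True)
        with open(os.path.join(cfg.output_dir, "report.partial.json"), "w") as fh:
            json.dump(_serialize(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
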