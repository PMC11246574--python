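"""Synthetic GWAS summary statistics with known causal and mediation structure.

The generator emulates the three-cornered design the mediation analysis
assumes: an exposure X, a mediator M and an outcome Y, observed only through
GWAS summary statistics from three non-overlapping samples. Per SNP j:

    eaf_j   ~ Uniform(eaf_range)
    gamma_j ~ Normal(0, sigma_gamma^2)            SNP -> exposure
    eta_j   ~ Normal(0, sigma_eta^2)              SNP -> mediator, not via X
    alpha_j =  0                  with prob 1 - pi_pleio
            ~ Normal(mu_alpha, sigma_alpha^2)     otherwise (horizontal pleiotropy)

    m_j     = delta * gamma_j + eta_j             true SNP -> mediator
    Gamma_j = tau_direct * gamma_j + beta2 * m_j + alpha_j

so the exposure's total causal effect on the outcome is
``tau_direct + delta * beta2`` and the mediated share is
``delta * beta2 / total``. The ``eta_j`` component gives the mediator
instrument strength conditional on the exposure — without it the
mediator-on-outcome effect beta2 is not identifiable from the multivariable
regression, because the SNP-mediator column would be an exact multiple of
the SNP-exposure column. Setting ``sigma_eta = 0`` recovers that degenerate
model.

Reported estimates are the truths plus independent Normal noise with the
standardized-trait standard error ``1 / sqrt(2 * n * eaf * (1 - eaf))``;
p-values are two-sided Normal. Noise for the three tables comes from named
substreams of one master seed, so the tables behave as three independent
samples (the two-sample assumption) and adding a table never perturbs
existing draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import SUMSTATS_COLUMNS, LDMatrix, SummaryStatsTable
from .errors import ConfigurationError, InputError

# Fixed substream indices: adding new streams at the end never changes
# draws from existing ones.
_SUBSTREAMS = {
    "eaf": 0,
    "gamma": 1,
    "eta": 2,
    "pleiotropy": 3,
    "exposure": 4,
    "mediator": 5,
    "outcome": 6,
    "outlier": 7,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, collision-free child generator of a master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_SUBSTREAMS[name],))
    )


@dataclass
class SimulationConfig:
    """Generating parameters for one exposure/mediator/outcome study triple.

    Defaults encode the reference condition used throughout the test suite:
    J = 100 independent instruments, three GWAS of n = 100,000 each, a direct
    exposure->outcome effect of 0.85 and a mediated path 0.3 x 0.5, i.e. a
    total effect of 1.0 of which 15% is mediated, and no horizontal
    pleiotropy. ``sigma_gamma = 0.1`` puts instruments in the
    strong-instrument regime the estimators assume: per-SNP F is about
    ``(sigma_gamma / se)^2 ~ 400`` at n = 1e5, so regression dilution from
    noise in the SNP-exposure estimates ((se / sigma_gamma)^2 = 0.25%) is
    negligible. ``sigma_eta = 0.025`` keeps the mediator's conditional
    instrument strength well above the per-SNP measurement noise floor
    (se ~ 0.005 at n = 1e5, so beta2 attenuation stays at the few-percent
    level) while keeping the mediator-driven share of outcome heterogeneity
    moderate.
    """

    J: int = 100
    n_exp: int = 100_000
    n_med: int = 100_000
    n_out: int = 100_000
    tau_direct: float = 0.85
    delta: float = 0.3
    beta2: float = 0.5
    pi_pleio: float = 0.0
    mu_alpha: float = 0.0
    sigma_alpha: float = 0.05
    sigma_gamma: float = 0.1
    sigma_eta: float = 0.025
    eaf_range: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def validate(self) -> None:
        if self.J < 2:
            raise ConfigurationError("J must be >= 2")
        for name in ("n_exp", "n_med", "n_out"):
            if getattr(self, name) < 100:
                raise ConfigurationError(f"{name} must be >= 100")
        if not (0.0 <= self.pi_pleio <= 1.0):
            raise ConfigurationError("pi_pleio must lie in [0, 1]")
        if self.sigma_alpha < 0:
            raise ConfigurationError("sigma_alpha must be >= 0")
        if self.sigma_eta < 0:
            raise ConfigurationError("sigma_eta must be >= 0")
        if self.sigma_gamma <= 0:
            raise ConfigurationError("sigma_gamma must be > 0")
        lo, hi = self.eaf_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigurationError("eaf_range must be an interval within (0, 1)")


@dataclass
class SimulationTruth:
    """The generating parameters against which recovery is tested."""

    total_effect: float
    mediation_proportion: float
    tau_direct: float
    delta: float
    beta2: float
    gamma: np.ndarray = field(repr=False, default=None)
    eta: np.ndarray = field(repr=False, default=None)
    alpha: np.ndarray = field(repr=False, default=None)
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("gamma", "eta", "alpha"):
            d[key] = np.asarray(d[key]).tolist()
        return d


def _se_standardized(n: int, eaf: np.ndarray) -> np.ndarray:
    """Standard error of a per-allele effect on a standardized trait."""
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def _positions(n_snps: int, block_size: int = 1) -> tuple[list[str], list[int]]:
    """Chromosome/position layout: each LD block on its own chromosome label,
    SNPs within a block 1 kb apart (well inside any clumping window), blocks
    trivially beyond any window because they never share a chromosome."""
    chroms, poss = [], []
    for j in range(n_snps):
        block, offset = divmod(j, block_size)
        chroms.append(str(block + 1))
        poss.append(1000 * (offset + 1))
    return chroms, poss


def _table(trait_id, role, snp_ids, chroms, poss, eaf, truth, n, rng) -> SummaryStatsTable:
    se = _se_standardized(n, eaf)
    beta = truth + rng.normal(0.0, se)
    pval = 2.0 * stats.norm.sf(np.abs(beta) / se)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chroms,
            "pos": poss,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
        }
    )
    df["pos"] = df["pos"].astype("int64")
    df["n"] = df["n"].astype("Int64")
    return SummaryStatsTable(trait_id, role, df[SUMSTATS_COLUMNS])


def simulate_study_triple(
    config: SimulationConfig,
) -> tuple[SummaryStatsTable, SummaryStatsTable, SummaryStatsTable, SimulationTruth]:
    """Generate (exposure, mediator, outcome) summary statistics plus truth.

    Identical configs (including the seed) give bit-identical outputs.
    """
    config.validate()
    J, seed = config.J, config.seed

    eaf = substream(seed, "eaf").uniform(*config.eaf_range, size=J)
    gamma = substream(seed, "gamma").normal(0.0, config.sigma_gamma, size=J)
    eta = substream(seed, "eta").normal(0.0, config.sigma_eta, size=J)

    rng_p = substream(seed, "pleiotropy")
    is_pleio = rng_p.random(J) < config.pi_pleio
    alpha = np.where(
        is_pleio, rng_p.normal(config.mu_alpha, config.sigma_alpha, size=J), 0.0
    )

    m = config.delta * gamma + eta
    big_gamma = config.tau_direct * gamma + config.beta2 * m + alpha

    snp_ids = [f"rs{j + 1:05d}" for j in range(J)]
    chroms, poss = _positions(J)

    exposure = _table(
        "exposure", "exposure", snp_ids, chroms, poss, eaf, gamma, config.n_exp,
        substream(seed, "exposure"),
    )
    mediator = _table(
        "mediator", "mediator", snp_ids, chroms, poss, eaf, m, config.n_med,
        substream(seed, "mediator"),
    )
    outcome = _table(
        "outcome", "outcome", snp_ids, chroms, poss, eaf, big_gamma, config.n_out,
        substream(seed, "outcome"),
    )

    total = config.tau_direct + config.delta * config.beta2
    proportion = config.delta * config.beta2 / total if total != 0 else float("nan")
    truth = SimulationTruth(
        total_effect=total,
        mediation_proportion=proportion,
        tau_direct=config.tau_direct,
        delta=config.delta,
        beta2=config.beta2,
        gamma=gamma,
        eta=eta,
        alpha=alpha,
        seed=seed,
    )
    return exposure, mediator, outcome, truth


def simulate_ld_blocks(
    snp_ids: list[str], block_size: int, within_r2: float, seed: int = 0
) -> LDMatrix:
    """Block-diagonal LD: consecutive SNPs share a block with constant r2.

    Within-block off-diagonal entries equal ``within_r2``; between blocks r2
    is 0; the diagonal is 1. Positions place same-block SNPs 1 kb apart and
    different blocks on different chromosome labels, so any physical
    clumping window separates blocks and contains each block.
    """
    if block_size < 1:
        raise ConfigurationError("block_size must be >= 1")
    if not (0.0 <= within_r2 <= 1.0):
        raise ConfigurationError("within_r2 must lie in [0, 1]")
    J = len(snp_ids)
    r2 = np.zeros((J, J))
    for start in range(0, J, block_size):
        stop = min(start + block_size, J)
        r2[start:stop, start:stop] = within_r2
    np.fill_diagonal(r2, 1.0)
    chroms, poss = _positions(J, block_size)
    return LDMatrix(snp_ids=list(snp_ids), r2=r2, positions=list(zip(chroms, poss)))


def inject_outliers(
    table: SummaryStatsTable, snp_ids: list[str], shift_in_ses: float, seed: int = 0
) -> SummaryStatsTable:
    """Shift the beta of each target SNP by ``shift_in_ses`` standard errors.

    The shift sign is drawn per target from the ``outlier`` substream of
    ``seed``; p-values of shifted rows are recomputed; all other rows are
    returned unchanged. Used to plant detectable pleiotropic outliers for
    outlier-test benchmarks.
    """
    unknown = set(snp_ids) - set(table.snp_ids)
    if unknown:
        raise InputError(f"unknown target snp_ids: {sorted(unknown)}")
    df = table.data.copy()
    rng = substream(seed, "outlier")
    for snp in snp_ids:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        idx = df.index[df["snp_id"] == snp][0]
        if shift_in_ses == 0:
            continue
        se = df.at[idx, "se"]
        df.at[idx, "beta"] = df.at[idx, "beta"] + sign * shift_in_ses * se
        df.at[idx, "pval"] = max(
            2.0 * stats.norm.sf(abs(df.at[idx, "beta"]) / se), np.finfo(float).tiny
        )
    prov = dict(table.provenance)
    prov["injected_outliers"] = {"snp_ids": list(snp_ids), "shift_in_ses": shift_in_ses}
    return SummaryStatsTable(table.trait_id, table.trait_role, df, prov)
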