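# Methods

This note documents the statistical procedures implemented in `mrmediate`,
the assumptions behind them, the synthetic-data generator used to validate
them, and the numerical and design choices that were genuinely open.

## Setting and assumptions

All estimators operate on GWAS summary statistics: per-SNP effect estimates
with standard errors for an exposure, optionally a mediator, and an
outcome, from non-overlapping samples (two-sample MR). Valid causal
inference requires the three instrumental-variable assumptions: instruments
are (1) strongly associated with the exposure, (2) independent of
exposure–outcome confounders, and (3) affect the outcome only through the
exposure. The sensitivity battery exists because (3) — no horizontal
pleiotropy — is untestable directly and frequently violated.

## Instrument selection and harmonization

Instruments are SNPs with p strictly below 5×10⁻⁸ (a relaxed 5×10⁻⁶
fallback is applied, and logged, when nothing passes — the convention for
self-reported traits with few genome-wide hits), pruned to mutual
independence by greedy clumping: visit SNPs by ascending p (ties broken by
SNP id so results are reproducible), keep the best, discard neighbours with
r² > 0.001 within 10,000 kb on the same chromosome. A local blocklist file
removes SNPs known to act through confounders (smoking, alcohol, diabetes,
...), replacing interactive variant-annotation look-ups with a reviewable
input. "Retain when r² below the threshold" is the universal reading of an
independence filter and is what the implementation does.

Instrument strength: with the effect-allele frequency available,
R²ⱼ = 2·eaf(1−eaf)·βⱼ² (standardized trait) and
Fⱼ = (n−2)R²ⱼ/(1−R²ⱼ); without it, the z-score fallback Fⱼ = (βⱼ/seⱼ)²
with R²ⱼ = Fⱼ/(Fⱼ+n−2), flagged per SNP. The overall F for k instruments
is ((n−k−1)/k)·R²/(1−R²) with R² = ΣR²ⱼ. F > 10 is the conventional
weak-instrument screen.

Harmonization aligns every table to the first exposure's effect allele:
swapped alleles flip the beta sign, strand-complemented alleles are
complemented then aligned, and palindromic (A/T, C/G) SNPs — whose strand
cannot be resolved from alleles — are dropped (`drop_all`) or aligned by
allele frequency (`infer_by_eaf`, the default) unless either frequency lies
within 0.08 of 0.5, in which case they are dropped as ambiguous. Every
action is logged per SNP. There is no proxy-SNP lookup: instruments missing
from the outcome GWAS are simply lost at intersection.

## Estimators

**IVW** (primary): weighted regression of Γ̂ on γ̂ through the origin,
weights 1/se(Γ̂)². Standard errors default to multiplicative random
effects — inflated by √max(1, Q/df) — which equal the fixed-effect errors
under homogeneity and are never narrower; the truncation at 1 is the
standard convention. Fixed-effect errors are available by option.

**MR-Egger**: the same regression with a free intercept after orienting all
SNPs so γ̂ ≥ 0 (without orientation the intercept is not interpretable as
average directional pleiotropy). The slope is consistent under InSIDE
(instrument strength independent of direct effects); the intercept's
two-sided test is the pleiotropy check used by the decision layer.

**Weighted median**: Wald ratios Γ̂ⱼ/γ̂ⱼ weighted by γ̂ⱼ²/se(Γ̂ⱼ)²,
combined by interpolating the cumulative weight midpoints at 1/2;
consistent when ≥50% of weight is on valid instruments. The SE comes from a
parametric bootstrap (B = 1000 by default, seeded) resampling both γ̂ and
Γ̂ from their sampling distributions.

**MR-PRESSO**: the observed statistic is the sum of weighted squared
leave-one-out residuals. Its null distribution is simulated by resampling
*both* sides — γ̂* ~ N(γ̂, se_γ²) and Γ̂* ~ N(γ̂·β̂₋ⱼ, se_Γ²) — and
refitting each simulated dataset with the same leave-one-out procedure
against the resampled exposures. Simulating only the outcome side leaves
the observed residuals over-dispersed by β²se_γ² relative to the null and
makes the global test strongly anti-conservative (measured KS distance 0.42
from uniform under the null, versus 0.05 with both sides resampled).
Per-SNP outlier p-values are raw empirical fractions of the simulated
residual distribution — not (r+1)/(n+1) smoothed, since after Bonferroni
adjustment the smoothed minimum J/(n_sim+1) could never fall below the 0.05
threshold at the default settings, making outliers undetectable by
construction. The corrected estimate is IVW on the non-flagged SNPs; the
distortion test compares the corrected-minus-raw shift against shifts from
removing random subsets of the same size.

**Multivariable MR**: MV-IVW regresses Γ̂ on the J×K exposure matrix
(no intercept, same weights and random-effects scaling, df = J−K);
MVMR-Egger adds a common intercept after orienting SNPs to the first
exposure; MVMR-median minimizes the weighted L1 objective
Σ√wⱼ·|Γ̂ⱼ − Σθₖγ̂ⱼₖ| (median regression on √w-scaled data, bootstrap SEs);
MVMR-Lasso gives each SNP a lasso-penalized free intercept and re-estimates
by MV-IVW on the SNPs whose intercept shrinks to zero. The lasso penalty
descends a geometric grid from the smallest λ that zeroes every intercept
and stops at the first λ whose valid-SNP Cochran Q is below the chi-square
5% critical value — the fewest exclusions consistent with homogeneity.
Conditional instrument strength per exposure is the mean weighted squared
residual of its SNP effects regressed on the other exposures' effects
(df J−K+1); it approaches the marginal F when instrument sets are
orthogonal and collapses toward zero for collinear exposures. At K = 1 it
reduces to the mean per-SNP chi-square, which matches the R²-based overall
F only in the small-R² regime — the equality is asymptotic, not algebraic.

## Decision layer

Q-values are Benjamini–Hochberg step-up, computed within each outcome
across its exposures (one family per outcome). Local-FDR tools produce
different q-values; BH was chosen for determinism and transparency, and the
report header says so. A pair is called **causal** when the IVW p < 0.05
and q < 0.05, at least one sensitivity estimator is significant with the
same sign, and the Egger intercept shows no pleiotropy (p ≥ 0.05);
**suggestive** relaxes only the FDR rule; **not_robust** marks primary
significance failing a robustness rule; otherwise **no_evidence**.
Covariates for multivariable adjustment are exposures with |β| > 0.5 and
p < 0.05 — the magnitude rule is applied to the absolute value so strong
protective effects qualify.

Mediators are screened by two criteria: the exposure must causally affect
the mediator, and the mediator must affect the outcome both with and
without adjustment for the exposure, with a consistent direction. For
accepted mediators the indirect effect is β₁β₂ (β₁ from UVMR of the
exposure on the mediator; β₂ from MVMR of the outcome on mediator plus
exposure), the proportion is β₁β₂/total, and its 95% CI uses the
first-order Delta variance

Var(p̂) = (β₂/T)²σ₁² + (β₁/T)²σ₂² + (β₁β₂/T²)²σ_T²,

treating β₁ and β₂ as independent (they come from separate fits on
separate outcome data) and ignoring the covariance of each with the total
effect. Both covariances are positive in this design — β₁ and the total
share the exposure GWAS, β₂ and the total share the outcome GWAS — so the
interval is mildly conservative; simulation at the reference condition puts
its coverage near the top of the nominal range (≈0.97). A variant treating
the total as fixed is reported in diagnostics. Negative point proportions
are floored at 0% and flagged; flooring never alters the indirect effect or
the interval. Proportions are printed as percentages to one decimal;
full precision goes to JSON.

## The synthetic generator

Per SNP: eaf ~ U(0.1, 0.9); γⱼ ~ N(0, σ_γ²) (SNP→exposure);
ηⱼ ~ N(0, σ_η²) (SNP→mediator not via the exposure); with probability
π_pleio a pleiotropic effect αⱼ ~ N(μ_α, σ_α²), else 0. True effects:
mⱼ = δγⱼ + ηⱼ and Γⱼ = τγⱼ + β₂mⱼ + αⱼ, so the exposure's total effect is
τ + δβ₂ and the mediated share δβ₂/(τ+δβ₂). Reported estimates add
independent normal noise with the standardized-trait SE
1/√(2n·eaf(1−eaf)); the three tables draw from named substreams of one
master seed, so they behave as independent samples and adding a table never
perturbs existing draws.

Defaults (the reference condition): J = 100, n = 100,000 per GWAS, τ = 0.85,
δ = 0.3, β₂ = 0.5 (total 1.0, 15% mediated), no pleiotropy. σ_γ = 0.1 puts
instruments in the strong-instrument regime the estimators assume (per-SNP
F ≈ (σ_γ/se)² ≈ 400; regression dilution (se/σ_γ)² ≈ 0.25%). σ_η = 0.025
keeps the mediator's conditional instrument strength well above the
measurement-noise floor (se ≈ 0.005 at n = 10⁵), so the attenuation of β₂
from noise in the mediator column stays at the few-percent level. The ηⱼ
component is essential, not cosmetic: with mⱼ = δγⱼ exactly, the mediator
has zero instrument strength conditional on the exposure and β₂ is not
identifiable from the multivariable regression (the two design columns
become two noisy proxies of the same γⱼ and the coefficient split is
determined by their noise, not by β₂).

What the generator does **not** emulate: binary/logit traits (all traits
are continuous and standardized; the source analyses include self-reported
binary traits), MAF-dependent effect sizes, sample overlap, winner's curse,
realistic LD (blocks are constant-r², block-diagonal), or
mediator-specific instruments beyond the ηⱼ mechanism. Passing calibration
on this generator therefore demonstrates correctness of the estimators
under their own assumptions, not robustness to those real-data features.

## Validation design and problem sizes

The calibration batteries use: 200 replicates for IVW bias/coverage (mean
bias < 0.02, coverage within [0.93, 0.97]); 1000 for the Egger intercept
type-I error under balanced pleiotropy (σ_α = 0.005, comparable to the
per-SNP SE); 100 for weighted-median robustness (40% invalid instruments
with μ_α = 0.2 — pleiotropic effects comparable to the main per-SNP
effects); 100 for MR-PRESSO detection of a 10-SE planted outlier (J = 50,
n_sim = 1000); 500/100 for mediation CI coverage and median absolute
proportion error. Estimator-calibration batteries use all J simulated SNPs
as instruments — p-value selection would superimpose winner's-curse
selection bias on the quantity being measured — while the mediation battery
and the pipeline examples run the full selection path. These sizes give
Monte-Carlo standard errors comfortably below the tolerances they are
checked against (e.g. ±0.008 on a 95% coverage estimate at 500
replicates).

## Numerical choices and limitations

- Wald-ratio SEs are first order (se_Γ/|γ̂|), ignoring se_γ; adequate past
  the F > 10 screen. No second-order correction is implemented.
- Normal (not t) 95% intervals throughout, including Egger.
- p-values are clipped below at the smallest positive double rather than
  reported as 0.
- Weighted-regression solutions go through explicit normal equations with a
  rank check; collinear exposure columns raise a singular-design error
  naming the offending pair.
- QuantReg (IRLS) solves the weighted L1 problem for MVMR-median; exact-fit
  data converges to machine precision, and non-convergence raises rather
  than returning a silent partial fit.
- The MVMR-Lasso λ grid is geometric (factor 0.85, 50 points) from λ_max;
  the retained set is monotone in λ in practice but the joint θ/intercept
  refit does not guarantee it combinatorially.
- Bidirectional analysis swaps exposure and outcome roles wholesale and
  re-runs stage 1; it shares the FDR family convention.
- Reports avoid timestamps and unordered containers, so a fixed
  configuration and seed reproduce byte-identical JSON.
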