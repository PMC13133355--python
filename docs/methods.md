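# Methods

This note documents the models implemented in `carriermr`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions a maintainer would want to know.
No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Two-sample MR model

All univariable estimators operate on harmonized per-SNP pairs
(β̂_Xj, se_Xj; β̂_Yj, se_Yj) under the working model

    β̂_Yj = θ_T β_Xj + α_j + ε_j,   ε_j ~ N(0, se_Yj²),

where θ_T is the causal effect per unit exposure (per year of ANM or AAM,
on the log hazard/odds scale) and α_j is SNP j's direct (pleiotropic)
effect, zero for a valid instrument.

* **IVW**: weighted regression through the origin, weights 1/se_Yj²;
  closed form θ̂ = Σw β_X β_Y / Σw β_X². The default flavour is
  multiplicative random effects — SE inflated by max(1, √(Q/df)) — because
  heterogeneity-aware IVW is the natural companion of a reported Q;
  fixed-effects is available by flag and both are labelled.
* **Penalization** multiplies weights by min(1, 20·p_j), p_j the χ²₁
  upper-tail probability of SNP j's Q contribution at the unpenalized
  estimate. The constant 20 follows the convention of the penalized
  estimator family and is configurable.
* **Robust** fits use a Tukey biweight M-estimator (tuning constant 4.685,
  IRLS on inverse-variance-standardized residuals with MAD scale,
  convergence 1e−8). The reported SE uses the final robust weights in the
  WLS formula with the same multiplicative inflation — an approximation,
  adequate for a sensitivity row.
* **MR-Egger** adds an intercept after re-orienting every SNP so
  β̂_Xj > 0 (required for the intercept to estimate average directional
  pleiotropy). The slope is the causal estimate under InSIDE.
* **Medians**: simple, inverse-variance-weighted, and penalized-weighted
  50th percentiles of the per-SNP Wald ratios, with linear interpolation
  across the midpoint-standardized cumulative weight function. SEs come
  from a seeded parametric bootstrap (default 1000 draws) perturbing both
  β̂_X and β̂_Y at their reported SEs.
* **Radial outliers**: the radial reformulation (β_Y/se_Y on β_X/se_Y
  through the origin) has slope equal to IVW and per-SNP Q contributions
  summing exactly to Cochran's Q; SNPs with contribution p < 0.05 are
  removed, by default iterating until none remain (single-pass available —
  with one pass the flagged set matches the first iteration only).
* **Heterogeneity**: Q at the IVW estimate, df = J−1, I² = max(0,(Q−df)/Q)
  with a test-based (ln H) confidence interval.

Two-sided p-values use the normal reference distribution throughout, and
every log-scale estimate is reported alongside its exponentiated HR/OR.

## Horseshoe pleiotropy-robust model

`mr_horse` fits, per SNP,

    β̂_Yj ~ N(θ β_j + α_j, se_Yj²),   β̂_Xj ~ N(β_j, se_Xj²),
    α_j ~ N(0, τ²λ_j²),
    β_j | α_j ~ N(m + ρ_j σ_b α_j/(τλ_j), σ_b²(1−ρ_j²)),

with λ_j, τ, σ_b ~ half-Cauchy(0,1), ρ_j = 2u_j−1, u_j ~ Beta(10,10), and
θ, m ~ N(0,1). The ρ_j coupling lets direct effects track instrument
strength, so the estimator remains consistent under correlated pleiotropy
(InSIDE violations) while the horseshoe shrinks valid SNPs' α_j hard
toward zero.

Sampling is Metropolis-within-Gibbs: θ, m, α, β are conditionally normal
and Gibbs-updated (α and β vectorized across SNPs); λ, τ, σ_b use
log-scale random-walk proposals (steps 1.0/0.3/0.3) and ρ an atanh-scale
walk (step 0.5). Defaults: 4 chains from over-dispersed starts around the
IVW estimate, 1000 warmup + 1000 retained draws per chain. Convergence is
gated on the rank-normalized split-R̂ of θ (arviz); R̂ > 1.05 flags the
result non-converged with a warning. The causal estimate is the posterior
mean; the 95% interval is the 2.5–97.5 percentile range of pooled draws.

## Multivariable MR and mediation

`mvmr_fit` regresses β̂_Yj on (β̂_Xj, β̂_Mj, …) without intercept, weights
1/se_Yj², with the same multiplicative random-effects SE inflation; an
all-zero mediator column is dropped with coefficient fixed at 0 (the
nested univariable model). A conditional F-like diagnostic is reported per
exposure: the inverse-variance-weighted mean square of that exposure's
betas after projecting out the others.

`mediation_decompose` computes total (univariable IVW), direct
(multivariable exposure coefficient) and mediated = total − direct on the
*identical* SNP set, so the decomposition identity holds exactly by
construction. The mediated-effect SE is a seeded parametric bootstrap
(default 1000) perturbing all betas at their reported SEs; a delta-method
value from the bootstrap covariance is stored as a cross-check, and a
product-method estimate (exposure→mediator slope × mediator coefficient)
is available as a diagnostic. SHBG adjustment is the same operation with
SHBG as the covariate; nothing is special-cased.

## Harmonization

Tables are matched by variant ID only (chr/pos are opaque metadata;
LD-surrogate substitution is accepted as a precomputed two-column map
applied beforehand). Where effect alleles are swapped, betas are negated
and frequencies complemented; non-palindromic strand flips are resolved
by allele complementation. A/T and C/G SNPs cannot be strand-resolved
from labels: within the frequency window 0.5 ± 0.08 (configurable; the
source analyses say only "close to 0.5") they are excluded as ambiguous,
outside it they are aligned by frequency matching (eaf vs 1−eaf), which
overrides the allele labels. Optional re-orientation to the
exposure-increasing allele is a pure reparameterization; an end-to-end
test asserts all estimators are invariant to it. The exclusion log
partitions the input: |intersection| = |retained| + |excluded|.

## Carrier-cohort validation

**Phenotype derivation.** Natural menopause is an event only when reported
as the sole reason periods stopped and when the event age precedes RRSO,
any cancer diagnosis and interview; the event age adds one year to "age at
last menstruation" when derived from "no period in the past year", unless
an explicit age at menopause is recorded. Premenopausal classifications
(period in the past year; periods not stopped; medication/oral
contraceptives before age 40; pregnancy; breastfeeding) censor at the
earliest of RRSO/diagnosis/death/interview. Anyone premenopausal at the
administrative cap (60 years) is recorded as an event at the cap.
RRSO/hysterectomy as the reason censors at the age at last period. Records
with the needed ages missing, or with contradictory timing, are excluded
with a machine-readable reason. Two under-specified corners were resolved
as: medication/OC stopping at 40+ is treated like other non-natural
stopping (censored at last period), and a missing interview age where the
40-year rule would apply excludes the record.

**Weighted-cohort correction.** Within age strata at event/censoring
(default breakpoints 18/30/40/50/61), affected individuals get weight
p_s N_s/n_aff and unaffected (1−p_s)N_s/(N_s−n_aff), where p_s is the
cumulative incidence at the stratum midpoint from the supplied
age-specific rate table. The weighted affected fraction then equals p_s
identically (asserted to 1e−12). Strata lacking affected or unaffected
members are merged leftward with a warning. The exact weight formula in
the source methodology is in cited prior work; this stratum-matching form
is the direct implementable reading of matching observed to established
incidence.

**Censored regression.** The trait model is a right-censored homoscedastic
normal (Tobit-type) likelihood — events contribute the normal density,
censored rows the upper tail, each weighted by its sampling weight —
maximized by BFGS over (coefficients, log σ) with analytic gradients,
started from OLS on the uncensored rows, gradient tolerance 1e−8 (scaled),
200 iterations max. Variance is a cluster-level sandwich: per-observation
scores summed within family, G/(G−1) small-sample correction, Hessian by
central differences of the analytic gradient. With no censoring the MLE
equals OLS (asserted to 1e−6); AAM validation reuses the same fit with all
rows uncensored. Covariates are the standardized score plus birth-cohort
indicators (<1940, 1940–49, 1950–59, ≥1960 for ANM; two further bins for
AAM), reference the earliest.

## Synthetic-data generators

**Summary statistics.** True per-allele exposure effects are N(0, 0.08²)
years — a few weeks per allele, the magnitude reproductive-trait GWAS
report. Reported SEs are log-uniform, 0.004–0.012 on the exposure side
(a ~200k-sample trait GWAS) and 0.01–0.04 on the outcome side (a carrier
GWAS of tens of thousands), independent of effect size — the simplest
model consistent with two-sample MR, since no SE model is prescribed by
the source analyses. Effect-allele frequencies are uniform on (0.05,
0.95). Pleiotropy modes: *balanced* α ~ N(0, sd²); *directional*
α = sign(β_X)·N(mean, sd²) — defined on the exposure-increasing allele,
where the Egger intercept lives, since a fixed-sign α under symmetric
allele coding would cancel on orientation; *correlated*
α = ρ·scaled(β_X) + residual (default ρ = 0.7), the standard InSIDE
violation. The invalid set is a random fraction, or optionally the
weakest instruments (`invalid_weakest`), which concentrates contamination
at low weight — the regime in which majority-validity estimators retain
nominal behaviour. A configurable fraction of SNPs has alleles swapped
and/or strand-flipped between tables, and ~2% are palindromic, to
exercise harmonization. Reported betas are drawn around the truth at the
reported SEs. A single seeded generator produces all draws in a
documented order, so identical seeds give byte-identical tables.

**Carrier cohort.** Families of 1–3 women carry dosages drawn binomially
at the score model's frequencies; latent ANM is trait_mean +
gs_true_effect·z + family effect + noise with total SD trait_sd (defaults
50 ± 4 years, 1.5 y/SD, no family effect — dependence enters the analysis
only through clustered variance, matching how the analysis treats it).
Censoring processes: RRSO (exponential hazard 0.015/y from age 30),
death (0.003/y from 40), interview age uniform 25–70, cancer diagnosis
from the scenario's age-specific incidence table via piecewise-exponential
inversion. Ascertainment accepts families with an affected member always
and others with probability 1/oversample_affected (default 2) — a
stand-in for testing-based recruitment, whose real mechanism is not
quantitatively specified anywhere; the knob is not a claim about any
actual study. Questionnaire fields are then written consistently with the
latent trait and censoring history, so the phenotype-derivation rules are
exercised end to end (a test asserts every derived event age equals the
latent truth).

**What passing tests do and do not show.** The generators match the
analysis' own assumptions: linear trait model, normal errors at reported
SEs, uncorrelated instruments, homoscedastic censored-normal trait,
non-informative censoring. Passing recovery and calibration tests
therefore validates the estimators and their implementation, not
robustness to LD between instruments, SE misreporting, winner's-curse in
instrument selection, informative censoring, or real questionnaire
messiness — none of which are simulated.

## Numerical choices and edge cases

* Weighted-median interpolation uses midpoint cumulative weights; a SNP
  holding essentially all weight pins the median to its ratio up to an
  interpolation term of order (other weight)/(dominant weight).
* Zero exposure betas are excluded from ratio estimates (logged count);
  bootstrap draws that hit exactly zero are nudged to the smallest float.
* The Tobit fit accepts BFGS "precision loss" terminations when the
  scaled gradient is below 1e−4, and raises otherwise with the gradient
  norm; the NLL path over accepted iterates is recorded and asserted
  non-increasing in tests.
* Degenerate MVMR columns (all-zero betas) are dropped with coefficient 0
  rather than failing; genuinely collinear designs raise with the
  condition number (threshold 1e8).
* Coverage, breakdown and calibration tests run at reduced replicate
  counts and cohort sizes (e.g. 120–500 replicates, 250–2000 families),
  chosen to keep the whole suite fast while leaving binomial noise well
  inside the asserted bands.

## Known limitations

* No LD: instruments are simulated and analysed as uncorrelated, and no
  proxy search is performed (surrogate maps are accepted as input).
* The horseshoe sampler is a random-walk/Gibbs hybrid, not HMC; for very
  small SNP sets or extreme shrinkage it mixes more slowly, which the
  split-R̂ gate surfaces rather than hides.
* Age-stratified outcome analyses are supported by supplying one outcome
  table per stratum and comparing estimates (`compare_estimates`); the
  package does not estimate stratum-specific per-SNP effects itself.
* The retrospective-likelihood per-SNP hazard estimation used to produce
  real carrier outcome statistics, genotype QC and imputation are out of
  scope; outcome tables are inputs.
* No multiple-testing adjustment is applied across estimator rows; the
  reported p-values are unadjusted two-sided, matching how such tables
  are conventionally presented.
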