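# carriermr

Two-sample Mendelian randomization (MR) of reproductive-timing traits on
breast-cancer risk in *BRCA1*/*BRCA2* pathogenic-variant carriers.

## The problem

Whether age at natural menopause (ANM) and age at menarche (AAM) causally
modify breast-cancer risk in *BRCA1*/*BRCA2* carriers is hard to settle
observationally: carriers are rare, frequently undergo risk-reducing
salpingo-oophorectomy (RRSO), and retrospective series are ascertained
through clinical genetic testing, which oversamples affected women. MR
side-steps these biases by using trait-associated SNPs as instrumental
variables: per-allele effects on the trait (from population GWAS) are
related to per-allele effects on carrier breast-cancer risk (log hazard
ratios from carrier consortium GWAS).

`carriermr` implements that full analysis chain as a tested library plus
thin analysis drivers, exercised end-to-end on synthetic data with known
ground truth:

1. **Genetic scores** (`carriermr.scores`) — GS = Σₖ βₖ xₖ over per-allele
   weights and dosages, sample-standardized; the theoretical population
   effect per score SD is √(Σₖ 2pₖ(1−pₖ)βₖ²) under Hardy–Weinberg and
   independence.
2. **Carrier-cohort validation** (`carriermr.cohort`) — derives a
   right-censored ANM phenotype from questionnaire fields (censoring at
   the earliest of RRSO, any cancer diagnosis, death, interview, or age
   60), corrects ascertainment with weighted-cohort sampling weights that
   match observed incidence to established age-specific rates, and fits a
   weighted censored-normal (Tobit-type) regression of the trait on the
   standardized score with family-clustered sandwich SEs.
3. **Harmonization** (`carriermr.sumstats`) — aligns exposure, outcome and
   mediator summary statistics to a shared effect allele, excluding
   strand-ambiguous palindromic SNPs (eaf within 0.08 of 0.5) and
   resolving the rest by frequency matching.
4. **Estimator suite** (`carriermr.mr`) — for the model
   β̂_Yj = θ_T β̂_Xj + ε_Tj, ε_Tj ~ N(0, se(β̂_Yj)²):
   IVW (fixed and multiplicative random effects), penalized and robust
   variants, MR-Egger with its directional-pleiotropy intercept,
   simple/weighted/penalized-weighted medians with bootstrap SEs, radial
   outlier removal, Cochran's Q / I² heterogeneity.
5. **Pleiotropy-robust Bayesian MR** (`carriermr.horse`) — a horseshoe
   shrinkage model on per-SNP direct effects α_j, allowing α_j to
   correlate with instrument strength (InSIDE violations), sampled by
   Metropolis-within-Gibbs with split-R̂ convergence gating.
6. **Multivariable MR mediation** (`carriermr.mvmr`) — β̂_Yj = θ_D β̂_Xj +
   θ_M β̂_Mj + ε_Dj; total (univariable IVW on the same SNPs), direct
   (θ_D), mediated = total − direct with bootstrap SE, as used to separate
   the BMI-mediated component of the AAM effect.
7. **Synthetic data** (`carriermr.synthetic`) — generators for both the
   summary-statistic experiments (configurable balanced / directional /
   correlated pleiotropy) and the ascertained family cohort, with ground
   truth recorded for every draw.

## Worked example

Generate the synthetic study inputs and run the analyses:

```bash
python analysis/01_simulate_inputs.py
python analysis/02_validate_scores.py
python analysis/03_univariable_mr.py
python analysis/04_mediation_mr.py
```

which prints (seed 1):

```
censored regression: 1.466 years later ANM per SD (95% CI 1.244-1.688, p=2.5e-38)
theoretical population value: 1.44 y/SD; 945 events, 3150 censored, 2000 families, 0 records excluded
brca2: IVW HR 1.019 (0.993-1.045, p=0.156); Q p=0.4, I2=2.0%; 13 radial outliers removed -> HR 1.021
brca1: IVW HR 0.970 (0.945-0.995, p=0.017); Q p=0.41, I2=1.6%; 12 radial outliers removed -> HR 0.971
total effect:  HR 0.907 per year (0.886-0.928)
direct effect: HR 0.876 per year (0.845-0.908), BMI-adjusted
```

Reading these numbers: the score validation recovers the generator's
1.44-year-per-SD effect inside its cluster-robust CI despite 77% of the
cohort being censored before natural menopause; the univariable MR HRs are
single noisy realizations whose CIs cover the generating per-year hazard
ratios (1.04 and 0.99); and the mediation decomposition splits the total
AAM effect (generated at HR 0.93/year) into a stronger BMI-adjusted direct
effect (generated at 0.90/year) plus a positive BMI-mediated component.

The same stages are scriptable through the CLI (`carriermr simulate`,
`carriermr harmonize`, `carriermr score`, `carriermr validate`,
`carriermr mr`, `carriermr mvmr`, `carriermr run --config run.yaml`).

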