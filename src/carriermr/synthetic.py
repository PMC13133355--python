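"""Synthetic inputs with known ground truth for every analysis stage.

Two generators:

* :func:`gen_twosample_sumstats` — per-SNP GWAS summary statistics under a
  linear causal model ``by_j = theta * bx_j + theta_M * bm_j + alpha_j``
  with configurable balanced / directional / correlated pleiotropy, plus
  reported estimates drawn around the truth at the reported SEs. A
  configurable fraction of SNPs has alleles swapped or strand-flipped
  between tables to exercise harmonization, and a fraction is palindromic.
* :func:`gen_carrier_cohort` — an ascertained family-based carrier cohort
  with dosages at the score model's allele frequencies, a latent
  reproductive trait linear in the standardized score, competing censoring
  events (RRSO, cancer diagnosis, death, interview) and the questionnaire
  fields the phenotype-derivation rules consume.

All randomness flows through a single seeded generator per call; the draw
order is fixed and documented in each function so fixtures stay stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import IncidenceTable
from .scores import GeneticScoreModel

_NONPAL_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                 ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
_PAL_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ScenarioError(ValueError):
    pass


@dataclass(frozen=True)
class MediatorSpec:
    """Mediator path: SNP -> mediator effects and mediator -> outcome effect.

    ``theta_m`` is the causal effect of the mediator on the outcome (log HR
    per mediator unit); ``exposure_to_mediator`` the linear effect of the
    exposure on the mediator, so the mediated effect of the exposure is
    ``theta_m * exposure_to_mediator``; ``beta_m_sd`` the SD of the
    exposure-independent per-allele SNP -> mediator effects; ``se_m_range``
    the reported-SE range for the mediator association table.
    """

    theta_m: float = 0.0
    beta_m_sd: float = 0.05
    exposure_to_mediator: float = 0.0
    se_m_range: tuple = (0.002, 0.01)
    label: str = "bmi"


@dataclass(frozen=True)
class SumstatsScenario:
    """Generative conditions for a two-sample summary-statistics experiment.

    Defaults mirror the carrier-study regime: a few hundred uncorrelated
    instruments for a reproductive trait measured in years (per-allele
    effects of a few weeks), outcome on the log-HR scale with SEs of the
    size a consortium GWAS of tens of thousands of carriers reports.
    """

    n_snps: int = 288
    theta: float = 0.0  # causal (direct) effect, outcome units / exposure unit
    exposure_beta_sd: float = 0.08  # years per allele
    se_x_range: tuple = (0.004, 0.012)  # exposure GWAS ~200k samples
    se_y_range: tuple = (0.01, 0.04)  # carrier outcome GWAS, tens of thousands
    pleiotropy_mode: str = "none"  # none | balanced | directional | correlated
    pleiotropy_sd: float = 0.0
    pleiotropy_mean: float = 0.0
    prop_invalid: float = 0.0
    invalid_weakest: bool = False  # concentrate pleiotropy in the weakest instruments
    corr_rho: float = 0.7  # alpha ~ rho * scaled(beta_x) + residual (correlated mode)
    mediator_spec: MediatorSpec | None = None
    eaf_range: tuple = (0.05, 0.95)
    flip_fraction: float = 0.3  # alleles swapped between tables
    strand_flip_fraction: float = 0.2  # non-palindromic strand representation flips
    palindromic_fraction: float = 0.02
    seed: int | None = None

    def __post_init__(self):
        if self.n_snps < 3:
            raise ScenarioError("n_snps must be >= 3")
        if not (0.0 <= self.prop_invalid <= 1.0):
            raise ScenarioError("prop_invalid must lie in [0, 1]")
        for name, rng_ in (("se_x_range", self.se_x_range), ("se_y_range", self.se_y_range)):
            if not (0 < rng_[0] <= rng_[1]):
                raise ScenarioError(f"{name} must be strictly positive")
        if not (0.0 < self.eaf_range[0] < self.eaf_range[1] < 1.0):
            raise ScenarioError("eaf_range must be a sub-interval of (0, 1)")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "correlated"):
            raise ScenarioError(f"unknown pleiotropy_mode '{self.pleiotropy_mode}'")


def _log_uniform(rng, lo, hi, n):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), n))


def gen_twosample_sumstats(scenario: SumstatsScenario):
    """Generate exposure / outcome (/ mediator) summary tables plus truth.

    Draw order (single seeded generator): eaf, allele pairs, true exposure
    betas, reported SEs (x then y), invalid-SNP assignment and pleiotropic
    effects, mediator SEs and SNP->mediator effects, reported exposure
    betas, reported mediator betas, reported outcome betas, allele
    swap/strand masks.

    Returns ``(exposure, outcome, mediator_or_None, truth)`` where truth
    holds the causal parameters, per-SNP direct effects and validity flags.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    J = sc.n_snps

    eaf = rng.uniform(*sc.eaf_range, J)
    pal = rng.random(J) < sc.palindromic_fraction
    pair_idx = rng.integers(0, len(_NONPAL_PAIRS), J)
    ea = np.array([_NONPAL_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_NONPAL_PAIRS[i][1] for i in pair_idx])
    pal_idx = rng.integers(0, len(_PAL_PAIRS), J)
    ea[pal] = [_PAL_PAIRS[i][0] for i in pal_idx[pal]]
    oa[pal] = [_PAL_PAIRS[i][1] for i in pal_idx[pal]]

    beta_x = rng.normal(0.0, sc.exposure_beta_sd, J)
    se_x = _log_uniform(rng, *sc.se_x_range, J)
    se_y = _log_uniform(rng, *sc.se_y_range, J)

    invalid = np.zeros(J, dtype=bool)
    alpha = np.zeros(J)
    if sc.pleiotropy_mode != "none" and sc.prop_invalid > 0:
        if sc.invalid_weakest:
            k = int(round(sc.prop_invalid * J))
            invalid[np.argsort(np.abs(beta_x))[:k]] = True
        else:
            invalid = rng.random(J) < sc.prop_invalid
        k = int(invalid.sum())
        if sc.pleiotropy_mode == "balanced":
            alpha[invalid] = rng.normal(0.0, sc.pleiotropy_sd, k)
        elif sc.pleiotropy_mode == "directional":
            # directional pleiotropy is defined on the exposure-increasing
            # allele (the orientation in which the Egger intercept lives)
            alpha[invalid] = np.sign(beta_x[invalid]) * rng.normal(
                sc.pleiotropy_mean, sc.pleiotropy_sd, k)
        elif sc.pleiotropy_mode == "correlated":
            # InSIDE violation: alpha tracks instrument strength
            scaled = beta_x[invalid] / sc.exposure_beta_sd * sc.pleiotropy_sd
            resid = rng.normal(0.0, sc.pleiotropy_sd * np.sqrt(1 - sc.corr_rho**2), k)
            alpha[invalid] = sc.corr_rho * scaled + resid

    med = sc.mediator_spec
    if med is not None:
        se_m = _log_uniform(rng, *med.se_m_range, J)
        delta = rng.normal(0.0, med.beta_m_sd, J)
        beta_m = med.exposure_to_mediator * beta_x + delta
        theta_total = sc.theta + med.theta_m * med.exposure_to_mediator
    else:
        se_m, beta_m = None, np.zeros(J)
        theta_total = sc.theta

    beta_y = sc.theta * beta_x + (med.theta_m * beta_m if med else 0.0) + alpha

    bx_hat = beta_x + se_x * rng.standard_normal(J)
    bm_hat = beta_m + se_m * rng.standard_normal(J) if med else None
    by_hat = beta_y + se_y * rng.standard_normal(J)

    swap = rng.random(J) < sc.flip_fraction
    strand = (rng.random(J) < sc.strand_flip_fraction) & ~pal

    variant_id = np.array([f"rs{i + 1}" for i in range(J)])
    chrom = rng.integers(1, 23, J)
    pos = rng.integers(1, 2_000_000, J).cumsum()

    def table(beta, se, flipped):
        ea_t, oa_t = ea.copy(), oa.copy()
        eaf_t = eaf.copy()
        beta_t = np.asarray(beta, float).copy()
        if flipped:
            ea_t[swap], oa_t[swap] = oa[swap], ea[swap]
            beta_t[swap] *= -1.0
            eaf_t[swap] = 1.0 - eaf_t[swap]
            ea_t[strand] = [_COMPLEMENT[a] for a in ea_t[strand]]
            oa_t[strand] = [_COMPLEMENT[a] for a in oa_t[strand]]
        return pd.DataFrame(
            {"variant_id": variant_id, "chr": chrom, "pos": pos,
             "effect_allele": ea_t, "other_allele": oa_t,
             "eaf": eaf_t, "beta": beta_t, "se": se}
        )

    exposure = table(bx_hat, se_x, flipped=False)
    outcome = table(by_hat, se_y, flipped=True)
    mediator = table(bm_hat, se_m, flipped=True) if med else None

    truth = {
        "theta": sc.theta,
        "theta_total": theta_total,
        "theta_m": med.theta_m if med else None,
        "exposure_to_mediator": med.exposure_to_mediator if med else None,
        "seed": sc.seed,
        # per-SNP ground truth, indexed by variant so it can be aligned to
        # whatever subset survives harmonization
        "snps": pd.DataFrame(
            {"alpha": alpha, "valid": ~invalid, "beta_x_true": beta_x,
             "beta_m_true": beta_m, "palindromic": pal, "swapped": swap},
            index=pd.Index(variant_id, name="variant_id"),
        ),
    }
    return exposure, outcome, mediator, truth


@dataclass(frozen=True)
class CohortScenario:
    """Generative conditions for an ascertained carrier cohort.

    Defaults emulate a clinical-genetics recruitment: 1-3 women per family,
    population ANM around 50 +/- 4 years, interview between ages 25 and 70,
    RRSO and background-mortality hazards of realistic magnitude, and
    affected-enriched sampling controlled by ``oversample_affected``.
    """

    n_families: int = 1000
    members_per_family: tuple = (1, 2, 3)
    gs_true_effect: float = 1.5  # years of trait per SD of score
    trait: str = "anm"  # which trait the score drives: anm | aam
    trait_mean: float = 50.0
    trait_sd: float = 4.0
    aam_mean: float = 13.0
    aam_sd: float = 1.5
    family_sd: float = 0.0  # shared family random effect on the trait
    rrso_hazard: float = 0.015  # per year from age 30
    death_hazard: float = 0.003  # per year from age 40
    interview_age_range: tuple = (25.0, 70.0)
    admin_censor_age: float = 60.0
    birth_cohort_probs: tuple = (
        ("<1940", 0.1), ("1940-1949", 0.2), ("1950-1959", 0.3), (">=1960", 0.4)
    )
    incidence_table: tuple = (
        (18, 30, 0.003), (30, 40, 0.012), (40, 50, 0.022),
        (50, 60, 0.018), (60, 80, 0.015),
    )
    oversample_affected: float = 2.0
    gene: str = "BRCA2"
    seed: int | None = None

    def __post_init__(self):
        if self.trait_sd <= 0:
            raise ScenarioError("trait_sd must be positive")
        if self.admin_censor_age <= 18:
            raise ScenarioError("admin_censor_age must exceed the minimum adult age")
        if any(r < 0 for _, _, r in self.incidence_table):
            raise ScenarioError("incidence rates must be non-negative")
        if abs(self.gs_true_effect) + abs(self.family_sd) >= self.trait_sd:
            raise ScenarioError("gs_true_effect and family_sd exceed total trait SD")
        if self.oversample_affected < 1:
            raise ScenarioError("oversample_affected must be >= 1")

    def incidence(self) -> IncidenceTable:
        lo, hi, r = zip(*self.incidence_table)
        return IncidenceTable(lo, hi, r)


def _draw_piecewise_exponential(rng, table: IncidenceTable, n):
    """Event ages from age-specific hazards; NaN when no event by table end."""
    lo = np.asarray(table.age_lo, float)
    hi = np.asarray(table.age_hi, float)
    r = np.asarray(table.rate, float)
    cum = np.concatenate([[0.0], np.cumsum(r * (hi - lo))])
    u = rng.exponential(1.0, n)  # target cumulative hazard
    ages = np.full(n, np.nan)
    for k in range(lo.size):
        hit = (u >= cum[k]) & (u < cum[k + 1]) & (r[k] > 0)
        ages[hit] = lo[k] + (u[hit] - cum[k]) / r[k]
    return ages


def gen_carrier_cohort(scenario: CohortScenario, gs_model: GeneticScoreModel) -> pd.DataFrame:
    """Simulate an ascertained carrier cohort with questionnaire fields.

    Per family, members are drawn until ``n_families`` are accepted;
    families containing no affected member are accepted with probability
    ``1 / oversample_affected`` (affected families always), emulating
    testing-based recruitment. Per individual the draw order is: family
    size, dosages, family effect, trait noise, AAM noise, birth cohort,
    interview age, RRSO age, death age, cancer-diagnosis age, acceptance.

    The returned frame carries id, family_id, gene, birth_cohort, the
    questionnaire fields, affected status, AAM, dosage columns
    (``dos_<variant_id>``), and generator-truth columns prefixed
    ``truth_``.
    """
    sc = scenario
    if gs_model.n_snps < 1:
        raise ScenarioError("score model must contain at least one SNP")
    rng = np.random.default_rng(sc.seed)
    p = gs_model.frequencies
    w = gs_model.weights
    mu_score = float(np.sum(2.0 * p * w))
    sd_score = float(np.sqrt(np.sum(2.0 * p * (1.0 - p) * w**2)))
    if sd_score == 0:
        raise ScenarioError("score model has zero theoretical SD")
    resid_sd = np.sqrt(sc.trait_sd**2 - sc.gs_true_effect**2 - sc.family_sd**2)
    aam_resid_sd = (
        np.sqrt(sc.aam_sd**2 - sc.gs_true_effect**2 - sc.family_sd**2)
        if sc.trait == "aam" else sc.aam_sd
    )
    bc_labels, bc_probs = zip(*sc.birth_cohort_probs)
    sizes = np.asarray(sc.members_per_family)
    incidence = sc.incidence()

    rows = []
    fam_accepted = 0
    person = 0
    while fam_accepted < sc.n_families:
        m = int(rng.choice(sizes))
        dos = rng.binomial(2, p, size=(m, p.size)).astype(float)
        u_f = rng.normal(0.0, sc.family_sd) if sc.family_sd > 0 else 0.0
        z = (dos @ w - mu_score) / sd_score
        if sc.trait == "anm":
            anm = sc.trait_mean + sc.gs_true_effect * z + u_f + rng.normal(0, resid_sd, m)
            aam = sc.aam_mean + rng.normal(0, aam_resid_sd, m)
        else:
            aam = sc.aam_mean + sc.gs_true_effect * z + u_f + rng.normal(0, aam_resid_sd, m)
            anm = sc.trait_mean + rng.normal(0, sc.trait_sd, m)
        anm = np.clip(anm, 30.0, None)
        aam = np.clip(aam, 8.0, 20.0)
        bc = rng.choice(bc_labels, size=m, p=bc_probs)
        t_int = rng.uniform(*sc.interview_age_range, m)
        t_rrso = 30.0 + rng.exponential(1.0 / sc.rrso_hazard, m) if sc.rrso_hazard > 0 \
            else np.full(m, np.inf)
        t_death = 40.0 + rng.exponential(1.0 / sc.death_hazard, m) if sc.death_hazard > 0 \
            else np.full(m, np.inf)
        t_dx = _draw_piecewise_exponential(rng, incidence, m)
        t_dx = np.where(np.isnan(t_dx), np.inf, t_dx)

        alive_at_int = t_death > t_int
        t_obs_end = np.minimum(t_int, t_death)
        affected = t_dx < t_obs_end

        any_affected = bool(affected.any())
        accept = any_affected or rng.random() < 1.0 / sc.oversample_affected
        if not accept:
            continue
        fam_accepted += 1
        fid = f"F{fam_accepted:05d}"

        for i in range(m):
            person += 1
            rrso_obs = t_rrso[i] if t_rrso[i] <= t_obs_end[i] else np.nan
            dx_obs = t_dx[i] if affected[i] else np.nan
            meno = anm[i]
            stop_candidates = {"natural_menopause": meno}
            if not np.isnan(rrso_obs):
                stop_candidates["rrso"] = rrso_obs
            first_reason = min(stop_candidates, key=stop_candidates.get)
            first_age = stop_candidates[first_reason]
            if first_age <= t_obs_end[i]:
                periods_stopped = True
                period_past_year = bool(t_obs_end[i] < first_age + 1.0)
                reason = first_reason
                age_lm = first_age - 1.0 if reason == "natural_menopause" else first_age
            else:
                periods_stopped = False
                period_past_year = True
                reason = None
                age_lm = np.nan
            rows.append(
                {
                    "id": f"I{person:06d}",
                    "family_id": fid,
                    "gene": sc.gene,
                    "birth_cohort": bc[i],
                    "period_past_year": period_past_year,
                    "periods_stopped": periods_stopped,
                    "reason": reason,
                    "age_last_menstruation": age_lm,
                    "age_rrso": rrso_obs,
                    "age_cancer_diagnosis": dx_obs,
                    "age_death": t_death[i] if not alive_at_int[i] else np.nan,
                    "age_interview": t_int[i] if alive_at_int[i] else np.nan,
                    "affected": bool(affected[i]),
                    "aam": aam[i],
                    "truth_anm": anm[i],
                    "truth_score_z": z[i],
                    **{f"dos_{v}": dos[i, k] for k, v in enumerate(gs_model.variant_id)},
                }
            )
    return pd.DataFrame(rows)


def cohort_dosage_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Extract the dosage columns as an individuals-by-SNP matrix."""
    cols = [c for c in cohort.columns if c.startswith("dos_")]
    out = cohort[cols].copy()
    out.columns = [c[len("dos_"):] for c in cols]
    return out
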