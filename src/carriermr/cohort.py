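"""Instrument validation in an ascertained carrier cohort.

Three stages, mirroring how family-based clinical-genetics cohorts are
analysed:

1. :func:`derive_menopause_phenotype` turns raw questionnaire fields
   (period in the past year, reason periods stopped, ages at last
   menstruation / RRSO / cancer diagnosis / interview) into a
   right-censored age-at-natural-menopause observation. Censoring is at
   the earliest of RRSO, any cancer diagnosis, death, interview; women
   premenopausal at the administrative cap (default 60 years) are treated
   as menopausal at the cap.
2. :func:`compute_cohort_weights` corrects for ascertainment (affected
   carriers are oversampled in testing-based recruitment) by weighting
   individuals within age strata so the weighted affected fraction equals
   the fraction implied by established age-specific incidence rates.
3. :func:`fit_censored_regression` fits a weighted right-censored normal
   (Tobit-type) linear regression of the observation on the standardized
   genetic score and birth-cohort indicators, with family-clustered
   sandwich standard errors to account for dependence among relatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

DEFAULT_ADMIN_CAP = 60.0

#: birth-cohort bins used for the menopause analysis (reference = earliest)
ANM_BIRTH_COHORTS = ("<1940", "1940-1949", "1950-1959", ">=1960")
#: finer bins for the menarche analysis
AAM_BIRTH_COHORTS = ("<1940", "1940-1949", "1950-1959", "1960-1969", ">=1970")

PREMENOPAUSAL_REASONS = ("medication", "oral_contraceptive", "pregnancy", "breastfeeding")
SURGICAL_REASONS = ("rrso", "hysterectomy")


class CohortError(ValueError):
    pass


class RecordExcluded(Exception):
    """A questionnaire record that cannot be phenotyped; carries the reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass(frozen=True)
class CensoredObservation:
    """A right-censored age-at-natural-menopause observation (years)."""

    value: float
    event: bool  # True: natural menopause observed (or administrative cap)
    censor_age: float
    reason: str

    def __post_init__(self):
        if self.value < 0:
            raise CohortError("negative observation age")
        if self.value > self.censor_age + 1e-9:
            raise CohortError("observation exceeds its censoring bound")


def _as_reasons(reason) -> frozenset:
    if reason is None or (isinstance(reason, float) and np.isnan(reason)):
        return frozenset()
    if isinstance(reason, str):
        return frozenset(r.strip() for r in reason.split("+") if r.strip())
    return frozenset(reason)


def _get(record, key):
    v = record.get(key) if hasattr(record, "get") else getattr(record, key, None)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    return v


def derive_menopause_phenotype(record, admin_cap: float = DEFAULT_ADMIN_CAP) -> CensoredObservation:
    """Derive a censored ANM observation from questionnaire fields.

    ``record`` is a mapping (or namespace) with fields ``period_past_year``,
    ``periods_stopped``, ``reason`` (``natural_menopause``, ``rrso``,
    ``hysterectomy``, ``medication``, ``oral_contraceptive``, ``pregnancy``,
    ``breastfeeding``, ``chemotherapy``, ``radiotherapy``, ``unspecified``;
    multiple reasons joined by ``+``), ``age_last_menstruation``,
    ``age_rrso``, ``age_cancer_diagnosis``, ``age_death``, ``age_interview``.

    Rules applied, in order:

    * natural menopause event only when the reason is natural menopause
      *alone* and the event age precedes RRSO, any cancer diagnosis and
      interview; the event age adds one year to 'age at last menstruation'
      when derived from "no period in the past year";
    * women premenopausal by questionnaire (period in past year, periods
      not stopped, medication/OC before age 40, pregnancy, breastfeeding)
      are censored at the earliest of RRSO / diagnosis / death / interview;
    * anyone premenopausal at ``admin_cap`` is recorded as an
      administrative event at the cap;
    * RRSO/hysterectomy as the reason: premenopausal until, and censored
      at, the age at last period;
    * periods stopped with the needed ages missing, or contradictory ages:
      :class:`RecordExcluded` with a reason.
    """
    reasons = _as_reasons(_get(record, "reason"))
    age_lm = _get(record, "age_last_menstruation")
    age_rrso = _get(record, "age_rrso")
    age_dx = _get(record, "age_cancer_diagnosis")
    age_death = _get(record, "age_death")
    age_int = _get(record, "age_interview")
    period_py = _get(record, "period_past_year")
    stopped = _get(record, "periods_stopped")

    for label, a in (("rrso", age_rrso), ("diagnosis", age_dx),
                     ("death", age_death), ("interview", age_int),
                     ("last_menstruation", age_lm)):
        if a is not None and a < 0:
            raise RecordExcluded(f"negative_age_{label}")

    censor_events = [a for a in (age_rrso, age_dx, age_death, age_int) if a is not None]
    base_censor = min(censor_events) if censor_events else np.inf

    def censored_at(age, why):
        age = min(age, base_censor)
        if age >= admin_cap:
            return CensoredObservation(admin_cap, True, admin_cap, "admin_cap")
        return CensoredObservation(age, False, age, why)

    # natural menopause, reported alone
    if reasons == {"natural_menopause"}:
        age_meno = _get(record, "age_menopause")
        if age_meno is not None:
            event_age = float(age_meno)
        elif age_lm is not None:
            # "no period in the past year": menopause = last menstruation + 1
            event_age = age_lm + 1.0
        else:
            raise RecordExcluded("missing_age_at_menopause")
        if age_int is not None and event_age > age_int:
            raise RecordExcluded("menopause_after_interview")
        earlier = [a for a in (age_rrso, age_dx, age_int) if a is not None]
        if all(event_age < a for a in earlier):
            if event_age >= admin_cap:
                return CensoredObservation(admin_cap, True, admin_cap, "admin_cap")
            return CensoredObservation(event_age, True, event_age, "natural_menopause")
        # reported menopause did not precede RRSO/diagnosis: censor there
        blockers = [a for a in (age_rrso, age_dx) if a is not None and a <= event_age]
        if not blockers:
            raise RecordExcluded("contradictory_menopause_timing")
        return censored_at(min(blockers), "menopause_after_censoring_event")

    # surgical stopping: premenopausal until age at last period
    if reasons & set(SURGICAL_REASONS):
        if age_lm is None:
            raise RecordExcluded("missing_age_at_last_period")
        return censored_at(age_lm, "surgical")

    # premenopausal classifications
    premenopausal = (
        period_py is True
        or stopped is False
        or bool(reasons & {"pregnancy", "breastfeeding"})
    )
    if reasons & {"medication", "oral_contraceptive"}:
        if age_int is None:
            raise RecordExcluded("missing_interview_age_for_medication_rule")
        if age_int < 40.0:
            premenopausal = True
        else:
            # 40+: stopping on medication/OC is not taken as premenopausal;
            # treated like other non-natural stopping, censored at last period
            if age_lm is None:
                raise RecordExcluded("missing_age_at_last_period")
            return censored_at(age_lm, "medication_40plus")
    if premenopausal:
        if not censor_events:
            raise RecordExcluded("no_censoring_age_available")
        return censored_at(base_censor, _censor_label(base_censor, age_rrso, age_dx,
                                                      age_death, age_int))

    # periods stopped for another (or unspecified) reason
    if stopped is True or reasons:
        if age_lm is None:
            raise RecordExcluded("periods_stopped_missing_ages")
        return censored_at(age_lm, "non_natural_stopping")

    raise RecordExcluded("uninterpretable_record")


def _censor_label(age, age_rrso, age_dx, age_death, age_int):
    for label, a in (("rrso", age_rrso), ("cancer_diagnosis", age_dx),
                     ("death", age_death), ("interview", age_int)):
        if a is not None and a == age:
            return label
    return "censored"


def derive_cohort_phenotypes(cohort: pd.DataFrame, admin_cap: float = DEFAULT_ADMIN_CAP):
    """Vector version of :func:`derive_menopause_phenotype` over a cohort table.

    Returns (observations DataFrame indexed like the retained rows with
    columns ``value, event, censor_age, reason``, exclusion-log DataFrame
    with columns ``id, reason``).
    """
    rows, excl = [], []
    for idx, rec in cohort.iterrows():
        try:
            obs = derive_menopause_phenotype(rec, admin_cap=admin_cap)
        except RecordExcluded as e:
            excl.append({"id": rec.get("id", idx), "reason": e.reason})
            continue
        rows.append(
            {"index": idx, "value": obs.value, "event": obs.event,
             "censor_age": obs.censor_age, "reason": obs.reason}
        )
    obs_df = pd.DataFrame(rows).set_index("index") if rows else pd.DataFrame(
        columns=["value", "event", "censor_age", "reason"])
    return obs_df, pd.DataFrame(excl, columns=["id", "reason"])


@dataclass(frozen=True)
class IncidenceTable:
    """Age-specific annual disease incidence (contiguous intervals)."""

    age_lo: tuple
    age_hi: tuple
    rate: tuple

    def __post_init__(self):
        lo = np.asarray(self.age_lo, float)
        hi = np.asarray(self.age_hi, float)
        r = np.asarray(self.rate, float)
        if np.any(r < 0):
            raise CohortError("negative incidence rate")
        if np.any(hi <= lo):
            raise CohortError("empty age interval")
        if np.any(lo[1:] != hi[:-1]):
            raise CohortError("age intervals must be contiguous and non-overlapping")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "IncidenceTable":
        return cls(tuple(df["age_lo"]), tuple(df["age_hi"]), tuple(df["rate"]))

    @classmethod
    def read(cls, path) -> "IncidenceTable":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age_lo": self.age_lo, "age_hi": self.age_hi, "rate": self.rate})

    def cumulative_hazard(self, age) -> np.ndarray:
        """Integrated incidence from the table's start to ``age``."""
        age = np.atleast_1d(np.asarray(age, float))
        lo = np.asarray(self.age_lo, float)
        hi = np.asarray(self.age_hi, float)
        r = np.asarray(self.rate, float)
        exposure = np.clip(age[:, None], lo, hi) - lo
        out = (exposure * r).sum(axis=1)
        return out if out.size > 1 else out

    def prob_affected_by(self, age):
        """1 - exp(-cumulative hazard): probability of disease by ``age``."""
        return 1.0 - np.exp(-self.cumulative_hazard(age))


@dataclass
class CohortWeights:
    """Per-individual sampling weights with per-stratum diagnostics."""

    weights: pd.Series
    diagnostics: pd.DataFrame

    def __post_init__(self):
        w = self.weights.to_numpy(float)
        if np.any(~np.isfinite(w)) or np.any(w <= 0):
            raise CohortError("weights must be positive and finite")


def compute_cohort_weights(
    ages, affected, incidence: IncidenceTable, age_strata
) -> CohortWeights:
    """Weighted-cohort ascertainment correction.

    Individuals are assigned to age strata (``age_strata`` = breakpoint
    sequence) by their age at event/censoring. Within stratum *s* with
    ``N_s`` members of which ``n_aff`` are affected, and incidence-implied
    affected probability ``p_s`` (cumulative incidence at the stratum
    midpoint), affected individuals receive weight ``p_s N_s / n_aff`` and
    unaffected ``(1 - p_s) N_s / (N_s - n_aff)``, making the weighted
    affected fraction equal ``p_s`` exactly. Strata with zero affected (or
    zero unaffected) members while ``p_s`` implies some are merged with the
    neighbouring stratum, with a warning.
    """
    ages = pd.Series(np.asarray(ages, float))
    affected = pd.Series(np.asarray(affected, bool))
    edges = np.asarray(sorted(age_strata), float)
    if edges.size < 2:
        raise CohortError("need at least two stratum breakpoints")
    idx = np.clip(np.searchsorted(edges, ages, side="right") - 1, 0, edges.size - 2)

    # merge degenerate strata (no affected with p>0, or no unaffected) leftward
    strata = []
    members = {s: np.flatnonzero(idx == s) for s in range(edges.size - 1)}
    pending: list[int] = []
    for s in range(edges.size - 1):
        pending.append(s)
        rows = np.concatenate([members[t] for t in pending])
        if rows.size == 0:
            continue
        aff = affected.iloc[rows]
        if aff.any() and (~aff).any():
            strata.append(pending)
            pending = []
        # else keep accumulating into the next stratum
    def occupied(group):
        return sum(members[t].size for t in group) > 0

    if pending:
        if strata:
            if occupied(pending):
                warnings.warn("merged trailing age strata lacking affected/unaffected members")
            strata[-1].extend(pending)
        else:
            raise CohortError("no stratum contains both affected and unaffected individuals")
    if any(len(group) > 1 and all(occupied([t]) for t in group) for group in strata):
        warnings.warn("merged age strata lacking affected or unaffected members")

    w = np.empty(len(ages))
    diag = []
    for group in strata:
        rows = np.concatenate([members[t] for t in group])
        lo, hi = edges[group[0]], edges[group[-1] + 1]
        mid = 0.5 * (lo + hi)
        p_s = float(np.atleast_1d(incidence.prob_affected_by(mid))[0])
        aff = affected.iloc[rows].to_numpy()
        n, n_aff = rows.size, int(aff.sum())
        w_aff = p_s * n / n_aff
        w_un = (1.0 - p_s) * n / (n - n_aff)
        w[rows[aff]] = w_aff
        w[rows[~aff]] = w_un
        weighted_frac = w_aff * n_aff / (w_aff * n_aff + w_un * (n - n_aff))
        diag.append(
            {"age_lo": lo, "age_hi": hi, "n": n, "n_affected": n_aff,
             "p_implied": p_s, "observed_fraction": n_aff / n,
             "weighted_fraction": weighted_frac,
             "weight_affected": w_aff, "weight_unaffected": w_un}
        )
    return CohortWeights(weights=pd.Series(w, index=ages.index),
                         diagnostics=pd.DataFrame(diag))


@dataclass
class RegressionFit:
    """Censored weighted linear-regression fit with cluster-robust SEs."""

    names: list
    coef: np.ndarray
    se: np.ndarray
    naive_se: np.ndarray
    sigma: float
    n_events: int
    n_censored: int
    n_clusters: int
    converged: bool
    n_iter: int
    grad_norm: float
    nll_path: list = field(default_factory=list)

    def coefficient(self, name: str) -> float:
        return float(self.coef[self.names.index(name)])

    def coefficient_se(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def summary(self) -> pd.DataFrame:
        z = self.coef / self.se
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "ci_low": self.coef - 1.96 * self.se,
                "ci_high": self.coef + 1.96 * self.se,
                "p_value": 2.0 * stats.norm.sf(np.abs(z)),
            },
            index=self.names,
        )


def _tobit_nll_grad(params, y, event, X, w):
    """Weighted right-censored normal NLL with per-observation scores.

    Event rows contribute the normal log-density, censored rows the upper
    tail log-probability, each raised to its sampling weight. Returns
    (nll, gradient, per-observation score matrix) over (coef, log sigma).
    """
    p = X.shape[1]
    b, log_s = params[:p], params[p]
    s = np.exp(log_s)
    r = (y - X @ b) / s

    nll_i = np.empty_like(y)
    d_r = np.empty_like(y)  # dNLL_i / dr
    d_ls = np.empty_like(y)  # dNLL_i / dlog sigma

    ev = event
    nll_i[ev] = 0.5 * r[ev] ** 2 + 0.5 * np.log(2 * np.pi) + log_s
    d_r[ev] = r[ev]
    d_ls[ev] = 1.0 - r[ev] ** 2

    ce = ~event
    log_sf = stats.norm.logsf(r[ce])
    nll_i[ce] = -log_sf
    lam = np.exp(stats.norm.logpdf(r[ce]) - log_sf)  # inverse Mills ratio
    d_r[ce] = lam
    d_ls[ce] = -r[ce] * lam

    scores = np.empty((y.size, p + 1))
    scores[:, :p] = (-d_r / s)[:, None] * X
    scores[:, p] = d_ls
    scores *= w[:, None]
    nll = float(np.sum(w * nll_i))
    return nll, scores.sum(axis=0), scores


def fit_censored_regression(
    y,
    event,
    X: pd.DataFrame,
    weights=None,
    clusters=None,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> RegressionFit:
    """Weighted right-censored normal (Tobit-type) regression, maximum
    likelihood over (coefficients, log residual SD), with a cluster-level
    sandwich variance (score contributions summed within family and a
    G/(G-1) small-sample correction).

    ``X`` is the design matrix *without* intercept column handling — pass
    an explicit ``intercept`` column. ``event`` True rows are observed
    natural-menopause ages; False rows are right-censored at ``y``.
    """
    y = np.asarray(y, float)
    event = np.asarray(event, bool)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.shape(X)[1])]
    X = np.asarray(X, float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    clusters = np.arange(n) if clusters is None else np.asarray(clusters)
    n_events = int(event.sum())
    if n_events < 2:
        raise CohortError("censored regression requires at least 2 events")
    if np.linalg.matrix_rank(X) < p:
        raise CohortError("design matrix is rank deficient")

    # start from weighted OLS on the uncensored rows
    sw = np.sqrt(w[event])
    b0, *_ = np.linalg.lstsq(X[event] * sw[:, None], y[event] * sw, rcond=None)
    resid = y[event] - X[event] @ b0
    s0 = max(np.sqrt(np.average(resid**2, weights=w[event])), 1e-3)
    x0 = np.concatenate([b0, [np.log(s0)]])

    nll_path: list[float] = []

    def fun(params):
        nll, grad, _ = _tobit_nll_grad(params, y, event, X, w)
        return nll, grad

    def cb(params):
        nll_path.append(fun(params)[0])

    res = optimize.minimize(
        fun, x0, jac=True, method="BFGS", callback=cb,
        options={"gtol": tol * max(1.0, abs(fun(x0)[0])), "maxiter": max_iter},
    )
    gnorm = float(np.max(np.abs(res.jac)))
    # BFGS may stop on precision loss at a stationary point; accept if the
    # scaled gradient is tiny
    converged = bool(res.success or gnorm < 1e-4 * max(1.0, abs(res.fun)))
    if not converged:
        raise CohortError(
            f"censored regression did not converge after {res.nit} iterations "
            f"(gradient norm {gnorm:.3e})"
        )

    params = res.x
    _, _, scores = _tobit_nll_grad(params, y, event, X, w)

    # numerical Hessian via central differences of the analytic gradient
    k = p + 1
    H = np.empty((k, k))
    eps = 1e-5 * np.maximum(np.abs(params), 1.0)
    for j in range(k):
        up, dn = params.copy(), params.copy()
        up[j] += eps[j]
        dn[j] -= eps[j]
        H[:, j] = (fun(up)[1] - fun(dn)[1]) / (2 * eps[j])
    H = 0.5 * (H + H.T)
    H_inv = np.linalg.inv(H)

    cl = pd.Series(clusters)
    score_df = pd.DataFrame(scores)
    cluster_scores = score_df.groupby(cl.values).sum().to_numpy()
    G = cluster_scores.shape[0]
    meat = cluster_scores.T @ cluster_scores * (G / max(G - 1, 1))
    V = H_inv @ meat @ H_inv

    return RegressionFit(
        names=names,
        coef=params[:p],
        se=np.sqrt(np.diag(V)[:p]),
        naive_se=np.sqrt(np.diag(H_inv)[:p]),
        sigma=float(np.exp(params[p])),
        n_events=n_events,
        n_censored=int((~event).sum()),
        n_clusters=int(G),
        converged=converged,
        n_iter=int(res.nit),
        grad_norm=gnorm,
        nll_path=nll_path,
    )


def birth_cohort_design(categories, levels) -> pd.DataFrame:
    """Indicator columns for birth-cohort bins, reference = earliest level."""
    cats = pd.Series(categories).astype(str)
    cols = {}
    for level in levels[1:]:
        cols[f"cohort_{level}"] = (cats == level).astype(float).to_numpy()
    return pd.DataFrame(cols, index=cats.index)


def validate_instruments(
    cohort: pd.DataFrame,
    scores: pd.Series,
    incidence: IncidenceTable,
    trait: str = "anm",
    admin_cap: float = DEFAULT_ADMIN_CAP,
    age_strata=(18, 30, 40, 50, 61),
    use_weights: bool = True,
):
    """End-to-end instrument validation: phenotype derivation, weighted-cohort
    correction, censored regression of the trait on the standardized score
    adjusting for birth cohort, clustered by family.

    For ``trait="aam"`` age at menarche is fully observed, so the same
    likelihood reduces to weighted linear regression (no censored rows).
    Returns (RegressionFit, exclusion log).
    """
    if trait == "anm":
        obs, excl = derive_cohort_phenotypes(cohort, admin_cap=admin_cap)
        kept = cohort.loc[obs.index]
        y = obs["value"].to_numpy(float)
        event = obs["event"].to_numpy(bool)
        levels = ANM_BIRTH_COHORTS
        weight_age = obs["value"].to_numpy(float)
    elif trait == "aam":
        kept = cohort.loc[cohort["aam"].notna()]
        excl = pd.DataFrame(
            {"id": cohort.loc[cohort["aam"].isna(), "id"], "reason": "missing_aam"}
        )
        y = kept["aam"].to_numpy(float)
        event = np.ones(len(kept), dtype=bool)
        levels = AAM_BIRTH_COHORTS
        weight_age = kept["age_interview"].to_numpy(float)
    else:
        raise CohortError(f"unknown trait '{trait}'")

    if use_weights:
        cw = compute_cohort_weights(
            weight_age, kept["affected"].to_numpy(bool), incidence, age_strata
        )
        w = cw.weights.to_numpy(float)
    else:
        w = np.ones(len(kept))

    z = scores.loc[kept.index].to_numpy(float)
    z = (z - z.mean()) / z.std(ddof=0)
    design = birth_cohort_design(kept["birth_cohort"], levels)
    X = pd.DataFrame({"intercept": np.ones(len(kept)), "score": z}, index=kept.index)
    X = pd.concat([X, design.set_index(kept.index)], axis=1)
    X = X.loc[:, (X != 0).any(axis=0)]  # drop empty cohort bins
    fit = fit_censored_regression(
        y, event, X, weights=w, clusters=kept["family_id"].to_numpy()
    )
    return fit, excl
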