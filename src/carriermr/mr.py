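"""Univariable two-sample Mendelian randomization estimators.

Given per-SNP exposure effects ``bx_j`` (with SE ``sx_j``) and outcome
effects ``by_j`` on the log hazard/odds scale (with SE ``sy_j``), the suite
implements the estimators reported in carrier MR analyses:

* IVW — weighted regression of ``by`` on ``bx`` through the origin with
  weights ``1/sy^2``; fixed-effect or multiplicative random-effects
  (SE inflated by ``max(1, sqrt(Q/df))``), optionally penalized
  (heterogeneity-downweighted) and/or robust (Tukey biweight).
* MR-Egger — same regression with an intercept after orienting all
  exposure betas positive; the intercept estimates average directional
  pleiotropy, the slope the pleiotropy-adjusted causal effect under InSIDE.
* Simple / weighted / penalized-weighted median of the per-SNP Wald
  ratios, with parametric-bootstrap standard errors.
* Radial outlier detection via per-SNP contributions to Cochran's Q.
* Cochran's Q / I-squared heterogeneity diagnostics.

Estimates are per unit of exposure (per year of the reproductive trait)
and exponentiate to hazard/odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sumstats import HarmonizedInstrumentSet

PENALTY_CONSTANT = 20.0  # weight multiplier min(1, 20 * p_j)
TUKEY_C = 4.685


class MRError(ValueError):
    pass


def _normal_ci_p(estimate: float, se: float, level: float = 0.95):
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = estimate - z * se, estimate + z * se
    p = 2.0 * stats.norm.sf(abs(estimate) / se) if se > 0 else (1.0 if estimate == 0 else 0.0)
    return lo, hi, p


@dataclass
class MREstimate:
    """A causal-effect estimate on the log HR/OR scale with uncertainty."""

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    penalized: bool = False
    robust: bool = False
    scale: str = "log"
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_point(cls, method, estimate, se, n_snps, **kw):
        lo, hi, p = _normal_ci_p(estimate, se)
        return cls(method, float(estimate), float(se), lo, hi, p, int(n_snps), **kw)

    @property
    def hr(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def hr_ci(self) -> tuple:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    def as_dict(self) -> dict:
        d = {
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "hr": self.hr,
            "hr_ci_low": self.hr_ci[0],
            "hr_ci_high": self.hr_ci[1],
            "n_snps": self.n_snps,
        }
        if self.intercept is not None:
            d.update(
                intercept=self.intercept,
                intercept_se=self.intercept_se,
                intercept_p=self.intercept_p,
            )
        return d


@dataclass
class HeterogeneityStats:
    """Cochran's Q heterogeneity across per-SNP causal estimates."""

    Q: float
    df: int
    p_value: float
    i2: float
    i2_ci_low: float
    i2_ci_high: float
    contributions: np.ndarray

    def as_dict(self) -> dict:
        return {
            "Q": self.Q,
            "df": self.df,
            "p_value": self.p_value,
            "i2": self.i2,
            "i2_ci_low": self.i2_ci_low,
            "i2_ci_high": self.i2_ci_high,
        }


def _require(iset: HarmonizedInstrumentSet, n_min: int, what: str):
    if iset.n_snps < n_min:
        raise MRError(f"{what} requires >= {n_min} SNPs, got {iset.n_snps}")


def ratio_estimates(iset: HarmonizedInstrumentSet):
    """Per-SNP Wald ratios ``by/bx`` with first-order SEs ``sy/|bx|``.

    SNPs with exactly zero exposure beta are excluded (with their count
    reported via the second return value). Orientation-invariant.
    """
    if iset.n_snps == 0:
        raise MRError("empty instrument set")
    bx, by, sy = iset.beta_exposure, iset.beta_outcome, iset.se_outcome
    nonzero = bx != 0
    ratios = by[nonzero] / bx[nonzero]
    ses = sy[nonzero] / np.abs(bx[nonzero])
    return ratios, ses, int((~nonzero).sum())


def heterogeneity(iset: HarmonizedInstrumentSet, theta: float) -> HeterogeneityStats:
    """Cochran's Q at a given causal estimate, with test-based I^2 CI."""
    _require(iset, 2, "heterogeneity")
    bx, by, sy = iset.beta_exposure, iset.beta_outcome, iset.se_outcome
    w = 1.0 / sy**2
    contrib = w * (by - theta * bx) ** 2
    Q = float(contrib.sum())
    df = iset.n_snps - 1
    p = float(stats.chi2.sf(Q, df))
    i2 = max(0.0, (Q - df) / Q) if Q > 0 else 0.0
    lo, hi = _i2_ci(Q, df)
    return HeterogeneityStats(Q, df, p, i2, lo, hi, contrib)


def _i2_ci(Q: float, df: int, level: float = 0.95):
    """Test-based CI for I^2 via the Higgins-Thompson ln(H) method."""
    if df < 2 or Q <= 0:
        return 0.0, 0.0
    ln_h = 0.5 * max(0.0, np.log(Q) - np.log(df))
    if Q > df:
        se_ln_h = 0.5 * (np.log(Q) - np.log(df)) / (np.sqrt(2 * Q) - np.sqrt(2 * df - 1))
    else:
        se_ln_h = np.sqrt(1.0 / (2 * (df - 1)) * (1.0 - 1.0 / (3 * (df - 1) ** 2)))
    z = stats.norm.ppf(0.5 + level / 2.0)
    h_lo = np.exp(ln_h - z * se_ln_h)
    h_hi = np.exp(ln_h + z * se_ln_h)
    to_i2 = lambda h: max(0.0, (h**2 - 1.0) / h**2)
    return to_i2(h_lo), to_i2(h_hi)


def _penalize_weights(bx, by, w, theta):
    """Heterogeneity penalty: multiply weights by min(1, 20 p_j)."""
    q_j = w * (by - theta * bx) ** 2
    p_j = stats.chi2.sf(q_j, 1)
    return w * np.minimum(1.0, PENALTY_CONSTANT * p_j)


def _tukey_weights(resid_scaled):
    u = resid_scaled / TUKEY_C
    w = (1.0 - u**2) ** 2
    w[np.abs(u) >= 1.0] = 0.0
    return w


def _robust_irls(X, y, w, max_iter=100, tol=1e-8):
    """Iteratively-reweighted WLS with Tukey biweight loss on the
    inverse-variance-standardized residuals. Returns (coef, final_weights)."""
    sw = np.sqrt(w)
    Xs, ys = X * sw[:, None], y * sw
    coef, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    for _ in range(max_iter):
        resid = ys - Xs @ coef  # standardized residuals
        scale = np.median(np.abs(resid - np.median(resid))) / 0.6745
        scale = max(scale, 1e-12)
        rw = _tukey_weights(resid / scale)
        if rw.sum() == 0:
            raise MRError("robust fit degenerate: all observations downweighted")
        wt = w * rw
        swt = np.sqrt(wt)
        new_coef, *_ = np.linalg.lstsq(X * swt[:, None], y * swt, rcond=None)
        if np.max(np.abs(new_coef - coef)) < tol:
            coef = new_coef
            break
        coef = new_coef
    return coef, w * rw


def _wls(X, y, w):
    """Weighted least squares; returns (coef, cov_unit) where the true
    covariance is ``sigma^2 * cov_unit`` with sigma the residual scale."""
    sw = np.sqrt(w)
    Xs, ys = X * sw[:, None], y * sw
    xtx = Xs.T @ Xs
    coef = np.linalg.solve(xtx, Xs.T @ ys)
    return coef, np.linalg.inv(xtx)


def ivw(
    iset: HarmonizedInstrumentSet,
    weight_mode: str = "multiplicative_random",
    penalized: bool = False,
    robust: bool = False,
) -> tuple[MREstimate, HeterogeneityStats]:
    """Inverse-variance-weighted estimate: regression of ``by`` on ``bx``
    through the origin with weights ``1/sy^2``.

    ``weight_mode="fixed"`` uses the closed-form fixed-effect SE;
    ``"multiplicative_random"`` (default) inflates the SE by
    ``max(1, sqrt(Q/df))``. ``penalized`` downweights heterogeneous SNPs by
    ``min(1, 20 p_j)``; ``robust`` replaces least squares by a Tukey
    biweight M-estimator.
    """
    _require(iset, 2, "IVW")
    if weight_mode not in ("fixed", "multiplicative_random"):
        raise MRError(f"unknown weight_mode '{weight_mode}'")
    bx, by, sy = iset.beta_exposure, iset.beta_outcome, iset.se_outcome
    w = 1.0 / sy**2
    X = bx[:, None]

    theta0 = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    if penalized:
        w = _penalize_weights(bx, by, w, theta0)
        if w.sum() == 0:
            raise MRError("all weights zero after penalization")
    if robust:
        coef, w_eff = _robust_irls(X, by, w)
        theta = float(coef[0])
    else:
        coef, _ = _wls(X, by, w)
        theta = float(coef[0])
        w_eff = w

    var_fixed = 1.0 / np.sum(w_eff * bx**2)
    het = heterogeneity(iset, theta)
    if weight_mode == "multiplicative_random" and het.df > 0:
        infl = max(1.0, np.sqrt(het.Q / het.df))
    else:
        infl = 1.0
    se = float(np.sqrt(var_fixed) * infl)
    label = "IVW"
    if penalized:
        label = "Penalized " + label
    if robust:
        label = label.replace("IVW", "robust IVW") if penalized else "Robust IVW"
    est = MREstimate.from_point(
        label, theta, se, iset.n_snps, penalized=penalized, robust=robust,
        extra={"weight_mode": weight_mode},
    )
    return est, het


def egger(
    iset: HarmonizedInstrumentSet,
    weight_mode: str = "multiplicative_random",
    penalized: bool = False,
    robust: bool = False,
) -> MREstimate:
    """MR-Egger: weighted regression of ``by`` on ``bx`` with intercept.

    Exposure betas are oriented positive (sign-flipping ``by`` in step)
    before fitting, which the intercept's interpretation as average
    directional pleiotropy requires. Slope = pleiotropy-adjusted causal
    effect under InSIDE; intercept != 0 indicates directional pleiotropy.
    """
    _require(iset, 3, "MR-Egger")
    bx = iset.beta_exposure.copy()
    by = iset.beta_outcome.copy()
    sy = iset.se_outcome
    flip = bx < 0
    bx[flip] *= -1.0
    by[flip] *= -1.0
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])

    if penalized:
        coef0, _ = _wls(X, by, w)
        q_j = w * (by - X @ coef0) ** 2
        p_j = stats.chi2.sf(q_j, 1)
        w = w * np.minimum(1.0, PENALTY_CONSTANT * p_j)
    if robust:
        coef, w_eff = _robust_irls(X, by, w)
    else:
        coef, _ = _wls(X, by, w)
        w_eff = w

    cov_unit = np.linalg.inv((X * w_eff[:, None]).T @ X)
    resid = by - X @ coef
    df = iset.n_snps - 2
    q_e = float(np.sum(w_eff * resid**2))
    if weight_mode == "multiplicative_random" and df > 0:
        sigma2 = max(1.0, q_e / df)
    else:
        sigma2 = 1.0
    ses = np.sqrt(sigma2 * np.diag(cov_unit))
    intercept, slope = float(coef[0]), float(coef[1])
    i_lo, i_hi, i_p = _normal_ci_p(intercept, float(ses[0]))
    label = "MR-Egger"
    if robust:
        label = "Robust " + label
    if penalized:
        label = "Penalized " + label.lower().replace("mr-egger", "MR-Egger") \
            if robust else "Penalized " + label
    est = MREstimate.from_point(
        label, slope, float(ses[1]), iset.n_snps,
        penalized=penalized, robust=robust,
    )
    est.intercept, est.intercept_se, est.intercept_p = intercept, float(ses[0]), i_p
    est.extra["intercept_ci"] = (i_lo, i_hi)
    return est


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """50th weighted percentile with linear interpolation across the
    standardized cumulative weight function."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(0.5, cum, v))


def median_estimators(
    iset: HarmonizedInstrumentSet,
    variant: str = "weighted",
    n_boot: int = 1000,
    seed=None,
) -> MREstimate:
    """Simple / weighted / penalized-weighted median of per-SNP Wald ratios.

    Weighted variants weight by inverse ratio variance; the penalized
    variant multiplies weights by ``min(1, 20 p_j)`` from per-SNP Q
    contributions at the weighted-median estimate. SEs come from a seeded
    parametric bootstrap resampling ``bx`` and ``by`` at their reported SEs.
    """
    _require(iset, 3, "median estimator")
    if variant not in ("simple", "weighted", "penalized_weighted"):
        raise MRError(f"unknown median variant '{variant}'")
    if n_boot < 100:
        import warnings

        warnings.warn(f"n_boot={n_boot} < 100 gives unstable median SEs")
    bx, by = iset.beta_exposure, iset.beta_outcome
    sx, sy = iset.se_exposure, iset.se_outcome

    def point(bx_, by_):
        ratios = by_ / bx_
        if variant == "simple":
            w = np.ones_like(ratios)
        else:
            w = (bx_ / sy) ** 2  # 1 / SE(ratio)^2, first order
            if variant == "penalized_weighted":
                theta_w = _weighted_median(ratios, w)
                q_j = (1.0 / sy**2) * (by_ - theta_w * bx_) ** 2
                p_j = stats.chi2.sf(q_j, 1)
                w = w * np.minimum(1.0, PENALTY_CONSTANT * p_j)
        return _weighted_median(ratios, w)

    theta = point(bx, by)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + sx * rng.standard_normal(bx.shape)
        by_b = by + sy * rng.standard_normal(by.shape)
        bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
        boots[b] = point(bx_b, by_b)
    se = float(boots.std(ddof=1))
    labels = {
        "simple": "Simple median",
        "weighted": "Weighted median",
        "penalized_weighted": "Penalized weighted median",
    }
    return MREstimate.from_point(
        labels[variant], theta, se, iset.n_snps,
        penalized=(variant == "penalized_weighted"),
        extra={"n_boot": n_boot},
    )


def radial_outliers(
    iset: HarmonizedInstrumentSet,
    alpha_level: float = 0.05,
    iterate: bool = True,
    max_rounds: int = 20,
):
    """Radial-regression outlier detection.

    Fits the radial IVW (``by/sy`` on ``bx/sy`` through the origin, whose
    slope equals the IVW estimate), compares each SNP's Q contribution to a
    chi-square(1) reference, and removes SNPs with ``p_j < alpha_level``;
    with ``iterate`` the procedure repeats on the trimmed set until no new
    outliers emerge. Returns ``(outlier variant IDs, trimmed set)``.
    """
    _require(iset, 3, "radial outlier detection")
    current = iset.subset(np.ones(iset.n_snps, dtype=bool))
    outliers: list[str] = []
    for _ in range(max_rounds):
        bx, by, sy = current.beta_exposure, current.beta_outcome, current.se_outcome
        w = 1.0 / sy**2
        theta = float(np.sum(w * bx * by) / np.sum(w * bx**2))
        q_j = w * (by - theta * bx) ** 2
        p_j = stats.chi2.sf(q_j, 1)
        flag = p_j < alpha_level
        if flag.all():
            raise MRError("all SNPs flagged as radial outliers")
        if not flag.any():
            break
        outliers.extend(current.data.loc[flag, "variant_id"].tolist())
        current = current.subset(~flag)
        if not iterate:
            break
    trimmed = iset.drop_variants(outliers, "radial_outlier") if outliers else current
    return outliers, trimmed


def compare_estimates(a: MREstimate, b: MREstimate):
    """Two-sided z test for a difference between two independent estimates."""
    if a.scale != b.scale:
        raise MRError(f"estimates on different scales: '{a.scale}' vs '{b.scale}'")
    z = (a.estimate - b.estimate) / np.sqrt(a.se**2 + b.se**2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
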