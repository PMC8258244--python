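"""Univariable and multivariable two-sample MR estimators.

Notation: for SNP j, gamma_j is the SNP-exposure effect with SE sigma_xj,
Gamma_j the SNP-outcome effect (log-OR) with SE sigma_yj, and theta the
causal effect of the exposure on the outcome (log-OR per unit exposure).

Implemented methods:

* Wald ratios          theta_j = Gamma_j / gamma_j (delta-method SE)
* IVW                  weighted regression of Gamma on gamma through the
                       origin, weights 1/sigma_yj^2, multiplicative
                       random-effect SE scaling sqrt(Q/(J-1)) floored at 1
* Maximum likelihood   joint normal model for (gamma_hat, Gamma_hat) with
                       nuisance per-SNP true effects profiled out
* Weighted median      inverse-variance-weighted 50th percentile of ordered
                       ratio estimates; parametric-bootstrap SE
* MR-Egger             weighted regression with intercept (average
                       directional pleiotropy); Student-t inference, J-2 df
* MVMR                 joint weighted regression of Gamma on several
                       exposures' SNP effects, no intercept

All estimators consume a :class:`~summr.harmonize.HarmonizedInstrumentSet`
and only see its active (non-excluded) SNPs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import MethodError
from .harmonize import HarmonizedInstrumentSet

log = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)  # 1.959964...


def significance_label(pvalue: float, suggestive: float = 0.05,
                       significant: float = 0.01) -> str:
    """Annotation stars: '**' below the corrected threshold, '*' below the
    suggestive threshold, '' otherwise."""
    if pvalue < significant:
        return "**"
    if pvalue < suggestive:
        return "*"
    return ""


@dataclass(frozen=True)
class RatioEstimate:
    """Per-variant Wald ratio and its delta-method SE."""

    rsid: str
    theta: float
    se: float


@dataclass(frozen=True)
class MrResult:
    """One causal estimate: log-OR scale internally, OR scale for display."""

    method: str
    n_snp: int
    theta: float
    se: float
    pvalue: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None
    q_statistic: float | None = None
    df: int | None = None

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.theta)

    @property
    def or_ci(self) -> tuple[float, float]:
        half = Z95 * self.se
        return (math.exp(self.theta - half), math.exp(self.theta + half))

    @property
    def ci(self) -> tuple[float, float]:
        half = Z95 * self.se
        return (self.theta - half, self.theta + half)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lo, hi = self.or_ci
        return (f"{self.method}: n={self.n_snp} OR={self.odds_ratio:.2f} "
                f"({lo:.2f}-{hi:.2f}) p={self.pvalue:.2g}")


@dataclass(frozen=True)
class MvmrResult:
    """Multivariable MR: one coefficient per exposure."""

    exposures: tuple[str, ...]
    theta: tuple[float, ...]
    se: tuple[float, ...]
    pvalue: tuple[float, ...]
    n_snp: int
    n_dropped: int = 0

    def result_for(self, label: str) -> MrResult:
        i = self.exposures.index(label)
        return MrResult(method=f"MVMR ({label})", n_snp=self.n_snp,
                        theta=self.theta[i], se=self.se[i],
                        pvalue=self.pvalue[i])


def _normal_p(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


def wald_ratios(hset: HarmonizedInstrumentSet,
                second_order: bool = False) -> list[RatioEstimate]:
    """Per-variant causal estimates theta_j = Gamma_j / gamma_j.

    First-order SE sigma_yj/|gamma_j| by default; ``second_order=True``
    adds the exposure-uncertainty term Gamma^2 sigma_x^2 / gamma^4.
    SNPs with gamma_j = 0 are rejected (logged) rather than returned.
    """
    out: list[RatioEstimate] = []
    for row in hset.active.itertuples(index=False):
        if row.gamma == 0:
            log.warning("wald_ratios: %s rejected (zero exposure effect)",
                        row.rsid)
            continue
        var = row.sigma_y ** 2 / row.gamma ** 2
        if second_order:
            var += row.Gamma ** 2 * row.sigma_x ** 2 / row.gamma ** 4
        out.append(RatioEstimate(row.rsid, row.Gamma / row.gamma,
                                 math.sqrt(var)))
    return out


def ivw(hset: HarmonizedInstrumentSet, random_effects: bool = True) -> MrResult:
    """Inverse-variance-weighted estimate: weighted regression of Gamma on
    gamma through the origin with weights 1/sigma_y^2.

    The multiplicative random-effect model scales the fixed-effect SE by
    sqrt(Q/(J-1)) floored at 1, so over-dispersion widens the CI but
    under-dispersion never narrows it.
    """
    g, _, G, sy = hset.arrays()
    J = len(g)
    if J < 2:
        raise MethodError(f"IVW needs >= 2 SNPs, got {J} "
                          "(a single SNP must use the Wald ratio)")
    w = 1.0 / sy ** 2
    denom = float(np.sum(w * g * g))
    theta = float(np.sum(w * g * G)) / denom
    se_fixed = 1.0 / math.sqrt(denom)
    q = float(np.sum(w * (G - theta * g) ** 2))
    scale = max(1.0, math.sqrt(q / (J - 1)))
    se = se_fixed * scale if random_effects else se_fixed
    return MrResult(method="IVW", n_snp=J, theta=theta, se=se,
                    pvalue=_normal_p(theta / se), q_statistic=q, df=J - 1)


def cochran_q(hset: HarmonizedInstrumentSet, theta: float,
              df_loss: int = 1) -> tuple[float, int, float]:
    """Heterogeneity statistic Q = sum w_j (Gamma_j - theta*gamma_j)^2 with
    df = J - df_loss (use df_loss=2 after Egger) and upper-tail chi2 p."""
    g, _, G, sy = hset.arrays()
    if len(g) < 2:
        raise MethodError("Cochran Q needs >= 2 SNPs")
    w = 1.0 / sy ** 2
    q = float(np.sum(w * (G - theta * g) ** 2))
    df = len(g) - df_loss
    p = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    return q, df, p


def _profile_nll(theta: float, g: np.ndarray, sx: np.ndarray,
                 G: np.ndarray, sy: np.ndarray) -> float:
    # per-SNP true effects minimized out analytically (known variances)
    v = sy ** 2 + theta ** 2 * sx ** 2
    return float(0.5 * np.sum((G - theta * g) ** 2 / v))


def max_likelihood(hset: HarmonizedInstrumentSet, n_restarts: int = 5) -> MrResult:
    """Maximum-likelihood estimate under the bivariate normal measurement
    model, profiling out the per-SNP true exposure effects.

    SE from the observed information (numerical curvature of the profile
    log-likelihood at the optimum).
    """
    g, sx, G, sy = hset.arrays()
    J = len(g)
    if J < 1:
        raise MethodError("maximum likelihood needs >= 1 SNP")
    # starting point and scale from IVW (or the Wald ratio for J=1)
    w = 1.0 / sy ** 2
    denom = float(np.sum(w * g * g))
    t0 = float(np.sum(w * g * G)) / denom
    s0 = 1.0 / math.sqrt(denom)

    nll = lambda t: _profile_nll(t, g, sx, G, sy)  # noqa: E731
    width = 50.0 * max(s0, 1e-8)
    best = None
    for attempt in range(n_restarts):
        res = optimize.minimize_scalar(
            nll, bounds=(t0 - width, t0 + width), method="bounded",
            options={"xatol": 1e-12})
        interior = (t0 - width + 1e-6 * width < res.x < t0 + width - 1e-6 * width)
        if res.success and interior:
            best = res
            break
        width *= 10.0
    if best is None:
        raise MethodError(
            f"maximum likelihood failed to converge after {n_restarts} "
            f"bracket expansions (last bracket half-width {width:.3g})")
    theta = float(best.x)
    h = 1e-5 * (1.0 + abs(theta))
    curv = (nll(theta + h) - 2.0 * nll(theta) + nll(theta - h)) / h ** 2
    if curv <= 0:
        raise MethodError("maximum likelihood: non-positive observed information")
    se = 1.0 / math.sqrt(curv)
    return MrResult(method="Maximum likelihood", n_snp=J, theta=theta, se=se,
                    pvalue=_normal_p(theta / se))


def _weighted_median(theta: np.ndarray, weight: np.ndarray) -> float:
    order = np.argsort(theta)
    th = theta[order]
    w = weight[order] / weight[order].sum()
    s = np.cumsum(w) - 0.5 * w  # cumulative midpoint per ordered ratio
    if s[0] >= 0.5:
        return float(th[0])
    if s[-1] <= 0.5:
        return float(th[-1])
    k = int(np.searchsorted(s, 0.5))
    if s[k] == s[k - 1]:
        return float(th[k])
    frac = (0.5 - s[k - 1]) / (s[k] - s[k - 1])
    return float(th[k - 1] + frac * (th[k] - th[k - 1]))


def weighted_median_estimate(hset: HarmonizedInstrumentSet) -> float:
    """Point estimate only (no bootstrap): inverse-variance-weighted median
    of the ordered Wald ratios."""
    ratios = wald_ratios(hset)
    th = np.array([r.theta for r in ratios])
    w = np.array([1.0 / r.se ** 2 for r in ratios])
    return _weighted_median(th, w)


def weighted_median(hset: HarmonizedInstrumentSet, n_boot: int = 1000,
                    seed: int | None = None) -> MrResult:
    """Weighted-median estimator: consistent while valid instruments carry
    at least half the weight.  SE by seeded parametric bootstrap."""
    g, sx, G, sy = hset.arrays()
    J = len(g)
    if J < 3:
        raise MethodError(f"weighted median needs >= 3 SNPs, got {J}")
    if n_boot < 100:
        log.warning("weighted_median: n_boot=%d is small; SE will be noisy",
                    n_boot)
    nz = g != 0
    theta = _weighted_median(G[nz] / g[nz], (g[nz] / sy[nz]) ** 2)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        gb = g + sx * rng.standard_normal(J)
        Gb = G + sy * rng.standard_normal(J)
        ok = gb != 0
        boots[b] = _weighted_median(Gb[ok] / gb[ok], (gb[ok] / sy[ok]) ** 2)
    se = float(np.std(boots, ddof=1))
    return MrResult(method="Weighted median", n_snp=J, theta=theta, se=se,
                    pvalue=_normal_p(theta / se))


def egger(hset: HarmonizedInstrumentSet) -> MrResult:
    """MR-Egger regression: weighted regression of Gamma on gamma *with*
    intercept, after orienting all gamma_j >= 0.

    The intercept estimates average directional pleiotropy; its p-value is
    the pleiotropy test.  Student-t inference with J-2 df; multiplicative
    random-effect SE scaling floored at 1.
    """
    g, _, G, sy = hset.arrays()
    J = len(g)
    if J < 3:
        raise MethodError(f"MR-Egger needs >= 3 SNPs, got {J}")
    sign = np.where(g < 0, -1.0, 1.0)
    g, G = g * sign, G * sign
    w = 1.0 / sy ** 2
    sw, swg, swgg = np.sum(w), np.sum(w * g), np.sum(w * g * g)
    swG, swgG = np.sum(w * G), np.sum(w * g * G)
    det = sw * swgg - swg ** 2
    if det <= 0:
        raise MethodError("MR-Egger: degenerate design (no spread in gamma)")
    alpha = (swgg * swG - swg * swgG) / det
    theta = (sw * swgG - swg * swG) / det
    resid = G - alpha - theta * g
    q = float(np.sum(w * resid ** 2))
    df = J - 2
    scale = max(1.0, math.sqrt(q / df))
    se_theta = math.sqrt(sw / det) * scale
    se_alpha = math.sqrt(swgg / det) * scale
    p_theta = float(2.0 * stats.t.sf(abs(theta / se_theta), df))
    p_alpha = float(2.0 * stats.t.sf(abs(alpha / se_alpha), df))
    return MrResult(method="MR-Egger", n_snp=J, theta=float(theta),
                    se=float(se_theta), pvalue=p_theta,
                    intercept=float(alpha), intercept_se=float(se_alpha),
                    intercept_pvalue=p_alpha, q_statistic=q, df=df)


def f_statistic(hset: HarmonizedInstrumentSet) -> tuple[np.ndarray, float]:
    """Instrument strength: per-SNP F_j = (gamma_j/sigma_xj)^2 and the
    overall F (mean of F_j over active SNPs)."""
    g, sx, _, _ = hset.arrays()
    if len(g) < 1:
        raise MethodError("F statistic needs >= 1 SNP")
    per_snp = (g / sx) ** 2
    return per_snp, float(per_snp.mean())


def leave_one_out(hset: HarmonizedInstrumentSet) -> pd.DataFrame:
    """IVW re-estimated omitting each SNP in turn.

    The ``outside_full_ci`` flag marks omissions whose estimate leaves the
    all-SNP 95% CI -- the signature of an influential outlier.
    """
    if hset.n_active < 3:
        raise MethodError("leave-one-out needs >= 3 SNPs")
    full = ivw(hset)
    lo, hi = full.ci
    rows = []
    for rsid in hset.rsids():
        res = ivw(hset.without(rsid))
        rows.append({
            "omitted_rsid": rsid, "n_snp": res.n_snp, "theta": res.theta,
            "se": res.se, "or": res.odds_ratio, "ci_low": res.or_ci[0],
            "ci_high": res.or_ci[1], "pvalue": res.pvalue,
            "outside_full_ci": not (lo <= res.theta <= hi),
        })
    return pd.DataFrame(rows)


def mvmr(hset: HarmonizedInstrumentSet,
         covariate_effects: pd.DataFrame | Mapping[str, Mapping[str, float]],
         exposure_label: str = "exposure") -> MvmrResult:
    """Multivariable MR: weighted regression of Gamma_j on the SNP effects
    for the primary exposure plus one column per covariate exposure, no
    intercept, weights 1/sigma_yj^2.

    ``covariate_effects`` is a DataFrame indexed by rsid (or a nested
    mapping ``{label: {rsid: beta}}``) giving each covariate's SNP effects.
    SNPs missing any covariate effect are dropped and counted.
    """
    if not isinstance(covariate_effects, pd.DataFrame):
        covariate_effects = pd.DataFrame(covariate_effects)
    active = hset.active.set_index("rsid")
    merged = active.join(covariate_effects, how="left")
    complete = merged.dropna(subset=list(covariate_effects.columns))
    n_dropped = len(merged) - len(complete)
    labels = (exposure_label,) + tuple(covariate_effects.columns)
    K = len(labels)
    J = len(complete)
    if J < K + 2:
        raise MethodError(
            f"MVMR needs >= {K + 2} shared SNPs for {K} exposures, got {J}")
    X_full = np.column_stack([complete["gamma"].to_numpy(float)]
                             + [complete[c].to_numpy(float)
                                for c in covariate_effects.columns])
    # an identically-zero covariate column carries no information: drop it
    # from the regression (its coefficient is reported as 0) so the fit
    # degrades gracefully to fewer exposures rather than a singular system
    live = [k for k in range(K) if k == 0 or np.any(X_full[:, k] != 0)]
    X = X_full[:, live]
    y = complete["Gamma"].to_numpy(float)
    w = 1.0 / complete["sigma_y"].to_numpy(float) ** 2
    Xw = X * np.sqrt(w)[:, None]
    if np.linalg.matrix_rank(Xw) < len(live):
        raise MethodError(
            f"MVMR design is rank-deficient; collinear exposures among {labels}")
    xtx = X.T @ (w[:, None] * X)
    beta_live = np.linalg.solve(xtx, X.T @ (w * y))
    resid = y - X @ beta_live
    q = float(np.sum(w * resid ** 2))
    scale = max(1.0, math.sqrt(q / (J - len(live))))
    cov = np.linalg.inv(xtx) * scale ** 2
    se_live = np.sqrt(np.diag(cov))
    beta = np.zeros(K)
    se = np.full(K, math.inf)
    beta[live] = beta_live
    se[live] = se_live
    pvals = tuple(_normal_p(b / s) if math.isfinite(s) else 1.0
                  for b, s in zip(beta, se))
    if n_dropped:
        log.info("MVMR: dropped %d SNPs missing covariate effects", n_dropped)
    return MvmrResult(exposures=labels, theta=tuple(float(b) for b in beta),
                      se=tuple(float(s) for s in se), pvalue=pvals,
                      n_snp=J, n_dropped=n_dropped)
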