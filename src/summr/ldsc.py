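"""LD-score regression: per-trait heritability and cross-trait genetic
correlation from genome-wide z-scores, with block-jackknife SEs.

Under polygenic architecture the expected association chi-square of SNP j
grows linearly in its LD score l_j:

    E[z_j^2]       = intercept + n * h2 * l_j / M
    E[z1_j * z2_j] = intercept + sqrt(n1*n2) * rho_g * l_j / M

so heritability (h2) and genetic covariance (rho_g) are slopes of weighted
regressions on l_j, rescaled by M/n.  The genetic correlation is
rg = rho_g / sqrt(h2_1 * h2_2).  Confounding (and, for the cross trait,
sample overlap) moves the intercept, not the slope, which is why the
intercepts are left free.

Weights are the inverse squared expected variance 1/(1 + n*h2*l/M)^2 with
one re-weighting pass from an initial unweighted fit; the cross regression
uses the product form.  This is a deliberately simple, documented
approximation to the reference implementation's two-step weighting.
Standard errors come from a delete-a-block jackknife over contiguous
blocks (weights frozen at their full-sample values).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ParameterError


@dataclass
class LdscPanel:
    """Aligned per-SNP z-scores for two traits plus LD scores.

    ``M`` is the number of SNPs in the heritability denominator (>= the
    number of rows, since a panel may be a subset of the genome).
    """

    z1: np.ndarray
    z2: np.ndarray
    ell: np.ndarray
    n1: int
    n2: int
    M: int

    def __post_init__(self) -> None:
        self.z1 = np.asarray(self.z1, float)
        self.z2 = np.asarray(self.z2, float)
        self.ell = np.asarray(self.ell, float)
        if not (len(self.z1) == len(self.z2) == len(self.ell)):
            raise ParameterError("z1, z2, ell must have equal length")
        if np.any(self.ell <= 0):
            raise ParameterError("LD scores must be > 0")
        if self.M < len(self.ell):
            raise ParameterError("M must be >= the number of panel rows")

    def __len__(self) -> int:
        return len(self.ell)


@dataclass(frozen=True)
class H2Estimate:
    h2: float
    intercept: float
    se: float


@dataclass(frozen=True)
class RgEstimate:
    """Bivariate LD-score-regression genetic correlation.

    ``rg`` may legitimately fall outside [-1, 1] (it is a ratio of noisy
    estimates); ``flagged`` marks that case and degenerate fits.
    """

    h2_1: float
    h2_2: float
    rho_g: float
    rg: float
    se_rg: float
    intercept_1: float
    intercept_2: float
    gcov_intercept: float
    pvalue: float
    flagged: bool = False
    note: str = ""


def _block_starts(n: int, n_blocks: int) -> np.ndarray:
    # contiguous, nearly equal-size index blocks
    return (np.arange(n_blocks) * n) // n_blocks


def _wls_sums(x, y, w, starts):
    cols = np.column_stack([w, w * x, w * y, w * x * x, w * x * y])
    block = np.add.reduceat(cols, starts, axis=0)
    total = cols.sum(axis=0)
    return total, block


def _slope_intercept(s):
    sw, swx, swy, swxx, swxy = s[..., 0], s[..., 1], s[..., 2], s[..., 3], s[..., 4]
    det = sw * swxx - swx ** 2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swy - slope * swx) / sw
    return slope, intercept


def _regress(x, y, w, n_blocks):
    """Weighted regression with delete-a-block jackknife slopes.

    Returns (slope, intercept, jackknife slopes array)."""
    starts = _block_starts(len(x), n_blocks)
    total, block = _wls_sums(x, y, w, starts)
    slope, intercept = _slope_intercept(total)
    slopes_del, _ = _slope_intercept(total[None, :] - block)
    return float(slope), float(intercept), slopes_del


def _jackknife_se(values: np.ndarray) -> float:
    B = len(values)
    return float(math.sqrt((B - 1) / B * np.sum((values - values.mean()) ** 2)))


def _check_panel(panel: LdscPanel, n_blocks: int) -> None:
    if n_blocks < 2:
        raise ParameterError("n_blocks must be >= 2")
    if len(panel) < n_blocks:
        raise ParameterError(
            f"panel has {len(panel)} rows, fewer than {n_blocks} blocks")
    if np.ptp(panel.ell) == 0:
        raise ParameterError("constant LD scores: regression is degenerate")


def _h2_weights(n: int, h2_guess: float, ell: np.ndarray, M: int) -> np.ndarray:
    h = min(max(h2_guess, 0.0), 1.0)
    return 1.0 / (1.0 + n * h * ell / M) ** 2


def _fit_h2_internal(z, n, panel, n_blocks):
    y = z ** 2
    slope0, _, _ = _regress(panel.ell, y, np.ones_like(y), n_blocks)
    w = _h2_weights(n, slope0 * panel.M / n, panel.ell, panel.M)
    slope, intercept, slopes_del = _regress(panel.ell, y, w, n_blocks)
    scale = panel.M / n
    return slope * scale, intercept, slopes_del * scale, w


def fit_h2(panel: LdscPanel, trait: int = 1, n_blocks: int = 200) -> H2Estimate:
    """Heritability of one trait by LD-score regression with a free
    intercept; SE by delete-a-block jackknife."""
    if trait not in (1, 2):
        raise ParameterError("trait must be 1 or 2")
    _check_panel(panel, n_blocks)
    z = panel.z1 if trait == 1 else panel.z2
    n = panel.n1 if trait == 1 else panel.n2
    h2, intercept, h2_del, _ = _fit_h2_internal(z, n, panel, n_blocks)
    return H2Estimate(h2=float(h2), intercept=float(intercept),
                      se=_jackknife_se(h2_del))


def fit_rg(panel: LdscPanel, n_blocks: int = 200) -> RgEstimate:
    """Cross-trait genetic correlation with jackknife SE of the full ratio
    (heritabilities and genetic covariance are all recomputed per deleted
    block).

    When either heritability estimate is non-positive the correlation is
    undefined; a flagged estimate with ``rg = nan`` is returned rather
    than raising, mirroring how weak traits fail in practice.
    """
    _check_panel(panel, n_blocks)
    h2_1, int_1, h1_del, _ = _fit_h2_internal(panel.z1, panel.n1, panel, n_blocks)
    h2_2, int_2, h2_del, _ = _fit_h2_internal(panel.z2, panel.n2, panel, n_blocks)
    w_cross = np.sqrt(
        _h2_weights(panel.n1, h2_1, panel.ell, panel.M)
        * _h2_weights(panel.n2, h2_2, panel.ell, panel.M))
    scale = panel.M / math.sqrt(panel.n1 * panel.n2)
    slope, gcov_int, slopes_del = _regress(
        panel.ell, panel.z1 * panel.z2, w_cross, n_blocks)
    rho_g = slope * scale
    rho_del = slopes_del * scale

    if h2_1 <= 0 or h2_2 <= 0:
        return RgEstimate(h2_1=h2_1, h2_2=h2_2, rho_g=rho_g, rg=float("nan"),
                          se_rg=float("nan"), intercept_1=int_1,
                          intercept_2=int_2, gcov_intercept=gcov_int,
                          pvalue=float("nan"), flagged=True,
                          note="non-positive heritability estimate")
    rg = rho_g / math.sqrt(h2_1 * h2_2)
    eps = 1e-12
    rg_del = rho_del / np.sqrt(np.clip(h1_del, eps, None)
                               * np.clip(h2_del, eps, None))
    se = _jackknife_se(rg_del)
    clipped = bool(np.any(h1_del <= 0) or np.any(h2_del <= 0))
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(rg) / se))
    else:
        p = 1.0 if rg == 0 else 0.0
    flagged = clipped or abs(rg) > 1 or se == 0
    note = ("jackknife heritability clipped" if clipped else
            "|rg| > 1" if abs(rg) > 1 else
            "degenerate jackknife" if se == 0 else "")
    return RgEstimate(h2_1=float(h2_1), h2_2=float(h2_2), rho_g=float(rho_g),
                      rg=float(rg), se_rg=se, intercept_1=float(int_1),
                      intercept_2=float(int_2), gcov_intercept=float(gcov_int),
                      pvalue=p, flagged=flagged, note=note)
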