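"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator works entirely on the summary scale the analysis consumes: a
continuous exposure measured in a large cohort (default n = 941,280, the
scale of current drinks-per-week GWAS) and a binary outcome analysed as a
case-control GWAS whose effects live on the log-odds scale (defaults sized
like a rheumatoid-arthritis GWAS, 14,361 cases / 43,923 controls).

Per SNP j with effect-allele frequency p_j:

* true exposure effects gamma_j are oriented to the exposure-increasing
  allele (the convention instrument lists are reported in) and scaled so
  the instruments jointly explain a configurable fraction of exposure
  variance (default 1%, which at these sample sizes yields per-SNP F
  around 10^2);
* standard errors follow the standard GWAS approximations
  sigma_x = 1/sqrt(2 p q n) for the standardized continuous trait and
  sigma_y = 1/sqrt(2 p q n phi (1-phi)) on the log-OR scale, phi the case
  fraction;
* observed effects are gamma_hat ~ N(gamma, sigma_x^2) and
  Gamma_hat ~ N(theta*gamma + alpha, sigma_y^2), where alpha_j is the
  direct (pleiotropic) SNP-outcome effect.

Pleiotropy scenarios: balanced (zero-mean alpha), directional (non-zero
mean on a fraction of SNPs), and confounder-mediated (a fraction of SNPs
act through a shared confounder that loads on both exposure and outcome,
breaking the exclusion restriction as a group -- the scenario multivariable
MR is designed to repair).

A separate genome-wide panel generator produces paired z-scores and LD
scores with a planted genetic covariance for LD-score regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import ParameterError
from .io import GwasRecord, InstrumentList
from .ldsc import LdscPanel

_DEFAULT_N_EXPOSURE = 941_280
_DEFAULT_N_CASES = 14_361
_DEFAULT_N_CONTROLS = 43_923

_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_NON_PALINDROMIC_PAIRS = (("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
                          ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"))


@dataclass(frozen=True)
class BalancedPleiotropy:
    """Zero-mean direct effects alpha_j ~ N(0, sd^2) on every SNP."""

    sd: float


@dataclass(frozen=True)
class DirectionalPleiotropy:
    """Direct effects alpha_j ~ N(mean, sd^2) on a fraction of SNPs.

    Invalid SNPs are spread evenly across the instrument-strength
    distribution so the *weight share* of invalid instruments matches the
    stated fraction (robustness guarantees like the weighted median's 50%
    breakdown point are about weight, not counts).
    """

    mean: float
    sd: float = 0.0
    fraction: float = 1.0


@dataclass(frozen=True)
class ConfounderPleiotropy:
    """A fraction of SNPs act through a shared confounder.

    Loaded SNPs get a loading u_j (scaled so the loadings explain
    ``h2_confounder`` of the confounder's variance); the confounder adds
    ``exposure_loading * u_j`` to the SNP-exposure effect and
    ``outcome_effect * u_j`` directly to the SNP-outcome effect.  Because
    the same u_j enters both, IVW is biased while MVMR that includes the
    confounder's SNP effects recovers theta.
    """

    fraction: float = 0.3
    outcome_effect: float = 0.5
    exposure_loading: float = 0.5
    h2_confounder: float = 0.02
    n_confounder: int = 700_000


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside every generated dataset."""

    theta_true: float
    gamma_true: np.ndarray
    alpha: np.ndarray
    cluster_id: np.ndarray
    seed: int | None = None
    rho_g_true: float | None = None
    h2_x: float | None = None
    h2_y: float | None = None
    confounder_loadings: np.ndarray | None = None
    confounder_records: list[GwasRecord] | None = field(default=None,
                                                        repr=False)


def _alleles(J: int, palindromic_fraction: float,
             rng: np.random.Generator) -> tuple[list[str], list[str], np.ndarray]:
    if not (0.0 <= palindromic_fraction <= 1.0):
        raise ParameterError("palindromic_fraction must lie in [0, 1]")
    n_pal = int(round(palindromic_fraction * J))
    is_pal = np.zeros(J, dtype=bool)
    is_pal[rng.permutation(J)[:n_pal]] = True
    ea, oa = [], []
    for flag in is_pal:
        pool = _PALINDROMIC_PAIRS if flag else _NON_PALINDROMIC_PAIRS
        a, b = pool[rng.integers(len(pool))]
        ea.append(a)
        oa.append(b)
    return ea, oa, is_pal


def _records(rsids: Sequence[str], ea: Sequence[str], oa: Sequence[str],
             eaf: np.ndarray, beta: np.ndarray, se: np.ndarray,
             n: float | None = None, n_cases: float | None = None,
             n_controls: float | None = None) -> list[GwasRecord]:
    pvals = 2.0 * stats.norm.sf(np.abs(beta / se))
    return [GwasRecord(rsid=r, effect_allele=a, other_allele=b,
                       eaf=float(p), beta=float(bb), se=float(s),
                       pvalue=float(max(pv, 1e-300)), n=n,
                       n_cases=n_cases, n_controls=n_controls)
            for r, a, b, p, bb, s, pv in zip(rsids, ea, oa, eaf, beta, se, pvals)]


def gen_two_sample(J: int = 99,
                   n_exp: int = _DEFAULT_N_EXPOSURE,
                   n_cases: int = _DEFAULT_N_CASES,
                   n_controls: int = _DEFAULT_N_CONTROLS,
                   theta_true: float = 0.0,
                   pleiotropy: BalancedPleiotropy | DirectionalPleiotropy
                   | ConfounderPleiotropy | None = None,
                   h2_exposure: float = 0.01,
                   eaf_range: tuple[float, float] = (0.05, 0.95),
                   palindromic_fraction: float = 0.0,
                   seed: int | None = None,
                   rsid_start: int = 1_000_001
                   ) -> tuple[list[GwasRecord], list[GwasRecord],
                              InstrumentList, SimulationTruth]:
    """Generate matched exposure and outcome summary statistics.

    Returns ``(exposure_records, outcome_records, instruments, truth)``.
    Identical seed and parameters give identical output.
    """
    if J < 1:
        raise ParameterError("J must be >= 1")
    if n_exp < 2 or n_cases + n_controls < 2:
        raise ParameterError("sample sizes must be >= 2")
    if not (0 < h2_exposure < 1):
        raise ParameterError("h2_exposure must lie in (0, 1)")
    lo, hi = eaf_range
    if not (0 < lo < hi < 1):
        raise ParameterError("eaf_range must satisfy 0 < low < high < 1")
    rng = np.random.default_rng(seed)

    p = rng.uniform(lo, hi, J)
    het = 2.0 * p * (1.0 - p)
    raw = np.abs(rng.standard_normal(J))  # exposure-increasing orientation
    gamma = raw * np.sqrt(h2_exposure / np.sum(het * raw ** 2))

    alpha = np.zeros(J)
    cluster_id = np.zeros(J, dtype=int)
    loadings = None
    confounder_records = None
    if isinstance(pleiotropy, BalancedPleiotropy):
        alpha = rng.normal(0.0, pleiotropy.sd, J)
    elif isinstance(pleiotropy, DirectionalPleiotropy):
        if not (0.0 < pleiotropy.fraction <= 1.0):
            raise ParameterError("pleiotropy fraction must lie in (0, 1]")
        m = max(1, int(round(pleiotropy.fraction * J)))
        # even spread over ratio-weight ranks: invalid weight share ~= fraction
        order = np.argsort(het * gamma ** 2)
        idx = order[((np.arange(m) + 0.5) * J / m).astype(int)]
        alpha[idx] = rng.normal(pleiotropy.mean, pleiotropy.sd, m)
        cluster_id[idx] = 1
    elif isinstance(pleiotropy, ConfounderPleiotropy):
        if not (0.0 < pleiotropy.fraction <= 1.0):
            raise ParameterError("confounder fraction must lie in (0, 1]")
        m = max(1, int(round(pleiotropy.fraction * J)))
        idx = rng.permutation(J)[:m]
        u_raw = rng.standard_normal(m)
        u = np.zeros(J)
        u[idx] = u_raw * np.sqrt(
            pleiotropy.h2_confounder / np.sum(het[idx] * u_raw ** 2))
        gamma = gamma + pleiotropy.exposure_loading * u
        alpha = pleiotropy.outcome_effect * u
        cluster_id[idx] = 1
        loadings = u
    elif pleiotropy is not None:
        raise ParameterError(f"unknown pleiotropy scenario: {pleiotropy!r}")

    sigma_x = 1.0 / np.sqrt(het * n_exp)
    n_out = n_cases + n_controls
    phi = n_cases / n_out
    sigma_y = 1.0 / np.sqrt(het * n_out * phi * (1.0 - phi))

    gamma_hat = gamma + sigma_x * rng.standard_normal(J)
    Gamma_hat = theta_true * gamma + alpha + sigma_y * rng.standard_normal(J)

    rsids = [f"rs{rsid_start + j}" for j in range(J)]
    ea, oa, _ = _alleles(J, palindromic_fraction, rng)
    exposure = _records(rsids, ea, oa, p, gamma_hat, sigma_x, n=n_exp)
    outcome = _records(rsids, ea, oa, p, Gamma_hat, sigma_y,
                       n=n_out, n_cases=n_cases, n_controls=n_controls)

    if loadings is not None:
        assert isinstance(pleiotropy, ConfounderPleiotropy)
        sigma_u = 1.0 / np.sqrt(het * pleiotropy.n_confounder)
        u_hat = loadings + sigma_u * rng.standard_normal(J)
        confounder_records = _records(rsids, ea, oa, p, u_hat, sigma_u,
                                      n=pleiotropy.n_confounder)

    truth = SimulationTruth(theta_true=theta_true, gamma_true=gamma,
                            alpha=alpha, cluster_id=cluster_id, seed=seed,
                            h2_x=h2_exposure,
                            confounder_loadings=loadings,
                            confounder_records=confounder_records)
    ivs = InstrumentList(tuple(rsids), source_label="synthetic exposure")
    return exposure, outcome, ivs, truth


def gen_clustered(cluster_means: Sequence[float],
                  cluster_sizes: Sequence[int],
                  null_size: int = 0,
                  junk_size: int = 0,
                  se_scale: float = 1.0,
                  junk_range: float = 3.0,
                  seed: int | None = None,
                  n_exp: int = _DEFAULT_N_EXPOSURE,
                  n_cases: int = _DEFAULT_N_CASES,
                  n_controls: int = _DEFAULT_N_CONTROLS,
                  eaf_range: tuple[float, float] = (0.1, 0.9)
                  ) -> tuple[list[GwasRecord], list[GwasRecord],
                             InstrumentList, SimulationTruth]:
    """Generate instruments whose per-variant causal estimates concentrate
    around distinct cluster means, plus null and broadly scattered junk
    variants.

    ``cluster_id`` in the returned truth is 1..K for substantive clusters,
    0 for null variants, -1 for junk.  ``se_scale`` multiplies the outcome
    SE (smaller values give tighter, easier-to-separate clusters).
    """
    if len(cluster_means) != len(cluster_sizes):
        raise ParameterError("cluster_means and cluster_sizes length mismatch")
    if any(s < 1 for s in cluster_sizes):
        raise ParameterError("every cluster needs at least 1 member")
    if null_size < 0 or junk_size < 0:
        raise ParameterError("null_size and junk_size must be >= 0")
    if se_scale <= 0:
        raise ParameterError("se_scale must be > 0")
    rng = np.random.default_rng(seed)
    J = int(sum(cluster_sizes)) + null_size + junk_size

    theta_j = np.zeros(J)
    cluster_id = np.zeros(J, dtype=int)
    pos = 0
    for k, (mu, size) in enumerate(zip(cluster_means, cluster_sizes), start=1):
        theta_j[pos:pos + size] = mu
        cluster_id[pos:pos + size] = k
        pos += size
    pos += null_size  # null variants keep theta_j = 0, cluster_id = 0
    if junk_size:
        theta_j[pos:] = rng.uniform(-junk_range, junk_range, junk_size)
        cluster_id[pos:] = -1

    p = rng.uniform(*eaf_range, J)
    het = 2.0 * p * (1.0 - p)
    gamma = rng.uniform(0.02, 0.05, J) * rng.choice([-1.0, 1.0], J)
    sigma_x = 1.0 / np.sqrt(het * n_exp)
    n_out = n_cases + n_controls
    phi = n_cases / n_out
    sigma_y = se_scale / np.sqrt(het * n_out * phi * (1.0 - phi))

    gamma_hat = gamma + sigma_x * rng.standard_normal(J)
    Gamma_hat = theta_j * gamma + sigma_y * rng.standard_normal(J)

    rsids = [f"rs{2000001 + j}" for j in range(J)]
    ea, oa, _ = _alleles(J, 0.0, rng)
    exposure = _records(rsids, ea, oa, p, gamma_hat, sigma_x, n=n_exp)
    outcome = _records(rsids, ea, oa, p, Gamma_hat, sigma_y,
                       n=n_out, n_cases=n_cases, n_controls=n_controls)
    truth = SimulationTruth(theta_true=float("nan"), gamma_true=gamma,
                            alpha=theta_j * gamma, cluster_id=cluster_id,
                            seed=seed)
    ivs = InstrumentList(tuple(rsids), source_label="synthetic clustered")
    return exposure, outcome, ivs, truth


def gen_ldsc_panel(M: int, n1: int, n2: int, h2_x: float, h2_y: float,
                   rho_g: float, overlap_intercept: float = 0.0,
                   ld_score_distribution: tuple[float, float] = (2.0, 50.0),
                   seed: int | None = None) -> LdscPanel:
    """Generate a genome-wide panel of paired z-scores and LD scores.

    Per SNP j with LD score l_j (gamma-distributed, right-skewed like
    empirical LD scores), (z1, z2) is bivariate normal with

        Var(z1) = 1 + n1*h2_x*l_j/M
        Var(z2) = 1 + n2*h2_y*l_j/M
        Cov     = sqrt(n1*n2)*rho_g*l_j/M + overlap_intercept

    ``rho_g`` is the genetic covariance; the planted genetic correlation is
    rho_g/sqrt(h2_x*h2_y) and must have magnitude <= 1.
    """
    if M < 1000:
        raise ParameterError("M must be >= 1000")
    if not (0 <= h2_x <= 1 and 0 <= h2_y <= 1):
        raise ParameterError("heritabilities must lie in [0, 1]")
    if abs(rho_g) > np.sqrt(h2_x * h2_y) + 1e-12:
        raise ParameterError("|rho_g| must be <= sqrt(h2_x*h2_y)")
    shape, scale = ld_score_distribution
    if shape <= 0 or scale <= 0:
        raise ParameterError("LD score distribution parameters must be > 0")
    rng = np.random.default_rng(seed)
    ell = rng.gamma(shape, scale, M)

    v1 = 1.0 + n1 * h2_x * ell / M
    v2 = 1.0 + n2 * h2_y * ell / M
    c = np.sqrt(n1 * n2) * rho_g * ell / M + overlap_intercept
    resid = v2 - c ** 2 / v1
    bad = np.flatnonzero(resid < 0)
    if bad.size:
        raise ParameterError(
            f"covariance matrix not positive semi-definite at SNP index "
            f"{int(bad[0])} (overlap_intercept too large?)")
    a = rng.standard_normal(M)
    b = rng.standard_normal(M)
    z1 = np.sqrt(v1) * a
    z2 = (c / np.sqrt(v1)) * a + np.sqrt(resid) * b
    return LdscPanel(z1=z1, z2=z2, ell=ell, n1=n1, n2=n2, M=M)
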