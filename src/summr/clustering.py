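"""Clustering of per-variant causal estimates.

A single MR estimate averages over instruments, but distinct biological
mechanisms can drive subsets of variants toward different causal effects.
This module fits, for each candidate number of substantive clusters K, a
mixture over the Wald ratios theta_j with components

* substantive k:  Normal(mu_k, se_j^2)   -- a shared causal effect,
* null:           Normal(0,    se_j^2)   -- no effect,
* junk:           Uniform over the observed theta range inflated by 20%,

where each variant keeps its own measurement variance se_j^2 (optionally
inflated), so components cannot collapse.  EM maximizes the likelihood,
K is selected by BIC (ties toward smaller K), and a variant is hard-
assigned only where its posterior exceeds a threshold; a substantive
cluster is *displayed* only if enough variants are assigned to it
(defaults 0.8 and 4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .estimators import RatioEstimate
from .exceptions import MethodError, ParameterError

log = logging.getLogger(__name__)

NULL_LABEL = "null"
JUNK_LABEL = "junk"
UNASSIGNED_LABEL = "unassigned"


@dataclass
class ClusterSolution:
    """Fitted mixture over per-variant causal estimates."""

    n_components: int                 # BIC-selected number of substantive clusters
    mu: np.ndarray                    # cluster means, ascending
    pi: np.ndarray                    # mixing proportions [clusters..., null, junk]
    responsibilities: pd.DataFrame    # per-variant posterior, rows sum to 1
    assignments: pd.DataFrame         # rsid, cluster label, probability
    displayed_clusters: tuple[int, ...]  # 1-based ids passing the display rule
    bic_trace: dict[int, float]
    loglik: float
    loglik_trace: list[float]
    threshold: float
    min_size: int
    seed: int | None

    @property
    def n_displayed(self) -> int:
        return len(self.displayed_clusters)


def _kmeanspp_init(theta: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    centers = [theta[rng.integers(len(theta))]]
    while len(centers) < K:
        d2 = np.min((theta[:, None] - np.array(centers)[None, :]) ** 2, axis=1)
        total = d2.sum()
        if total <= 0:
            centers.append(theta[rng.integers(len(theta))])
            continue
        centers.append(theta[rng.choice(len(theta), p=d2 / total)])
    return np.array(sorted(centers))


def _em(theta: np.ndarray, var: np.ndarray, mu0: np.ndarray,
        junk_logpdf: float, tol: float, max_iter: int
        ) -> tuple[float, np.ndarray, np.ndarray, np.ndarray, list[float]]:
    """EM for K = len(mu0) substantive components + null + junk.

    Raises MethodError if the log-likelihood ever decreases (beyond
    numerical jitter) -- it must be monotone for a correct EM step.
    """
    J = len(theta)
    K = len(mu0)
    C = K + 2
    mu = mu0.astype(float).copy()
    pi = np.full(C, 1.0 / C)
    prec = 1.0 / var
    const = -0.5 * np.log(2.0 * np.pi * var)
    prev_ll = -np.inf
    trace: list[float] = []
    resp = np.full((J, C), 1.0 / C)
    for _ in range(max_iter):
        logpdf = np.empty((J, C))
        means = np.concatenate([mu, [0.0]])
        logpdf[:, :K + 1] = const[:, None] - 0.5 * prec[:, None] * \
            (theta[:, None] - means[None, :]) ** 2
        logpdf[:, K + 1] = junk_logpdf
        logw = np.log(np.clip(pi, 1e-300, None))[None, :] + logpdf
        norm = logsumexp(logw, axis=1)
        ll = float(norm.sum())
        if ll < prev_ll - 1e-6 * (1.0 + abs(prev_ll)):
            raise MethodError(f"EM log-likelihood decreased: {prev_ll} -> {ll}")
        trace.append(ll)
        resp = np.exp(logw - norm[:, None])
        for k in range(K):
            wk = resp[:, k] * prec
            denom = wk.sum()
            if denom > 0:
                mu[k] = float(np.dot(wk, theta) / denom)
        pi = resp.mean(axis=0)
        if abs(ll - prev_ll) < tol:
            prev_ll = ll
            break
        prev_ll = ll
    return prev_ll, mu, pi, resp, trace


def fit_clusters(ratios: Sequence[RatioEstimate], K_max: int = 5,
                 threshold: float = 0.8, min_size: int = 4,
                 seed: int | None = None, n_starts: int = 5,
                 variance_inflation: float = 1.0, tol: float = 1e-8,
                 max_iter: int = 10_000) -> ClusterSolution:
    """Fit mixtures for K = 0..K_max substantive clusters and select by BIC.

    Posterior responsibilities are computed at the optimum; a variant is
    hard-assigned to the component with maximal posterior only when that
    posterior exceeds ``threshold``; a substantive cluster is displayed
    only when at least ``min_size`` variants are assigned to it.  The full
    per-K BIC trace is kept so cluster appearance/disappearance across
    instrument curation can be audited.
    """
    if K_max < 1:
        raise ParameterError("K_max must be >= 1")
    if not ratios or len(ratios) < min_size:
        raise ParameterError(
            f"need at least min_size={min_size} variants, got {len(ratios)}")
    if not (0.0 < threshold < 1.0):
        raise ParameterError("threshold must lie in (0, 1)")
    if variance_inflation <= 0:
        raise ParameterError("variance_inflation must be > 0")
    theta = np.array([r.theta for r in ratios], float)
    se = np.array([r.se for r in ratios], float)
    if np.any(se <= 0):
        raise ParameterError("ratio SEs must be > 0")
    rsids = [r.rsid for r in ratios]
    var = variance_inflation * se ** 2
    J = len(theta)

    spread = float(theta.max() - theta.min())
    pad = 0.1 * spread if spread > 0 else 0.1 * float(np.median(se))
    junk_logpdf = -np.log(max(spread + 2 * pad, 1e-12))

    rng = np.random.default_rng(seed)
    fits: dict[int, tuple] = {}
    bic_trace: dict[int, float] = {}
    for K in range(K_max + 1):
        best = None
        failures: list[str] = []
        for _ in range(n_starts if K > 0 else 1):
            mu0 = _kmeanspp_init(theta, K, rng) if K > 0 else np.empty(0)
            try:
                fit = _em(theta, var, mu0, junk_logpdf, tol, max_iter)
            except MethodError as exc:  # pragma: no cover - defensive
                failures.append(str(exc))
                continue
            if best is None or fit[0] > best[0]:
                best = fit
        if best is None:
            raise MethodError(
                f"EM failed in all starts at K={K}: {failures}")
        fits[K] = best
        n_params = 2 * K + 1  # K means + (K+2-1) free mixing proportions
        bic_trace[K] = -2.0 * best[0] + n_params * np.log(J)

    K_best = 0
    for K in range(K_max + 1):
        if bic_trace[K] < bic_trace[K_best] - 1e-9:
            K_best = K
    ll, mu, pi, resp, trace = fits[K_best]

    # canonical order: ascending means (label-permutation invariance)
    if K_best > 0:
        order = np.argsort(mu)
        mu = mu[order]
        pi = np.concatenate([pi[order], pi[K_best:]])
        resp = np.column_stack([resp[:, order], resp[:, K_best:]])

    comp_labels = [f"cluster_{k + 1}" for k in range(K_best)] + \
        [NULL_LABEL, JUNK_LABEL]
    resp_df = pd.DataFrame(resp, columns=comp_labels)
    resp_df.insert(0, "rsid", rsids)

    best_comp = np.argmax(resp, axis=1)
    best_prob = resp[np.arange(J), best_comp]
    hard = [comp_labels[c] if p > threshold else UNASSIGNED_LABEL
            for c, p in zip(best_comp, best_prob)]
    assignments = pd.DataFrame({"rsid": rsids, "cluster": hard,
                                "probability": best_prob})
    displayed = tuple(
        k + 1 for k in range(K_best)
        if sum(h == f"cluster_{k + 1}" for h in hard) >= min_size)
    log.info("cluster fit: selected K=%d, displayed clusters %s (BIC %s)",
             K_best, displayed,
             {k: round(v, 2) for k, v in bic_trace.items()})
    return ClusterSolution(
        n_components=K_best, mu=mu, pi=pi, responsibilities=resp_df,
        assignments=assignments, displayed_clusters=displayed,
        bic_trace=bic_trace, loglik=ll, loglik_trace=trace,
        threshold=threshold, min_size=min_size, seed=seed)


def assignment_table(solution: ClusterSolution) -> pd.DataFrame:
    """One row per variant: rsid, hard cluster label (or unassigned), and
    the posterior probability behind it -- the data behind a scatter of
    exposure vs outcome effects colored by cluster."""
    return solution.assignments.copy()
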