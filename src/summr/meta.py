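"""Fixed-effect inverse-variance meta-analysis of odds ratios across
diseases, and analytic power for binary-outcome MR.

These operate on *printed* results as well as freshly computed ones: a
published OR with its 95% CI is enough, since the log-scale SE is
recoverable as (ln(high) - ln(low)) / (2 * 1.959964).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .estimators import MrResult, Z95
from .exceptions import MethodError, ParameterError


@dataclass(frozen=True)
class MetaInput:
    """One study's estimate on the log-OR scale."""

    label: str
    theta: float
    se: float

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ParameterError(f"{self.label}: se must be > 0")

    @classmethod
    def from_or_ci(cls, label: str, or_: float, low: float,
                   high: float) -> "MetaInput":
        """Build from a printed odds ratio and its 95% CI."""
        if or_ <= 0:
            raise ParameterError(f"{label}: odds ratio must be > 0")
        if not (low < or_ < high):
            raise ParameterError(
                f"{label}: need low < OR < high, got {low}, {or_}, {high}")
        return cls(label, math.log(or_), se_from_ci(low, high))


def se_from_ci(low: float, high: float) -> float:
    """Log-scale SE implied by a 95% CI on an odds ratio."""
    if low <= 0 or high <= 0:
        raise ParameterError("CI bounds must be positive")
    if not low < high:
        raise ParameterError("CI requires low < high")
    return (math.log(high) - math.log(low)) / (2.0 * Z95)


def meta_fixed(inputs: Sequence[MetaInput]) -> MrResult:
    """Fixed-effect inverse-variance pooled estimate with cross-study
    Cochran Q."""
    if len(inputs) < 2:
        raise MethodError("meta-analysis needs >= 2 studies")
    w = [1.0 / s.se ** 2 for s in inputs]
    sw = sum(w)
    theta = sum(wi * s.theta for wi, s in zip(w, inputs)) / sw
    se = 1.0 / math.sqrt(sw)
    q = sum(wi * (s.theta - theta) ** 2 for wi, s in zip(w, inputs))
    df = len(inputs) - 1
    p = float(2.0 * stats.norm.sf(abs(theta / se)))
    return MrResult(method="Fixed-effect meta", n_snp=len(inputs),
                    theta=theta, se=se, pvalue=p, q_statistic=q, df=df)


@dataclass(frozen=True)
class PowerSpec:
    """Inputs for the analytic binary-outcome MR power approximation."""

    alpha: float
    or_alt: float
    r2: float
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ParameterError("alpha must lie in (0, 1)")
        if self.or_alt <= 0:
            raise ParameterError("or_alt must be > 0")
        if not (0.0 <= self.r2 < 1.0):
            raise ParameterError("r2 must lie in [0, 1)")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ParameterError("case and control counts must be >= 1")


def mr_power_binary(spec: PowerSpec) -> float:
    """Power to detect OR ``or_alt`` per SD of exposure, with instruments
    explaining ``r2`` of exposure variance, in a case-control study.

    Normal approximation: with N = cases + controls and case fraction phi,
    the test statistic is centered at |ln OR| * sqrt(N * r2 * phi*(1-phi)),
    so power = Phi(-z_{1-alpha/2} + that noncentrality).
    """
    n = spec.n_cases + spec.n_controls
    phi = spec.n_cases / n
    b = abs(math.log(spec.or_alt))
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    ncp = b * math.sqrt(n * spec.r2 * phi * (1.0 - phi))
    return float(stats.norm.cdf(-z + ncp))
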