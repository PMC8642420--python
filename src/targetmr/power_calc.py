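"""Power diagnostics for MR with a binary outcome.

Instrument strength is summarized as the variance in the exposure explained
per SNP, R^2 = 2 beta^2 MAF (1-MAF); the classic sample-size heuristic
divides the epidemiological sample size by R^2; and the detectable OR at a
target power comes from the normal approximation for a case-control outcome,
log OR = (z_{1-alpha/2} + z_power) / sqrt(n R^2 k (1-k)).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .exceptions import ValidationError


@dataclass
class PowerQuery:
    """Inputs for a detectable-OR calculation on a binary outcome."""

    n: int
    k: float
    r2: float
    power: float = 0.8
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValidationError("n must be positive")
        if not 0.0 < self.k < 1.0:
            raise ValidationError("case fraction k must be in (0,1)")
        if not 0.0 < self.r2 < 1.0:
            raise ValidationError("r2 must be in (0,1)")
        if not 0.0 < self.power < 1.0:
            raise ValidationError("power must be in (0,1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must be in (0,1)")


def r2_from_beta_maf(beta: float, maf: float) -> float:
    """Variance in an SD-scaled exposure explained by one SNP: 2 beta^2 MAF (1-MAF)."""
    if not 0.0 < maf <= 0.5:
        raise ValidationError(f"MAF must be in (0, 0.5], got {maf}")
    return 2.0 * beta**2 * maf * (1.0 - maf)


def required_n(n_epi: float, r2: float) -> float:
    """Sample size for an MR study: epidemiological sample size divided by R^2."""
    if r2 <= 0:
        raise ValidationError("r2 must be > 0")
    return n_epi / r2


def detectable_or(query: PowerQuery) -> float:
    """Smallest OR above 1 detectable at the queried power and alpha.

    Normal approximation: the z-statistic for the causal log OR b has mean
    b * sqrt(n r2 k (1-k)), so the detectable effect solves
    b = (z_{1-alpha/2} + z_power) / sqrt(n r2 k (1-k)).
    """
    z_alpha = stats.norm.ppf(1.0 - query.alpha / 2.0)
    z_power = stats.norm.ppf(query.power)
    b = (z_alpha + z_power) / math.sqrt(
        query.n * query.r2 * query.k * (1.0 - query.k)
    )
    return math.exp(b)
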