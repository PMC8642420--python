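"""Core causal estimators.

Wald ratio for a single instrument, inverse-variance weighted (IVW)
combination for independent instruments (fixed effects up to three SNPs,
multiplicative random effects from four), generalized IVW for correlated
instruments using the signed LD matrix, and the Cochran Q heterogeneity
statistic.

Weights follow the NO-Measurement-Error convention of two-sample MR:
exposure standard errors enter the F-statistic and simulations only, never
the IVW weights. The reference distribution for p-values and 95% CIs is
normal throughout.
"""
from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import linalg, stats

from .exceptions import EstimationError
from .types import HarmonizedInstrument, InstrumentSet, MREstimate, Z_95

#: SNP count at which the IVW switches to multiplicative random effects
RANDOM_EFFECTS_MIN_SNPS = 4


def wald_ratio(inst: HarmonizedInstrument) -> MREstimate:
    """Single-instrument causal estimate: beta_outcome / beta_exposure.

    The SE is the first-order delta-method form se_outcome/|beta_exposure|
    (outcome noise only), which makes the single-SNP IVW reduce to this
    estimator exactly.
    """
    if inst.beta_exposure == 0:
        raise EstimationError(f"{inst.snp_id}: null instrument (beta_exposure = 0)")
    beta = inst.beta_outcome / inst.beta_exposure
    se = inst.se_outcome / abs(inst.beta_exposure)
    return MREstimate.from_beta_se(beta, se, method="wald", n_snps=1)


def _ratios_weights(
    instruments: Sequence[HarmonizedInstrument],
) -> tuple[np.ndarray, np.ndarray]:
    bx = np.array([i.beta_exposure for i in instruments])
    by = np.array([i.beta_outcome for i in instruments])
    sy = np.array([i.se_outcome for i in instruments])
    if np.any(bx == 0):
        bad = [i.snp_id for i in instruments if i.beta_exposure == 0]
        raise EstimationError(f"null instrument(s): {', '.join(bad)}")
    theta = by / bx
    w = (bx / sy) ** 2
    return theta, w


def cochran_q(
    instruments: Sequence[HarmonizedInstrument] | InstrumentSet, beta_ivw: float
) -> tuple[float, int, float]:
    """Cochran's Q about ``beta_ivw``: (Q, df, upper-tail chi-square p)."""
    if isinstance(instruments, InstrumentSet):
        instruments = instruments.instruments
    if len(instruments) < 2:
        raise EstimationError("Cochran's Q requires at least two instruments")
    theta, w = _ratios_weights(instruments)
    q = float(np.sum(w * (theta - beta_ivw) ** 2))
    df = len(instruments) - 1
    return q, df, float(stats.chi2.sf(q, df))


def ivw(
    instruments: InstrumentSet,
    random_effects_min_snps: int = RANDOM_EFFECTS_MIN_SNPS,
) -> MREstimate:
    """IVW combination of per-SNP Wald ratios for independent instruments.

    Fixed effects below ``random_effects_min_snps`` instruments; from that
    count on, the SE is inflated by max(1, sqrt(Q/(n-2))) (multiplicative
    overdispersion, floored so random effects never beat fixed).
    """
    if instruments.mode == "all_correlated":
        raise EstimationError("use ivw_correlated for all_correlated instrument sets")
    insts = instruments.instruments
    if not insts:
        raise EstimationError("empty instrument set")
    if len(insts) == 1:
        return wald_ratio(insts[0])

    theta, w = _ratios_weights(insts)
    beta = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    q, q_df, q_pval = cochran_q(insts, beta)

    n = len(insts)
    method = "ivw_fixed"
    if n >= random_effects_min_snps:
        method = "ivw_random"
        se *= max(1.0, math.sqrt(q / (n - 2)))
    return MREstimate.from_beta_se(
        beta, se, method=method, n_snps=n, q_stat=q, q_df=q_df, q_pval=q_pval
    )


def ivw_correlated(instruments: InstrumentSet, ridge: float = 0.0) -> MREstimate:
    """Generalized IVW for LD-correlated instruments.

    With x the exposure betas, y the outcome betas and Omega = S rho S
    (S the diagonal of outcome SEs, rho the signed correlation matrix on the
    harmonized alleles), the estimate is the GLS solution
    beta = (x' Omega^-1 x)^-1 x' Omega^-1 y with
    se = sqrt((x' Omega^-1 x)^-1), computed via a Cholesky solve.
    """
    if instruments.mode != "all_correlated":
        raise EstimationError("ivw_correlated requires mode=all_correlated")
    insts = instruments.instruments
    x = np.array([i.beta_exposure for i in insts])
    y = np.array([i.beta_outcome for i in insts])
    s = np.array([i.se_outcome for i in insts])
    rho = instruments.correlation.r
    omega = rho * np.outer(s, s)
    if ridge > 0:
        omega = omega + ridge * np.diag(s**2)
    try:
        cho = linalg.cho_factor(omega)
        oinv_x = linalg.cho_solve(cho, x)
        oinv_y = linalg.cho_solve(cho, y)
    except linalg.LinAlgError:
        raise EstimationError(
            "correlation-weighted system is singular; consider the "
            "estimator.ridge config option or pruning duplicate SNPs"
        ) from None
    xox = float(x @ oinv_x)
    if xox <= 0 or not math.isfinite(xox):
        raise EstimationError(
            "correlation-weighted system is singular; consider the "
            "estimator.ridge config option or pruning duplicate SNPs"
        )
    beta = float(x @ oinv_y) / xox
    se = 1.0 / math.sqrt(xox)
    q = q_df = q_pval = None
    if len(insts) >= 2:
        # heterogeneity about the GLS fit, on the same generalized metric
        resid = y - beta * x
        q = float(resid @ linalg.cho_solve(cho, resid))
        q_df = len(insts) - 1
        q_pval = float(stats.chi2.sf(q, q_df))
    return MREstimate.from_beta_se(
        beta,
        se,
        method="ivw_correlated",
        n_snps=len(insts),
        q_stat=q,
        q_df=q_df,
        q_pval=q_pval,
    )


def estimate_from_or_ci(
    or_value: float, ci_low: float, ci_high: float, method: str = "reported"
) -> MREstimate:
    """Reconstruct an estimate from a printed OR and 95% CI.

    The log-scale SE is recovered as (ln ci_high - ln ci_low)/(2 * z_0.975);
    the p-value follows from the normal z-statistic of the log OR. Useful for
    difference tests and p-value checks against published tables.
    """
    if not (0 < ci_low <= or_value <= ci_high):
        raise EstimationError("require 0 < ci_low <= OR <= ci_high")
    se = (math.log(ci_high) - math.log(ci_low)) / (2.0 * Z_95)
    return MREstimate.from_beta_se(math.log(or_value), se, method=method, n_snps=1)
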