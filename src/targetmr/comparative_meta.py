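"""Cross-stratum synthesis: meta-analysis, difference tests, multiplicity.

Stratum estimates (e.g. Europeans and East Asians for the same outcome) are
pooled by fixed-effect inverse-variance weighting unless Cochran's Q signals
heterogeneity, in which case DerSimonian-Laird random effects are used.
Differences between two strata are tested with a two-sample z on the log-OR
scale, and the Bonferroni threshold annotates each p-value as significant,
nominal or null.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import EstimationError
from .types import MREstimate


@dataclass
class MetaResult:
    pooled: MREstimate
    model: str  # "fixed" | "random"
    q_stat: float
    q_df: int
    q_pval: float
    inputs: list[str]


@dataclass
class DifferenceTest:
    delta: float
    se_delta: float
    z: float
    pval: float
    pair: tuple[str, str]


def meta_analyze(
    estimates: Sequence[MREstimate], het_alpha: float = 0.05
) -> MetaResult:
    """Pool estimates: fixed-effect IVW, or DerSimonian-Laird when Q p < het_alpha."""
    if len(estimates) < 2:
        raise EstimationError("meta-analysis requires at least two estimates")
    b = np.array([e.beta for e in estimates])
    v = np.array([e.se**2 for e in estimates])
    w = 1.0 / v
    beta_fixed = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - beta_fixed) ** 2))
    df = len(estimates) - 1
    q_pval = float(stats.chi2.sf(q, df))

    if q_pval < het_alpha:
        model = "random"
        # DerSimonian-Laird moment estimator, closed form
        tau2 = max(0.0, (q - df) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
        w_star = 1.0 / (v + tau2)
        beta = float(np.sum(w_star * b) / np.sum(w_star))
        se = float(1.0 / math.sqrt(np.sum(w_star)))
    else:
        model = "fixed"
        beta = beta_fixed
        se = float(1.0 / math.sqrt(np.sum(w)))

    pooled = MREstimate.from_beta_se(
        beta,
        se,
        method=f"meta_{model}",
        n_snps=max(e.n_snps for e in estimates),
        q_stat=q,
        q_df=df,
        q_pval=q_pval,
        outcome=estimates[0].outcome,
        stratum="+".join(e.stratum for e in estimates),
    )
    return MetaResult(
        pooled=pooled,
        model=model,
        q_stat=q,
        q_df=df,
        q_pval=q_pval,
        inputs=[e.stratum for e in estimates],
    )


def difference_test(e1: MREstimate, e2: MREstimate) -> DifferenceTest:
    """Two-sample z-test for a difference between two independent stratum estimates."""
    delta = e1.beta - e2.beta
    se_delta = math.sqrt(e1.se**2 + e2.se**2)
    z = delta / se_delta
    return DifferenceTest(
        delta=delta,
        se_delta=se_delta,
        z=z,
        pval=float(2.0 * stats.norm.sf(abs(z))),
        pair=(e1.stratum, e2.stratum),
    )


def bonferroni_threshold(alpha: float, n_phenotypes: int) -> float:
    """Per-test threshold controlling the family-wise error at ``alpha``."""
    if n_phenotypes < 1:
        raise EstimationError("n_phenotypes must be >= 1")
    return alpha / n_phenotypes


def annotate_significance(pval: float, alpha: float, corrected: float) -> str:
    """Classify a p-value as ``significant`` / ``nominal`` / ``null``.

    ``significant`` means below the Bonferroni-corrected threshold;
    ``nominal`` below the uncorrected alpha only.
    """
    if pval < corrected:
        return "significant"
    if pval < alpha:
        return "nominal"
    return "null"
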