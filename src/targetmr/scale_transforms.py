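"""Scale conversions for binary-outcome GWAS and reporting conventions.

Linear-model coefficients on a 0/1 outcome are converted to approximate log
odds ratios by dividing by k(1-k), where k is the case fraction; the z-score
(and hence the p-value) is preserved exactly. Final estimates are reported
per SD *decrease* in the exposure, the direction of pharmacological
inhibition, by negating the log-OR and mirroring the CI.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

from .exceptions import ValidationError
from .types import AssociationRecord, MREstimate


@dataclass
class ScaleContext:
    """Case fraction and optional per-population exposure SD (display only)."""

    k: float
    sd_ldl: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.k < 1.0:
            raise ValidationError(f"case fraction k must be in (0,1), got {self.k}")


def linear_to_log_or(
    beta_linear: float, se_linear: float, ctx: ScaleContext
) -> tuple[float, float]:
    """Convert a linear-probability coefficient and SE to the log-OR scale.

    Both are divided by k(1-k), so beta/se is unchanged.
    """
    if se_linear <= 0:
        raise ValidationError(f"se_linear must be > 0, got {se_linear}")
    denom = ctx.k * (1.0 - ctx.k)
    return beta_linear / denom, se_linear / denom


def transform_linear_records(
    records: Sequence[AssociationRecord], ctx: Optional[ScaleContext] = None
) -> list[AssociationRecord]:
    """Return records with any linear-scale rows converted to log_or.

    When ``ctx`` is None the case fraction is taken per record from
    n_cases/n; records already on another scale pass through unchanged.
    """
    out = []
    for rec in records:
        if rec.scale != "linear":
            out.append(rec)
            continue
        if ctx is not None:
            k_ctx = ctx
        else:
            if rec.n_cases is None or rec.n is None or rec.n == 0:
                raise ValidationError(
                    f"{rec.snp_id}: case fraction unavailable (need n_cases and n)"
                )
            k_ctx = ScaleContext(k=rec.n_cases / rec.n)
        beta, se = linear_to_log_or(rec.beta, rec.se, k_ctx)
        out.append(replace(rec, beta=beta, se=se, scale="log_or"))
    return out


def to_per_sd_decrease(estimate: MREstimate) -> MREstimate:
    """Flip an estimate from per-SD-increase to per-SD-decrease of the exposure.

    Log-OR is negated and the CI endpoints are swapped and negated; SE and
    p-value are untouched. Applying the function twice is the identity.
    """
    return replace(
        estimate,
        beta=-estimate.beta,
        ci_low=-estimate.ci_high,
        ci_high=-estimate.ci_low,
    )
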