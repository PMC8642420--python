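"""Core domain types shared across the package.

These are plain dataclasses: one SNP-trait association (:class:`AssociationRecord`),
a signed LD correlation matrix (:class:`CorrelationMatrix`), an exposure/outcome
pair on a shared effect-allele convention (:class:`HarmonizedInstrument`), a
causal estimate (:class:`MREstimate`) and the instrument container
(:class:`InstrumentSet`) the estimators consume.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .exceptions import ValidationError

VALID_ALLELES = frozenset("ACGT")
VALID_SCALES = frozenset({"sd", "log_or", "linear"})

#: two-sided 97.5% normal quantile used for all 95% confidence intervals
Z_95 = float(stats.norm.ppf(0.975))

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(allele: str) -> str:
    """Strand complement of a single-base allele."""
    return _COMPLEMENT[allele]


def is_palindromic(a1: str, a2: str) -> bool:
    """True for A/T and C/G variants, whose strand cannot be resolved from alleles."""
    return {a1, a2} in ({"A", "T"}, {"C", "G"})


def two_sided_p(beta: float, se: float) -> float:
    """Two-sided normal p-value for beta/se, floored at 1e-300 against underflow."""
    if se <= 0:
        raise ValidationError(f"standard error must be positive, got {se}")
    return max(float(2.0 * stats.norm.sf(abs(beta) / se)), 1e-300)


@dataclass
class AssociationRecord:
    """One SNP's association with one trait.

    ``beta``/``se`` units depend on ``scale``: SD units of the exposure
    (``sd``), log odds ratio (``log_or``), or linear-probability units from a
    linear model fit to a 0/1 outcome (``linear``).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: Optional[float] = None
    pval: Optional[float] = None
    n: Optional[int] = None
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    scale: str = "sd"

    def validate(self) -> "AssociationRecord":
        if not self.snp_id:
            raise ValidationError("snp_id must be a nonempty string")
        for name in ("effect_allele", "other_allele"):
            a = getattr(self, name)
            if a not in VALID_ALLELES:
                raise ValidationError(
                    f"{self.snp_id}: {name}={a!r} is not one of A/C/G/T"
                )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele are equal")
        if not (math.isfinite(self.beta) and math.isfinite(self.se)):
            raise ValidationError(f"{self.snp_id}: non-finite beta or se")
        if self.se <= 0:
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            raise ValidationError(f"{self.snp_id}: eaf must be in (0,1), got {self.eaf}")
        if self.pval is not None and not (0.0 < self.pval <= 1.0):
            raise ValidationError(f"{self.snp_id}: pval must be in (0,1], got {self.pval}")
        if self.n is not None and self.n <= 0:
            raise ValidationError(f"{self.snp_id}: n must be positive")
        for name in ("n_cases", "n_controls"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{self.snp_id}: {name} must be nonnegative")
        if self.scale not in VALID_SCALES:
            raise ValidationError(
                f"{self.snp_id}: scale={self.scale!r} not in {sorted(VALID_SCALES)}"
            )
        if (
            self.scale == "linear"
            and self.n is not None
            and self.n_cases is not None
            and self.n_controls is not None
            and self.n_cases + self.n_controls != self.n
        ):
            raise ValidationError(
                f"{self.snp_id}: linear-scale record requires n_cases + n_controls == n"
            )
        return self

    @property
    def z(self) -> float:
        return self.beta / self.se

    def p_or_computed(self) -> float:
        """The stored p-value, or the normal two-sided p from beta/se."""
        return self.pval if self.pval is not None else two_sided_p(self.beta, self.se)


@dataclass
class CorrelationMatrix:
    """Signed SNP x SNP allele-dosage correlation matrix (r, not r^2)."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)

    def validate(self, psd_tol: float = 1e-8) -> "CorrelationMatrix":
        n = len(self.snp_ids)
        if self.r.shape != (n, n):
            raise ValidationError(
                f"matrix shape {self.r.shape} does not match {n} snp_ids"
            )
        if len(set(self.snp_ids)) != n:
            raise ValidationError("duplicate snp_ids in correlation matrix")
        if not np.allclose(self.r, self.r.T, atol=1e-12, rtol=0):
            raise ValidationError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-12, rtol=0):
            raise ValidationError("correlation matrix diagonal is not 1")
        if np.any(np.abs(self.r) > 1.0 + 1e-8):
            raise ValidationError("correlation entries must lie in [-1, 1]")
        min_eig = float(np.linalg.eigvalsh(self.r).min())
        if min_eig < -psd_tol:
            raise ValidationError(
                f"correlation matrix is not positive semi-definite (min eigenvalue {min_eig:.3e})"
            )
        return self

    def index_of(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise ValidationError(f"SNP {snp_id} absent from correlation matrix") from None

    def subset(self, snp_ids: Sequence[str]) -> "CorrelationMatrix":
        """Restrict (and reorder) the matrix to the given SNPs."""
        idx = [self.index_of(s) for s in snp_ids]
        return CorrelationMatrix(list(snp_ids), self.r[np.ix_(idx, idx)].copy())

    def flip(self, snp_ids: Sequence[str]) -> "CorrelationMatrix":
        """Negate rows/columns of the given SNPs (allele-flip sign convention)."""
        sign = np.ones(len(self.snp_ids))
        for s in snp_ids:
            sign[self.index_of(s)] = -1.0
        return CorrelationMatrix(list(self.snp_ids), sign[:, None] * self.r * sign[None, :])


@dataclass
class HarmonizedInstrument:
    """Exposure and outcome betas for one SNP on a shared effect-allele convention."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: Optional[float] = None
    pval_exposure: Optional[float] = None
    flipped: bool = False
    dropped_reason: Optional[str] = None

    @property
    def dropped(self) -> bool:
        return self.dropped_reason is not None

    def validate(self) -> "HarmonizedInstrument":
        if not self.dropped and (self.se_exposure <= 0 or self.se_outcome <= 0):
            raise ValidationError(f"{self.snp_id}: standard errors must be positive")
        return self

    def exposure_p(self) -> float:
        return (
            self.pval_exposure
            if self.pval_exposure is not None
            else two_sided_p(self.beta_exposure, self.se_exposure)
        )


@dataclass
class MREstimate:
    """Causal log-OR per SD unit of exposure, with normal-theory CI and p-value."""

    beta: float
    se: float
    method: str
    n_snps: int
    ci_low: float = field(default=math.nan)
    ci_high: float = field(default=math.nan)
    pval: float = field(default=math.nan)
    q_stat: Optional[float] = None
    q_df: Optional[int] = None
    q_pval: Optional[float] = None
    stratum: str = ""
    outcome: str = ""

    @classmethod
    def from_beta_se(
        cls,
        beta: float,
        se: float,
        method: str,
        n_snps: int,
        **kwargs,
    ) -> "MREstimate":
        return cls(
            beta=beta,
            se=se,
            method=method,
            n_snps=n_snps,
            ci_low=beta - Z_95 * se,
            ci_high=beta + Z_95 * se,
            pval=two_sided_p(beta, se),
            **kwargs,
        )

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    def with_labels(self, stratum: str = "", outcome: str = "") -> "MREstimate":
        return replace(self, stratum=stratum or self.stratum, outcome=outcome or self.outcome)


@dataclass
class InstrumentSet:
    """Instruments entering an estimator, plus the LD matrix when they are correlated.

    ``mode`` is one of ``lead_snp`` (exactly one instrument), ``independent``
    (all pairwise r^2 below the pruning threshold) and ``all_correlated``
    (``correlation`` required, aligned to the instrument order).
    """

    instruments: list[HarmonizedInstrument]
    mode: str
    correlation: Optional[CorrelationMatrix] = None

    def __post_init__(self) -> None:
        if self.mode not in {"lead_snp", "independent", "all_correlated"}:
            raise ValidationError(f"unknown instrument mode {self.mode!r}")
        if self.mode == "lead_snp" and len(self.instruments) != 1:
            raise ValidationError("lead_snp mode requires exactly one instrument")
        if self.mode == "all_correlated":
            if self.correlation is None:
                raise ValidationError("all_correlated mode requires a correlation matrix")
            if self.correlation.snp_ids != [i.snp_id for i in self.instruments]:
                raise ValidationError(
                    "correlation matrix order does not match instrument order"
                )

    @property
    def snp_ids(self) -> list[str]:
        return [i.snp_id for i in self.instruments]

    def __len__(self) -> int:
        return len(self.instruments)
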