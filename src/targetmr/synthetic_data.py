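"""Synthetic two-sample GWAS summary statistics with known ground truth.

Simulation is at the summary level: estimated betas are drawn from a
multivariate normal centred on the true per-SNP effects, with covariance
combining the LD correlation structure with the analytic GWAS sampling
variance at the stated sample size, allele frequency and (for binary
outcomes) case fraction. This is exact for the assumptions the estimators
make and fast enough for thousands of replicates.

For an SD-scaled exposure, se(beta) ~ 1/sqrt(2 p (1-p) n). For a binary
outcome on the log-OR scale, se ~ 1/sqrt(2 p (1-p) n k (1-k)); a
``linear``-scale outcome multiplies both the true effect and the SE by
k(1-k), so the pipeline's linear-to-log-OR conversion must undo it.

Exposure and outcome samples are drawn independently (two-sample design, no
overlap).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .exceptions import ValidationError
from .types import AssociationRecord, CorrelationMatrix, two_sided_p

#: curated six-SNP gene-region instrument list used by the default scenario
HMGCR_SNPS = ["rs12916", "rs10066707", "rs17238484", "rs2006760", "rs2303152", "rs5909"]

# fixed non-palindromic allele pairs so harmonization is exercised but never drops
_ALLELE_PAIRS = [("T", "C"), ("A", "G"), ("T", "C"), ("A", "C"), ("T", "C"), ("A", "G")]

_DEFAULT_BETA_GX = [0.073, 0.035, 0.031, 0.028, 0.024, 0.021]
_DEFAULT_MAF = [0.39, 0.38, 0.47, 0.06, 0.11, 0.35]


def make_ld_block(
    n_snps: int, decay: float, snp_ids: Optional[Sequence[str]] = None
) -> CorrelationMatrix:
    """Autoregressive LD block: r[i,j] = decay^|i-j|; PSD by construction."""
    if n_snps < 1:
        raise ValidationError("n_snps must be >= 1")
    if not 0.0 <= decay < 1.0:
        raise ValidationError(f"decay must be in [0,1), got {decay}")
    idx = np.arange(n_snps)
    r = decay ** np.abs(idx[:, None] - idx[None, :])
    if snp_ids is None:
        snp_ids = [f"rs{i + 1}" for i in range(n_snps)]
    return CorrelationMatrix(list(snp_ids), r)


@dataclass
class SimulationScenario:
    """Full parameterization of the synthetic two-sample generator."""

    n_snps: int = 6
    ld: Union[float, CorrelationMatrix] = 0.6  # AR decay, or an explicit matrix
    beta_gx: Sequence[float] = field(default_factory=lambda: list(_DEFAULT_BETA_GX))
    maf: Sequence[float] = field(default_factory=lambda: list(_DEFAULT_MAF))
    n_exposure: int = 361_194
    n_outcome: int = 212_453
    k: float = 0.05
    theta: float = 0.0
    pleiotropy_sd: float = 0.0
    outcome_scale: str = "log_or"  # "log_or" | "linear"
    snp_ids: Optional[Sequence[str]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValidationError("n_snps must be >= 1")
        if len(self.beta_gx) != self.n_snps or len(self.maf) != self.n_snps:
            raise ValidationError("beta_gx and maf must have length n_snps")
        if any(not 0.0 < m <= 0.5 for m in self.maf):
            raise ValidationError("maf values must be in (0, 0.5]")
        if not 0.0 < self.k < 1.0:
            raise ValidationError("case fraction k must be in (0,1)")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValidationError("sample sizes must be positive")
        if self.outcome_scale not in {"log_or", "linear"}:
            raise ValidationError("outcome_scale must be log_or or linear")
        if self.pleiotropy_sd < 0:
            raise ValidationError("pleiotropy_sd must be nonnegative")
        if isinstance(self.ld, CorrelationMatrix):
            if len(self.ld.snp_ids) != self.n_snps:
                raise ValidationError("ld matrix dimension must equal n_snps")

    def resolve_ids(self) -> list[str]:
        if self.snp_ids is not None:
            return list(self.snp_ids)
        if isinstance(self.ld, CorrelationMatrix):
            return list(self.ld.snp_ids)
        if self.n_snps <= len(HMGCR_SNPS):
            return HMGCR_SNPS[: self.n_snps]
        return [f"rs{i + 1}" for i in range(self.n_snps)]

    def resolve_ld(self) -> CorrelationMatrix:
        if isinstance(self.ld, CorrelationMatrix):
            return self.ld
        return make_ld_block(self.n_snps, float(self.ld), self.resolve_ids())


def hmgcr_like(**overrides) -> SimulationScenario:
    """The default six-SNP gene-region scenario: one dominant lead SNP, AR LD,
    exposure GWAS of 361,194 and a binary outcome GWAS of 212,453 at case
    fraction 0.05."""
    return SimulationScenario(**overrides)


def _exposure_se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _outcome_se_log_or(maf: np.ndarray, n: int, k: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n * k * (1.0 - k))


def _draw_exposure(
    scenario: SimulationScenario, rho: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    maf = np.asarray(scenario.maf, dtype=float)
    beta_gx = np.asarray(scenario.beta_gx, dtype=float)
    se_x = _exposure_se(maf, scenario.n_exposure)
    cov_x = rho * np.outer(se_x, se_x)
    bx_hat = rng.multivariate_normal(beta_gx, cov_x, method="cholesky")
    return bx_hat, se_x


def _draw_outcome(
    scenario: SimulationScenario, rho: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    maf = np.asarray(scenario.maf, dtype=float)
    beta_gx = np.asarray(scenario.beta_gx, dtype=float)
    pleio = (
        rng.normal(0.0, scenario.pleiotropy_sd, size=scenario.n_snps)
        if scenario.pleiotropy_sd > 0
        else np.zeros(scenario.n_snps)
    )
    mean_y = scenario.theta * beta_gx + pleio
    se_y = _outcome_se_log_or(maf, scenario.n_outcome, scenario.k)
    if scenario.outcome_scale == "linear":
        kk = scenario.k * (1.0 - scenario.k)
        mean_y = mean_y * kk
        se_y = se_y * kk
    cov_y = rho * np.outer(se_y, se_y)
    by_hat = rng.multivariate_normal(mean_y, cov_y, method="cholesky")
    return by_hat, se_y


def _exposure_records(
    scenario: SimulationScenario, ids, bx_hat, se_x
) -> list[AssociationRecord]:
    records = []
    for j in range(scenario.n_snps):
        ea, oa = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        records.append(
            AssociationRecord(
                snp_id=ids[j],
                effect_allele=ea,
                other_allele=oa,
                beta=float(bx_hat[j]),
                se=float(se_x[j]),
                eaf=float(scenario.maf[j]),
                pval=two_sided_p(float(bx_hat[j]), float(se_x[j])),
                n=scenario.n_exposure,
                scale="sd",
            ).validate()
        )
    return records


def _outcome_records(
    scenario: SimulationScenario, ids, by_hat, se_y
) -> list[AssociationRecord]:
    n_cases = int(round(scenario.k * scenario.n_outcome))
    n_controls = scenario.n_outcome - n_cases
    records = []
    for j in range(scenario.n_snps):
        ea, oa = _ALLELE_PAIRS[j % len(_ALLELE_PAIRS)]
        records.append(
            AssociationRecord(
                snp_id=ids[j],
                effect_allele=ea,
                other_allele=oa,
                beta=float(by_hat[j]),
                se=float(se_y[j]),
                eaf=float(scenario.maf[j]),
                pval=two_sided_p(float(by_hat[j]), float(se_y[j])),
                n=scenario.n_outcome,
                n_cases=n_cases,
                n_controls=n_controls,
                scale=scenario.outcome_scale,
            ).validate()
        )
    return records


def simulate_two_sample(
    scenario: SimulationScenario, rng: Optional[np.random.Generator] = None
) -> tuple[list[AssociationRecord], list[AssociationRecord], CorrelationMatrix]:
    """Draw one replicate of exposure and outcome summary statistics.

    Returns (exposure records on the SD scale, outcome records on
    ``scenario.outcome_scale``, the LD correlation matrix). Fully
    deterministic given the scenario seed (or the supplied generator).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    ids = scenario.resolve_ids()
    corr = scenario.resolve_ld()
    bx_hat, se_x = _draw_exposure(scenario, corr.r, rng)
    by_hat, se_y = _draw_outcome(scenario, corr.r, rng)
    return (
        _exposure_records(scenario, ids, bx_hat, se_x),
        _outcome_records(scenario, ids, by_hat, se_y),
        corr,
    )


def simulate_outcome_grid(
    scenario: SimulationScenario,
    thetas: Mapping[str, float],
    seed: Optional[int] = None,
) -> tuple[list[AssociationRecord], dict[str, list[AssociationRecord]], CorrelationMatrix]:
    """One exposure GWAS shared across a grid of outcome GWAS.

    ``thetas`` maps outcome name to its true causal log-OR; each outcome
    sample is drawn independently of the others and of the exposure sample
    (two-sample design throughout). Returns
    (exposure records, {outcome: records}, LD matrix).
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    ids = scenario.resolve_ids()
    corr = scenario.resolve_ld()
    bx_hat, se_x = _draw_exposure(scenario, corr.r, rng)
    exposure = _exposure_records(scenario, ids, bx_hat, se_x)
    outcomes = {}
    for name, theta in thetas.items():
        sub = replace(scenario, theta=float(theta))
        by_hat, se_y = _draw_outcome(sub, corr.r, rng)
        outcomes[name] = _outcome_records(sub, ids, by_hat, se_y)
    return exposure, outcomes, corr
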