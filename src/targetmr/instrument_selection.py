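"""Instrument selection within the target gene region.

LD pruning to approximate independence, the mean-chi-square instrument
strength statistic, and an advisory screen of instruments against confounder
GWAS.
"""
from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .exceptions import EstimationError, ValidationError
from .types import (
    AssociationRecord,
    CorrelationMatrix,
    HarmonizedInstrument,
    InstrumentSet,
)

Record = Union[AssociationRecord, HarmonizedInstrument]

GENOME_WIDE_ALPHA = 5e-8


def _exposure_beta_se(rec: Record) -> tuple[float, float]:
    if isinstance(rec, HarmonizedInstrument):
        return rec.beta_exposure, rec.se_exposure
    return rec.beta, rec.se


def _exposure_p(rec: Record) -> float:
    if isinstance(rec, HarmonizedInstrument):
        return rec.exposure_p()
    return rec.p_or_computed()


def _rank_key(rec: Record) -> tuple:
    # ascending p, ties by larger |beta|, then lexicographic rsID: a total
    # order, so pruning is invariant to input row order
    beta, _ = _exposure_beta_se(rec)
    return (_exposure_p(rec), -abs(beta), rec.snp_id)


def ld_prune(
    records: Sequence[Record],
    corr: CorrelationMatrix,
    r2_threshold: float = 0.01,
    top: Optional[int] = None,
) -> InstrumentSet:
    """Greedy LD pruning: keep the strongest SNPs with pairwise r^2 below threshold.

    Candidates are ranked by ascending exposure p-value (ties broken by larger
    |beta|, then rsID) and accepted iff their squared correlation with every
    previously accepted SNP is below ``r2_threshold``. With ``top=1`` the
    single best surviving SNP is returned in ``lead_snp`` mode.
    """
    if not 0.0 < r2_threshold < 1.0:
        raise ValidationError(f"r2_threshold must be in (0,1), got {r2_threshold}")
    if not records:
        raise EstimationError("no records to prune")
    for rec in records:
        corr.index_of(rec.snp_id)  # raises naming the missing SNP

    selected: list[Record] = []
    for rec in sorted(records, key=_rank_key):
        i = corr.index_of(rec.snp_id)
        if all(
            corr.r[i, corr.index_of(s.snp_id)] ** 2 < r2_threshold for s in selected
        ):
            selected.append(rec)
        if top is not None and len(selected) >= top:
            break

    mode = "lead_snp" if (top == 1 or (top is None and len(selected) == 1)) else "independent"
    if top == 1:
        selected = selected[:1]
    return InstrumentSet(instruments=list(selected), mode=mode)


def f_statistic(records: Sequence[Record]) -> float:
    """Instrument strength: mean over SNPs of (beta/se)^2 on the exposure scale."""
    if not records:
        raise EstimationError("f_statistic requires at least one record")
    total = 0.0
    for rec in records:
        beta, se = _exposure_beta_se(rec)
        if se == 0:
            raise ValidationError(f"{rec.snp_id}: se is zero")
        total += (beta / se) ** 2
    return total / len(records)


def confounder_screen(
    instruments: InstrumentSet,
    confounder_stats: Mapping[str, Sequence[AssociationRecord]],
    alpha: float = GENOME_WIDE_ALPHA,
) -> pd.DataFrame:
    """Flag instruments associated with any confounder at p < alpha.

    Advisory only: the pipeline reports flags rather than dropping SNPs.
    Instruments missing from a confounder file get status ``untested``.
    Returns one row per instrument x confounder with columns
    ``snp_id, confounder, pval, status`` where status is ``flagged``/``ok``/
    ``untested``.
    """
    rows = []
    for inst in instruments.instruments:
        for name, stats_list in confounder_stats.items():
            match = next((r for r in stats_list if r.snp_id == inst.snp_id), None)
            if match is None:
                rows.append((inst.snp_id, name, None, "untested"))
                continue
            p = match.p_or_computed()
            rows.append((inst.snp_id, name, p, "flagged" if p < alpha else "ok"))
    return pd.DataFrame(rows, columns=["snp_id", "confounder", "pval", "status"])
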