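"""Reading, writing and harmonizing GWAS summary statistics and LD matrices.

File dialects
-------------
Summary statistics are header-bearing TSV or CSV. Column names are mapped
through :data:`COLUMN_ALIASES`; at minimum ``snp_id``, ``effect_allele``,
``other_allele``, ``beta`` and ``se`` (or aliases) must be present. LD
matrices are square TSVs whose first row and first column carry rsIDs and
whose cells are signed correlations r. All output is UTF-8 with POSIX
newlines.
"""
from __future__ import annotations

import csv
import math
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, HarmonizationError, ValidationError
from .types import (
    AssociationRecord,
    CorrelationMatrix,
    HarmonizedInstrument,
    MREstimate,
    complement,
    is_palindromic,
)

#: canonical name -> accepted aliases (all matched case-insensitively)
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "snp_id": ("snp_id", "snp", "rsid", "variant_id"),
    "effect_allele": ("effect_allele", "a1", "ea"),
    "other_allele": ("other_allele", "a2", "nea", "oa"),
    "beta": ("beta", "b"),
    "se": ("se", "standard_error"),
    "pval": ("pval", "p", "p_value"),
    "eaf": ("eaf", "af", "freq"),
    "n": ("n", "n_total", "sample_size"),
    "n_cases": ("n_cases", "ncase", "cases"),
    "n_controls": ("n_controls", "ncontrol", "controls"),
}

_MANDATORY = ("snp_id", "effect_allele", "other_allele", "beta", "se")

#: palindromic SNPs with min(eaf, 1-eaf) at or above this are dropped
PALINDROMIC_EAF_THRESHOLD = 0.42


def _canonical_columns(columns: Iterable[str]) -> dict[str, str]:
    """Map raw header names to canonical names via the alias table."""
    lookup = {
        alias: canonical
        for canonical, aliases in COLUMN_ALIASES.items()
        for alias in aliases
    }
    mapping: dict[str, str] = {}
    for col in columns:
        canonical = lookup.get(col.strip().lower())
        if canonical is not None and canonical not in mapping.values():
            mapping[col] = canonical
    return mapping


def _sniff_sep(path: str) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_sumstats(path: str, scale: str = "sd") -> list[AssociationRecord]:
    """Read a summary-statistics file into validated records, preserving row order.

    Parameters
    ----------
    path:
        TSV or CSV file with a header row.
    scale:
        Scale flag stamped onto every record (``sd``, ``log_or`` or ``linear``).
    """
    df = pd.read_csv(path, sep=_sniff_sep(path), float_precision="round_trip")
    mapping = _canonical_columns(df.columns)
    df = df.rename(columns=mapping)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing mandatory column(s) {', '.join(missing)} "
            f"(known aliases: {COLUMN_ALIASES})"
        )

    bad = df.index[~(np.isfinite(df["beta"]) & np.isfinite(df["se"]))].tolist()
    if bad:
        raise FormatError(f"{path}: non-finite beta/se in rows {bad}")
    dups = df["snp_id"][df["snp_id"].duplicated()].unique().tolist()
    if dups:
        raise FormatError(f"{path}: duplicate snp_id(s): {', '.join(map(str, dups))}")

    def _opt_float(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        return None if pd.isna(v) else float(v)

    def _opt_int(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        return None if pd.isna(v) else int(v)

    records = []
    for _, row in df.iterrows():
        rec = AssociationRecord(
            snp_id=str(row["snp_id"]),
            effect_allele=str(row["effect_allele"]).upper(),
            other_allele=str(row["other_allele"]).upper(),
            beta=float(row["beta"]),
            se=float(row["se"]),
            eaf=_opt_float(row, "eaf"),
            pval=_opt_float(row, "pval"),
            n=_opt_int(row, "n"),
            n_cases=_opt_int(row, "n_cases"),
            n_controls=_opt_int(row, "n_controls"),
            scale=scale,
        )
        try:
            rec.validate()
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from None
        records.append(rec)
    return records


def write_sumstats(records: Sequence[AssociationRecord], path: str) -> None:
    """Write records as TSV with canonical headers; floats keep full precision."""
    cols = (
        "snp_id effect_allele other_allele eaf beta se pval n n_cases n_controls".split()
    )

    def _fmt(v):
        if v is None:
            return "NA"
        if isinstance(v, float):
            return repr(v)  # shortest exact round-trip form
        return str(v)

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            fh.write("\t".join(_fmt(getattr(r, c)) for c in cols) + "\n")


def read_correlation_matrix(path: str) -> CorrelationMatrix:
    """Read a square signed LD matrix; symmetrize and PSD-repair within tolerance.

    Asymmetry up to 1e-8 is averaged away; a smallest eigenvalue in
    (-1e-8, 0) is clipped to zero and the diagonal renormalized to 1. Larger
    violations are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if row_ids != col_ids:
        raise FormatError(
            f"{path}: rsID mismatch between header row and first column"
        )
    r = df.to_numpy(dtype=float)
    if np.max(np.abs(r - r.T)) > 1e-8:
        raise FormatError(f"{path}: matrix asymmetry exceeds 1e-8")
    if np.any(np.abs(r) > 1.0 + 1e-8):
        raise FormatError(f"{path}: |r| > 1 entries present")
    if np.max(np.abs(np.diag(r) - 1.0)) > 1e-8:
        raise FormatError(f"{path}: diagonal entries differ from 1")
    r = (r + r.T) / 2.0
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    r = _psd_repair(r)
    return CorrelationMatrix(row_ids, r).validate()


def _psd_repair(r: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Clip a barely-negative spectrum to zero; reject genuinely indefinite input."""
    eigval, eigvec = np.linalg.eigh(r)
    if eigval.min() >= 0:
        return r
    if eigval.min() < -tol:
        raise FormatError(
            f"correlation matrix is not positive semi-definite "
            f"(min eigenvalue {eigval.min():.3e})"
        )
    repaired = (eigvec * np.clip(eigval, 0.0, None)) @ eigvec.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    repaired = (repaired + repaired.T) / 2.0
    np.fill_diagonal(repaired, 1.0)
    return repaired


def write_correlation_matrix(corr: CorrelationMatrix, path: str) -> None:
    """Write the LD-matrix dialect read by :func:`read_correlation_matrix`."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("snp_id\t" + "\t".join(corr.snp_ids) + "\n")
        for sid, row in zip(corr.snp_ids, corr.r):
            fh.write(sid + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")


def harmonize(
    exposure: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    palindromic_eaf_threshold: float = PALINDROMIC_EAF_THRESHOLD,
) -> list[HarmonizedInstrument]:
    """Align outcome records to the exposure effect-allele convention.

    For each SNP shared between the two sets the outcome alleles are matched
    directly, as a swap (beta negated), or via strand complement. Palindromic
    variants are frequency-aligned when both frequencies are informative
    (min(eaf, 1-eaf) below ``palindromic_eaf_threshold``) and dropped
    otherwise. Unresolvable allele sets are kept with a ``dropped_reason``.
    """
    out_by_id = {r.snp_id: r for r in outcome}
    shared = [r for r in exposure if r.snp_id in out_by_id]
    if not shared:
        raise HarmonizationError("no shared instruments between exposure and outcome")

    result: list[HarmonizedInstrument] = []
    for exp in shared:
        out = out_by_id[exp.snp_id]
        result.append(_harmonize_pair(exp, out, palindromic_eaf_threshold))
    return result


def _harmonize_pair(
    exp: AssociationRecord, out: AssociationRecord, pal_threshold: float
) -> HarmonizedInstrument:
    def build(flipped: bool, dropped_reason: Optional[str] = None) -> HarmonizedInstrument:
        return HarmonizedInstrument(
            snp_id=exp.snp_id,
            effect_allele=exp.effect_allele,
            other_allele=exp.other_allele,
            beta_exposure=exp.beta,
            se_exposure=exp.se,
            beta_outcome=-out.beta if flipped else out.beta,
            se_outcome=out.se,
            eaf=exp.eaf,
            pval_exposure=exp.pval,
            flipped=flipped,
            dropped_reason=dropped_reason,
        ).validate()

    ea, oa = exp.effect_allele, exp.other_allele
    pair = (out.effect_allele, out.other_allele)

    if is_palindromic(ea, oa):
        if pair not in ((ea, oa), (oa, ea)):
            return build(False, dropped_reason="allele mismatch")
        freqs = (exp.eaf, out.eaf)
        if any(f is None for f in freqs) or any(
            min(f, 1.0 - f) >= pal_threshold for f in freqs
        ):
            return build(False, dropped_reason="palindromic, ambiguous frequency")
        # Orient by frequency: effect alleles agree iff eafs fall on the same
        # side of 0.5. The outcome's printed alleles are unreliable for
        # palindromes (possible strand flip), so they are ignored here.
        flipped = (exp.eaf - 0.5) * (out.eaf - 0.5) < 0
        return build(flipped)

    if pair == (ea, oa):
        return build(False)
    if pair == (oa, ea):
        return build(True)
    comp = (complement(out.effect_allele), complement(out.other_allele))
    if comp == (ea, oa):
        return build(False)
    if comp == (oa, ea):
        return build(True)
    return build(False, dropped_reason="allele mismatch")


def align_correlation(
    corr: CorrelationMatrix, instruments: Sequence[HarmonizedInstrument]
) -> CorrelationMatrix:
    """Subset the LD matrix to the instruments and negate rows of flipped SNPs.

    The returned matrix is expressed on the harmonized effect-allele dosages,
    which is the convention the correlated IVW requires.
    """
    kept = [i for i in instruments if not i.dropped]
    sub = corr.subset([i.snp_id for i in kept])
    flipped = [i.snp_id for i in kept if i.flipped]
    return sub.flip(flipped) if flipped else sub


def write_results(estimates: Sequence[MREstimate], path: str) -> None:
    """Write the results table: ORs/CIs to 2 decimals, p-values to 3 decimals."""
    cols = [
        "outcome",
        "stratum",
        "method",
        "n_snps",
        "or",
        "ci_low",
        "ci_high",
        "pval",
        "q_pval",
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(cols)
        for e in estimates:
            writer.writerow(
                [
                    e.outcome,
                    e.stratum,
                    e.method,
                    e.n_snps,
                    f"{math.exp(e.beta):.2f}",
                    f"{math.exp(e.ci_low):.2f}",
                    f"{math.exp(e.ci_high):.2f}",
                    f"{e.pval:.3f}",
                    "NA" if e.q_pval is None else f"{e.q_pval:.3f}",
                ]
            )
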