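"""Config-driven orchestration of the full analysis grid.

A run configuration names exposure summary statistics per stratum, outcome
summary statistics per outcome per stratum, an LD matrix, the instrument
mode and thresholds. ``run_pipeline`` executes every outcome x stratum cell
independently (a failure in one cell never aborts the others), then derives
sex- and ancestry-difference tests and cross-ancestry meta-analyses, and
writes the results table, a full-precision table, diagnostics and a log.

Stratum labels follow ``<population>_<sex>`` with sex one of
``overall``/``men``/``women`` (e.g. ``EUR_overall``, ``EAS_women``).
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from typing import Any, Optional

import pandas as pd
import yaml

from . import sumstats_io
from .comparative_meta import (
    annotate_significance,
    bonferroni_threshold,
    difference_test,
    meta_analyze,
)
from .exceptions import FormatError, TargetMRError
from .instrument_selection import confounder_screen, f_statistic, ld_prune
from .mr_estimators import ivw, ivw_correlated
from .scale_transforms import to_per_sd_decrease, transform_linear_records
from .types import InstrumentSet, MREstimate


@dataclass
class RunConfig:
    """Parsed and validated run configuration."""

    exposures: dict[str, str]  # stratum -> path
    outcomes: dict[str, dict[str, dict]]  # outcome -> stratum -> {path, scale, ...}
    ld_matrix: str
    output_dir: str
    mode: str = "lead_snp"
    r2_threshold: float = 0.01
    het_alpha: float = 0.05
    alpha: float = 0.05
    n_phenotypes: int = 10
    confounder_alpha: float = 5e-8
    confounder_files: dict[str, str] = field(default_factory=dict)
    ridge: float = 0.0
    seed: int = 0

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        base = os.path.dirname(os.path.abspath(path))
        return cls.from_dict(raw, base_dir=base)

    @classmethod
    def from_dict(cls, raw: dict[str, Any], base_dir: str = ".") -> "RunConfig":
        def _resolve(p: str) -> str:
            return p if os.path.isabs(p) else os.path.join(base_dir, p)

        instruments = raw.get("instruments", {})
        meta = raw.get("meta", {})
        correction = raw.get("correction", {})
        confounders = raw.get("confounders", {})
        estimator = raw.get("estimator", {})
        outcomes: dict[str, dict[str, dict]] = {}
        for outcome, strata in raw.get("outcomes", {}).items():
            outcomes[outcome] = {}
            for stratum, spec in strata.items():
                if isinstance(spec, str):
                    spec = {"path": spec, "scale": "log_or"}
                spec = dict(spec)
                spec["path"] = _resolve(spec["path"])
                spec.setdefault("scale", "log_or")
                outcomes[outcome][stratum] = spec
        return cls(
            exposures={
                s: _resolve(p) for s, p in raw.get("exposures", {}).items()
            },
            outcomes=outcomes,
            ld_matrix=_resolve(raw["ld_matrix"]),
            output_dir=_resolve(raw.get("output_dir", "targetmr_out")),
            mode=instruments.get("mode", "lead_snp"),
            r2_threshold=float(instruments.get("r2_threshold", 0.01)),
            het_alpha=float(meta.get("het_alpha", 0.05)),
            alpha=float(correction.get("alpha", 0.05)),
            n_phenotypes=int(correction.get("n_phenotypes", 10)),
            confounder_alpha=float(confounders.get("alpha", 5e-8)),
            confounder_files={
                name: _resolve(p)
                for name, p in confounders.get("files", {}).items()
            },
            ridge=float(estimator.get("ridge", 0.0)),
            seed=int(raw.get("seed", 0)),
        )


def _population(stratum: str) -> str:
    return stratum.rsplit("_", 1)[0]


def _sex(stratum: str) -> str:
    return stratum.rsplit("_", 1)[1] if "_" in stratum else "overall"


def _estimate_cell(
    config: RunConfig,
    exposure_path: str,
    outcome_spec: dict,
    corr,
    log: list[str],
) -> tuple[MREstimate, InstrumentSet]:
    exposure = sumstats_io.read_sumstats(exposure_path, scale="sd")
    outcome = sumstats_io.read_sumstats(
        outcome_spec["path"], scale=outcome_spec.get("scale", "log_or")
    )
    outcome = transform_linear_records(outcome)
    harmonized = sumstats_io.harmonize(exposure, outcome)
    kept = [h for h in harmonized if not h.dropped]
    for h in harmonized:
        if h.dropped:
            log.append(f"  dropped {h.snp_id}: {h.dropped_reason}")
    if not kept:
        raise TargetMRError("all instruments dropped during harmonization")
    aligned = sumstats_io.align_correlation(corr, kept)

    if config.mode == "all_correlated":
        iset = InstrumentSet(
            instruments=kept, mode="all_correlated", correlation=aligned
        )
        est = ivw_correlated(iset, ridge=config.ridge)
    else:
        top = 1 if config.mode == "lead_snp" else None
        iset = ld_prune(kept, aligned, config.r2_threshold, top=top)
        est = ivw(iset)
    log.append(
        f"  mode={iset.mode} n_snps={est.n_snps} method={est.method}"
    )
    # reporting convention: per SD decrease in the exposure
    return to_per_sd_decrease(est), iset


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Execute the analysis grid and write all output tables.

    Returns a bundle of DataFrames: ``results`` (one row per outcome x
    stratum), ``differences`` (sex and ancestry z-tests), ``meta``
    (cross-ancestry pooling) and ``diagnostics`` (F-statistics, instrument
    counts, confounder flags).
    """
    os.makedirs(config.output_dir, exist_ok=True)
    corr = sumstats_io.read_correlation_matrix(config.ld_matrix)
    corrected = bonferroni_threshold(config.alpha, config.n_phenotypes)
    log: list[str] = [
        f"seed={config.seed} mode={config.mode} r2_threshold={config.r2_threshold}",
        f"alpha={config.alpha} corrected={corrected:.6g} het_alpha={config.het_alpha}",
    ]

    confounder_stats = {
        name: sumstats_io.read_sumstats(path)
        for name, path in config.confounder_files.items()
    }

    estimates: dict[tuple[str, str], MREstimate] = {}
    rows: list[dict] = []
    diag_rows: list[dict] = []
    estimate_list: list[MREstimate] = []

    for outcome, strata in config.outcomes.items():
        for stratum, spec in strata.items():
            log.append(f"cell {outcome} x {stratum}:")
            if stratum not in config.exposures:
                rows.append(
                    {"outcome": outcome, "stratum": stratum,
                     "status": "skipped: no exposure file for stratum"}
                )
                log.append("  skipped: no exposure file for stratum")
                continue
            if not os.path.exists(spec["path"]):
                rows.append(
                    {"outcome": outcome, "stratum": stratum,
                     "status": "skipped: missing input"}
                )
                log.append(f"  skipped: missing input {spec['path']}")
                continue
            try:
                est, iset = _estimate_cell(
                    config, config.exposures[stratum], spec, corr, log
                )
            except TargetMRError as exc:
                rows.append(
                    {"outcome": outcome, "stratum": stratum,
                     "status": f"error: {exc}"}
                )
                log.append(f"  error: {exc}")
                continue
            est = est.with_labels(stratum=stratum, outcome=outcome)
            estimates[(outcome, stratum)] = est
            estimate_list.append(est)
            rows.append(
                {
                    "outcome": outcome,
                    "stratum": stratum,
                    "status": "ok",
                    "method": est.method,
                    "n_snps": est.n_snps,
                    "beta": est.beta,
                    "se": est.se,
                    "or": est.odds_ratio,
                    "ci_low": math.exp(est.ci_low),
                    "ci_high": math.exp(est.ci_high),
                    "pval": est.pval,
                    "q_stat": est.q_stat,
                    "q_pval": est.q_pval,
                    "significance": annotate_significance(
                        est.pval, config.alpha, corrected
                    ),
                }
            )
            diag = {
                "outcome": outcome,
                "stratum": stratum,
                "f_statistic": f_statistic(iset.instruments),
                "n_snps": len(iset),
                "q_stat": est.q_stat,
                "q_pval": est.q_pval,
            }
            if confounder_stats:
                flags = confounder_screen(
                    iset, confounder_stats, alpha=config.confounder_alpha
                )
                n_flagged = int((flags["status"] == "flagged").sum())
                diag["confounder_flags"] = n_flagged
                if n_flagged:
                    log.append(f"  WARNING: {n_flagged} confounder flag(s)")
            diag_rows.append(diag)

    diff_rows = _difference_rows(config, estimates)
    meta_rows = _meta_rows(config, estimates)

    results = pd.DataFrame(rows)
    differences = pd.DataFrame(diff_rows)
    meta = pd.DataFrame(meta_rows)
    diagnostics = pd.DataFrame(diag_rows)

    out = config.output_dir
    sumstats_io.write_results(estimate_list, os.path.join(out, "results.tsv"))
    _write_tsv(results, os.path.join(out, "results_full.tsv"))
    _write_tsv(differences, os.path.join(out, "differences.tsv"))
    _write_tsv(meta, os.path.join(out, "meta.tsv"))
    _write_tsv(diagnostics, os.path.join(out, "diagnostics.tsv"))
    with open(os.path.join(out, "log.txt"), "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(log) + "\n")

    return {
        "results": results,
        "differences": differences,
        "meta": meta,
        "diagnostics": diagnostics,
    }


def _difference_rows(config, estimates) -> list[dict]:
    rows = []
    for outcome, strata in config.outcomes.items():
        populations = sorted({_population(s) for s in strata})
        # sex difference within each population
        for pop in populations:
            men = estimates.get((outcome, f"{pop}_men"))
            women = estimates.get((outcome, f"{pop}_women"))
            if men and women:
                d = difference_test(men, women)
                rows.append(
                    {"outcome": outcome, "comparison": "sex",
                     "pair": f"{pop}_men vs {pop}_women",
                     "delta": d.delta, "se": d.se_delta, "z": d.z, "pval": d.pval}
                )
        # ancestry difference between overall strata
        overall = [
            (pop, estimates.get((outcome, f"{pop}_overall"))) for pop in populations
        ]
        overall = [(p, e) for p, e in overall if e is not None]
        for i in range(len(overall)):
            for j in range(i + 1, len(overall)):
                d = difference_test(overall[i][1], overall[j][1])
                rows.append(
                    {"outcome": outcome, "comparison": "ancestry",
                     "pair": f"{overall[i][0]} vs {overall[j][0]}",
                     "delta": d.delta, "se": d.se_delta, "z": d.z, "pval": d.pval}
                )
    return rows


def _meta_rows(config, estimates) -> list[dict]:
    rows = []
    for outcome, strata in config.outcomes.items():
        populations = sorted({_population(s) for s in strata})
        overall = [
            e
            for pop in populations
            if (e := estimates.get((outcome, f"{pop}_overall"))) is not None
        ]
        if len(overall) >= 2:
            m = meta_analyze(overall, het_alpha=config.het_alpha)
            rows.append(
                {
                    "outcome": outcome,
                    "inputs": "+".join(m.inputs),
                    "model": m.model,
                    "beta": m.pooled.beta,
                    "se": m.pooled.se,
                    "or": m.pooled.odds_ratio,
                    "ci_low": math.exp(m.pooled.ci_low),
                    "ci_high": math.exp(m.pooled.ci_high),
                    "pval": m.pooled.pval,
                    "q_stat": m.q_stat,
                    "q_pval": m.q_pval,
                }
            )
    return rows


def _write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", na_rep="NA")


def render_forest(results_path: str) -> str:
    """Render the results table written by ``write_results`` as fixed-width text."""
    try:
        df = pd.read_csv(results_path, sep="\t", dtype=str)
    except Exception as exc:
        raise FormatError(f"cannot parse results table {results_path}: {exc}") from None
    required = {"outcome", "stratum", "method", "n_snps", "or", "ci_low", "ci_high", "pval"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"{results_path}: missing column(s) {sorted(required - set(df.columns))}"
        )
    header = f"{'outcome':<16} {'stratum':<14} {'method':<16} {'n':>3}  {'OR (95% CI)':<22} {'p':>6}"
    lines = [header, "-" * len(header)]
    last_outcome = None
    for _, row in df.iterrows():
        outcome = row["outcome"] if row["outcome"] != last_outcome else ""
        last_outcome = row["outcome"]
        or_ci = f"{row['or']} ({row['ci_low']}, {row['ci_high']})"
        lines.append(
            f"{outcome:<16} {row['stratum']:<14} {row['method']:<16} "
            f"{row['n_snps']:>3}  {or_ci:<22} p={row['pval']}"
        )
    return "\n".join(lines) + "\n"
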