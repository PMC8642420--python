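# targetmr

Drug-target Mendelian randomization (MR) from GWAS summary statistics.
The package estimates the causal effect of genetically proxied inhibition of
a drug target — instrumented on its downstream biomarker, with effects
reported per SD *decrease* of that biomarker — on binary disease outcomes,
per stratum (ancestry × sex), with:

- **`sumstats_io`** — read/write summary statistics (TSV/CSV with a column
  alias table) and signed LD correlation matrices; harmonize exposure and
  outcome to a shared effect-allele convention (strand complements handled,
  palindromic SNPs frequency-aligned or dropped); align the LD matrix to the
  harmonized alleles.
- **`instrument_selection`** — greedy LD pruning (rank by exposure p-value,
  accept if pairwise r² below threshold), mean-χ² F-statistics, advisory
  confounder screening at genome-wide significance.
- **`scale_transforms`** — linear-regression coefficients on 0/1 outcomes
  converted to log odds ratios via division by k(1−k) (k the case
  fraction; z-scores preserved), and the per-SD-decrease reporting flip.
- **`mr_estimators`** — Wald ratio, inverse-variance-weighted (IVW)
  combination (fixed effects for ≤3 SNPs, multiplicative random effects for
  ≥4), generalized IVW for LD-correlated instruments (GLS with
  Ω = S·ρ·S via Cholesky solves), Cochran-Q heterogeneity.
- **`comparative_meta`** — cross-ancestry meta-analysis (fixed effects, or
  DerSimonian–Laird when Q signals heterogeneity), two-sample z difference
  tests between strata, Bonferroni annotation
  (significant / nominal / null).
- **`power_calc`** — instrument R² = 2β²·MAF·(1−MAF), the n/R² sample-size
  heuristic, and the detectable OR at a target power for a binary outcome.
- **`synthetic_data`** — a summary-level two-sample simulator with known
  causal effect, autoregressive (or explicit) LD, analytic GWAS sampling
  variances, optional pleiotropy, and linear- or log-OR-scale binary
  outcomes; includes a six-SNP gene-region default scenario.
- **`pipeline`** / **`cli`** — YAML-config-driven orchestration of the full
  outcome × stratum grid plus a fixed-width text forest table.

## CLI

```sh
# generate a synthetic bundle (exposure.tsv, outcome.tsv, ld.tsv)
targetmr simulate --seed 1 --theta 0.3 --out simdir

# run the analysis grid
targetmr run --config config.yml

# detectable OR at 80% power
targetmr power --n 212453 --cases 10623 --r2 0.0025

# text forest table from a results file
targetmr forest out/results.tsv
```

A config file looks like:

```yaml
ld_matrix: ld.tsv
output_dir: out
instruments: {mode: lead_snp, r2_threshold: 0.01}   # or independent | all_correlated
meta: {het_alpha: 0.05}
correction: {alpha: 0.05, n_phenotypes: 10}
confounders:
  alpha: 5.0e-8
  files: {smoking: smoking.tsv}
exposures:
  EUR_overall: exposure_eur.tsv
  EAS_overall: exposure_eas.tsv
outcomes:
  asthma:
    EUR_overall: {path: asthma_eur.tsv, scale: linear}
    EAS_overall: {path: asthma_eas.tsv, scale: log_or}
```

Stratum labels are `<population>_<sex>` with sex one of
`overall`/`men`/`women`. Sex differences are tested within each population,
ancestry differences and meta-analysis across the `_overall` strata. Cells
are independent: a missing input file marks that cell
`skipped: missing input` and the rest of the grid completes. Outputs are
`results.tsv` (ORs/CIs to 2 decimals, p to 3), `results_full.tsv` (full
precision plus significance annotation), `differences.tsv`, `meta.tsv`,
`diagnostics.tsv` (F-statistics, heterogeneity, confounder flags) and
`log.txt`.

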