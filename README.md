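# mr2s

Two-sample Mendelian randomization (MR) from GWAS summary statistics.

`mr2s` turns a pair of summary-statistic tables (SNP–exposure and
SNP–outcome associations) into causal-effect estimates, handling the whole
funnel:

1. **Instrument selection** — genome-wide significance filter (default
   p < 5e-8), greedy LD pruning against a pairwise r² table (default
   r² ≤ 0.1), allele harmonization across samples (strand complements,
   effect/other swaps, frequency-orientation of palindromic SNPs), and
   screening of instruments associated with confounder traits.
2. **Instrument QC** — per-SNP variance explained
   (`VE% = 2 β² EAF (1−EAF) / var × 100`) and F-statistics
   (`F = R²(n−1−k) / ((1−R²)k)`), with weak-instrument flagging at F ≤ 10.
3. **Estimation** — Wald ratios, fixed/random-effects IVW with Cochran's Q,
   MR-Egger with its intercept test for directional pleiotropy, the
   weighted-median estimator with parametric-bootstrap SE, and the
   MR-PRESSO global / outlier / distortion resampling procedure.
4. **Decision rules** — weighted median, Egger and PRESSO require at least
   3 instruments (IVW always runs and reduces to the Wald ratio at J = 1);
   a significant Egger intercept switches the headline method from IVW to
   MR-PRESSO; estimates can be rescaled per exposure unit (e.g. per
   0.05-unit increase).
5. **Synthetic data** — a seeded generator of paired summary-statistic
   tables with known causal effect and controllable horizontal pleiotropy
   (balanced / directional / InSIDE-violating), so every stage is testable
   offline.

The package also bundles a 26-row instrument table for four plasma omega-3
fatty acids (ALA, DHA, DPA, EPA; CHARGE consortium GWAS, n = 8,866) used by
the QC acceptance checks and the `fixtures` subcommand.

## CLI

```bash
# one exposure-outcome pair
mr2s run --exposure exposure.tsv --outcome outcome.tsv \
    [--ld ld.tsv] [--confounder hdl.tsv ...] [--config cfg.yaml] \
    --exposure-n 8866 --exposure-variance 0.011 --out results/

# a grid of pairs declared in a YAML manifest
mr2s grid --manifest manifest.yaml --out results/

# synthetic two-sample study with ground truth
mr2s simulate --seed 5 --out simdir/

# bundled fatty-acid instrument tables
mr2s fixtures --out fixtures/
```

Input tables are tab-delimited UTF-8 with a header; canonical columns are
`rsid, chr, pos, ea, nea, eaf, beta, se, pval` (custom column maps are
supported, `NA` marks missing values, and published-table number styles
such as `9.61 E−44` are tolerated). LD input is three columns
`rsid_a, rsid_b, r2`. Outputs are `results.tsv` (long format),
`matrix.tsv` (method × pair matrix with `*` marking p < 0.05), `qc.tsv`
and `exclusions.tsv`.

## Library use

```python
from mr2s import (
    AnalysisConfig, SimulationConfig, ivw, mr_egger, mr_presso,
    run_pair, simulate_study, weighted_median,
)

study = simulate_study(SimulationConfig(J=26, beta_true=0.1, seed=1))
result = run_pair(study.exposure_table, study.outcome_table,
                  config=AnalysisConfig(significance_threshold=1.0))
for row in result.rows:
    print(row.method, row.beta, row.ci_low, row.ci_high, row.pval)
```

All stochastic procedures (weighted-median bootstrap, MR-PRESSO
resampling, simulation) take explicit seeds and are bit-reproducible.
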