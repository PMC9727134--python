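# tsage

Tissue-specific epigenetic age-acceleration analysis. `tsage` applies linear
DNA-methylation clocks to sperm and blood beta-value matrices, runs
sample-level quality control, computes mean-matched **GLAD** (germ-line age
differential) scores, and performs the two-group / two-tissue statistical
comparison battery. A synthetic methylome generator with known ground truth
makes every stage testable end to end without external array data.

## What it computes

1. **Simulation** (`tsage.simulate`) — paired sperm/blood cohorts with
   bimodal background betas, linearly age-drifting clock CpGs, DLK1-region
   contamination sentinels, a configurable multiplicative age-acceleration
   effect in one group, and the "true" clocks that exactly invert the
   generative model.
2. **Clocks** (`tsage.clocks`) — loads `cpg_id,coefficient` CSV files (one
   `(Intercept)` row), applies them to beta matrices with a `fail` /
   `mean_impute` / `reference_impute` missing-CpG policy, and supports the
   piecewise `log-adult` age transform and its exact inverse.
3. **QC** (`tsage.qc`) — beta-distribution bimodality (interval-mass
   thresholds), DLK1 mean-beta contamination check (default pass ≤ 0.25,
   sperm only), optional median log2-intensity floor, and a Welch t-test
   confirming chronological age is not confounded with group.
4. **GLAD** (`tsage.glad`) — mean-matching adjustment (shift predictions so
   the cohort means of adjusted and chronological age coincide) and
   `glad = (adjusted − chronological) / chronological` per sample, plus
   per-individual sperm-minus-blood predicted-age differences.
5. **Comparisons** (`tsage.compare`) — Welch t-tests (Satterthwaite df) on
   GLAD per tissue and on the paired differences, OLS regressions of
   predicted on chronological age with adjusted r², assembled into a JSON /
   Markdown report.
6. **Pipeline** (`tsage.pipeline`) — simulate/load → qc → predict → glad →
   compare with per-stage seed substreams, plain-text intermediates, SHA-256
   manifest, diagnostic scatterplots, and a Monte-Carlo power analysis.

## CLI

```sh
tsage simulate --config sim.yaml --out cohort/ --seed 1
tsage qc --betas cohort/betas_sperm.tsv --sheet cohort/sample_sheet.csv \
         --dlk1 cohort/dlk1_cpgs.txt --out qc/
tsage predict --betas qc/betas_filtered.tsv --clock cohort/clock_sperm.csv \
              --transform identity --missing fail --sheet cohort/sample_sheet.csv \
              --out predictions.tsv
tsage glad --predictions predictions.tsv --sheet cohort/sample_sheet.csv \
           --scope pooled --glad-form centered --out glad.tsv
tsage compare --glad glad.tsv --predictions predictions.tsv \
              --sheet cohort/sample_sheet.csv --out report/
tsage power --accel-grid 0,0.05,0.095,0.15 --replicates 200 --seed 1
tsage all --config run.yaml --out run/     # everything in one go
```

A pipeline YAML holds either a `sim:` block (SimConfig fields) or an
`inputs:` block with real file paths — never both. Exit codes: 0 success,
2 configuration error, 3 stage failure.

## File formats

* **Beta matrix** — TSV, first column `cpg_id`, one column per sample,
  values in [0,1].
* **Sample sheet** — CSV with `sample_id,individual_id,tissue,group,age_years`.
* **Clock** — CSV with `cpg_id,coefficient` and one `(Intercept)` row.
* **DLK1 annotation** — one CpG id per line.
* **Intensity table** — `sample_id,median_log2_intensity` (optional).

Input betas are assumed pre-normalized; no probe-level filtering or
array normalization is performed.
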