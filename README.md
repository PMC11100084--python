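# permscreen

Permutation-based association testing for low-multiplicity-of-infection
single-cell CRISPR screens.

For each perturbation–gene pair, the gene's raw UMI counts are regressed on
technical factors (library size, batch, …) with a negative-binomial GLM fitted
under the null, and the perturbation is tested with a GLM **score statistic**.
The perturbation labels are then permuted to build a null distribution of
score statistics, and a p-value is read off a method-of-moments **skew-normal
fit** to that null (with an empirical fallback when the fit is poor). Because
the statistic only needs the null fit, one fit per gene serves every
permutation; a spectral factorization of `Z'WZ` makes each permuted statistic
O(t·q) in the number of treated cells, permutations are shared across pairs
through nested without-replacement orderings, and a two-stage adaptive scheme
stops early on unpromising pairs.

The package also ships:

- dataset containers + MatrixMarket/TSV I/O and the standard QC filters
  (genes expressed in ≥ 0.005 of cells, gRNAs in ≥ 10 cells, cells with
  exactly one gRNA) — `permscreen.data_model`;
- pair construction with NT-cells / complement control-group semantics,
  effective-sample-size (ESS) pairwise QC at the default threshold of 7, and
  automatically matched negative-control pairs — `permscreen.pairs`;
- synthetic screens (signal-free null, positive-control with truth table) and
  a confounding/misspecification calibration study comparing the permuted
  score statistic against plain NB regression and a naive sum-statistic
  permutation test — `permscreen.simulate`;
- diagnostics: exact-vs-asymptotic Wilcoxon comparison, Fisher-exact and
  likelihood-ratio confounding tests, ESS-stratified QQ summaries —
  `permscreen.diagnostics`.

## CLI

```sh
# synthesize a screen (presets: null-small, null-paper, pc-small, pc-paper)
permscreen simulate --preset null-small --seed 1 --out data/

# dataset-level QC
permscreen qc --data data/ --out data_qc/

# calibration check on matched negative-control pairs
# (exit 0 = pass, 3 = calibration failure)
permscreen calibration-check --data data/ --out calib/ --seed 1

# discovery analysis (BH q-values; requires a calibration report or --force)
permscreen discovery --data data/ --out disc/ --seed 1 \
    --calibration-report calib/manifest.json

# confounding/misspecification calibration study
permscreen confounding-study --n-datasets 200 --out confounding/
```

Every run writes a `manifest.json` with the seed, configuration and filter
accounting; identical configs and seeds give byte-identical result tables.

### Input formats

Counts: MatrixMarket `counts.mtx` with sidecar `response_ids.txt` /
`cell_ids.txt` (one id per line), or a dense `counts.tsv` with a header row of
cell ids. Assignments (`cell_id`, `grna_id`), gRNA metadata (`grna_id`,
`target`, `targeting`, `grna_group`) and per-cell covariates are
tab-separated with headers.

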