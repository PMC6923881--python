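# protpred

Benchmarking pipeline for predicting **protein abundance from transcript
expression** in matched tumor cohorts (z-scored RNA-seq vs iTRAQ-ratio
proteomics). Proteomic coverage lags far behind transcriptomics, and
per-gene transcript–protein correlations in such cohorts hover only around
0.4–0.5 — so which regression model class to use, and for which proteins,
is an empirical question. `protpred` answers it by evaluating four model
classes under one cross-validation harness:

- **Fuzzy-logic regression** — per selected transcript, a Gaussian-KDE
  density of the protein over training samples within τ transcript-SDs of
  the query; densities are α-thresholded, intersected (pointwise minimum)
  on a 0.1-SD grid, and the argmax of the minimum is the prediction.
- **Gaussian Bayesian network** — ARACNE: pairwise Gaussian mutual
  information MI = −½ ln(1 − r²), a significance pre-filter, and the
  data-processing-inequality triple scan; the skeleton is oriented into a
  DAG, fit by per-node OLS on complete cases, and the protein is predicted
  by its linear-Gaussian conditional mean given its parents.
- **Random forest** — 100 trees on all transcripts, mtry ∈ {5, 10, 25}.
- **LASSO** — penalty fraction 0.1…0.9 of the maximal L1 norm, features
  restricted to complete, non-constant transcripts.
- **Ensemble** — per protein and fold, a weighted sum of the four
  predictions with weights ∝ max(training correlation, 0).

Models are compared per protein over k-fold CV (default 10) by Pearson
correlation and NRMSE (RMSE / ground-truth range), with pooled medians,
failure accounting, and top-100 cross-fold consistency tables. The fuzzy
and network models see only the 8 transcripts with the largest |Spearman ρ|
to the protein, computed on each fold's training split.

Because real matched proteogenomic cohorts of this kind are typically
access-restricted, the package ships a synthetic cohort generator
(`protpred.synthetic_data`) that reproduces the relevant statistical
structure — correlated transcript blocks, protein archetypes (sparse
linear, Markov chain, additive AND, threshold AND, null) with a
ground-truth manifest, two-institute protein layers, and missing values —
so every stage is testable offline, including structure-recovery checks
against known truth.

## Worked example

```python
from protpred import RunConfig, run_pipeline
from protpred.synthetic_data import CohortSpec

spec = CohortSpec(n_samples=60, n_transcripts=40, n_proteins=10, seed=11)
report = run_pipeline(RunConfig(n_folds=5, seed=11), cohort_spec=spec)
for method, s in sorted(report.summary.items()):
    print(f"{method:9s} median r = {s['median_correlation']:.3f}   "
          f"median NRMSE = {s['median_nrmse']:.3f}   failed = {s['n_failed']}")
```

prints

```
bn        median r = 0.827   median NRMSE = 0.202   failed = 0
ensemble  median r = 0.760   median NRMSE = 0.230   failed = 0
fuzzy     median r = 0.236   median NRMSE = 0.308   failed = 0
lasso     median r = 0.625   median NRMSE = 0.268   failed = 0
rf        median r = 0.722   median NRMSE = 0.247   failed = 0
```

Each line is a model's median held-out Pearson correlation and NRMSE pooled
over all (protein, fold) pairs of this 10-protein cohort, plus its count of
failed predictions. On this small mixed cohort the network and forest lead
(most proteins here have conditional-dependence structure), the fuzzy
predictor trails — its density intersection is diluted by the distractor
transcripts inside the top-8 selection — and the ensemble tracks the best
single methods without being told which one wins.

The same run from a shell:

```bash
protpred simulate --out data/ --seed 11 --n-samples 60 \
    --n-transcripts 40 --n-proteins 10
protpred run --transcripts data/transcripts.tsv --proteins data/proteins.tsv \
    --out results/ --n-folds 5 --seed 11
protpred report --predictions results/predictions.tsv \
    --proteins data/proteins.tsv --out report/
```

`run` writes `predictions.tsv`, `metrics.tsv`, `summary.json`, the
consistency and ensemble-weight tables, and the tuning traces (the 6-row
(τ, α) fuzzy grid, the 3-row mtry grid, per-protein LASSO fractions);
`report` regenerates metrics, consistency tables and histograms from stored
predictions.

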