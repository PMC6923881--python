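# Methods

`protpred` benchmarks four model classes for predicting protein abundance
from transcript expression in matched tumor cohorts, together with their
training-accuracy-weighted ensemble, under one shared cross-validation
harness. This note documents the models as implemented, the synthetic data
they are evaluated on, and the numerical and design choices that were
genuinely open.

## Problem setting

Inputs are two expression matrices over the same samples: z-scored RNA-seq
transcript abundances and iTRAQ-ratio-like protein abundances (genes in
rows on disk, samples × features in memory, missing entries explicit).
For every protein a separate regression model is built per cross-validation
fold; predictions on the held-out samples are scored by Pearson correlation
and NRMSE. Per-gene transcript–protein correlations in such cohorts center
near 0.4–0.5 with heavy tails, so no model class is expected to dominate
for all proteins — quantifying that is the point of the benchmark.

## Preprocessing

- **Normalization.** Each feature is standardized to mean 0, sample SD 1
  (n−1 denominator) over its observed values, the behaviour of R's `scale`.
  Features that are constant or have fewer than two observations are dropped
  from all downstream feature pools. Normalization is applied to the full
  matrix before fold splitting, mirroring the usual practice for these
  cohort-level z-scores; everything fit-like (selection, tuning, model
  fitting, ensemble weights) uses training rows only.
- **Institute merging.** When one cohort's proteins were quantified at two
  institutes, only proteins measured by both are kept and the first
  institute's values are used. Averaging two iTRAQ ratio scales elementwise
  is not well-posed and is deliberately not offered.
- **Folds.** Samples are partitioned into `n_folds` (default 10) balanced
  random test folds, deterministically from the run seed and invariant to
  input ordering (IDs are sorted before shuffling).
- **Transcript selection.** The fuzzy and network models receive only the
  `k = 8` transcripts with the largest |Spearman ρ| against the protein,
  computed on pairwise-complete training observations of each fold
  (anti-correlated transcripts count equally; ties break lexicographically).
  Per-fold-training selection avoids test-set leakage; computing one global
  selection on all data is the plausible alternative reading of the original
  procedure and would only make selections more stable.

## The fuzzy-logic predictor

For a test sample and each selected transcript *t* with training SD σₜ:

1. **Window:** training pairs with |xₜ − query| ≤ τ·σₜ (τ ∈ {0.5, 1, 2}).
   Windows with fewer than 10 pairs are discarded.
2. **Local density:** a Gaussian KDE (Silverman/`bw.nrd0` bandwidth — the R
   `density` default, since no estimator is canonical here) of the protein
   values in the window, evaluated on a fixed grid of 0.1·σ_y intervals
   spanning the protein's training range (grid points are interval
   midpoints, anchored at the training minimum).
3. **Support:** the hull [first, last] grid point with density > α
   (α ∈ {0.1, 0.3}), read as a contiguous interval; α is compared against
   raw density values, not rescaled memberships.
4. **Intersection:** over grid points in the intersection of all supports,
   the combined membership is the pointwise minimum of the densities; the
   prediction is the grid point maximizing it, ties toward the smaller
   value.

If every transcript is discarded or the supports share no grid point the
predictor returns the training mean with status `fallback_mean` — degraded
cases carry a flag rather than dropping the protein. (τ, α) are tuned once
per run over the 3 × 2 grid by inner 3-fold CV on the first fold's training
split, maximizing the median held-out correlation; if nothing is defined
the fallback is τ = 1, α = 0.1. The 10-sample rule is applied to window
occupancy (not to the count of above-α grid points, the other reading of
the rule), and the window width is governed by τ, not by the grid step.

## The Gaussian Bayesian network

Per protein, over the 9 nodes {protein} ∪ top-8 transcripts:

- **MI:** pairwise Gaussian mutual information, MI = −½·ln(1 − r²) nats,
  with r the pairwise-complete Pearson correlation clipped at 1 − 10⁻¹².
- **Pre-filter:** edges whose deviance 2·n·MI is insignificant against
  χ²₁ at p = 0.05 are dropped. This also resolves the all-independent tie
  case where a strict-minimum DPI alone would keep a complete noise graph.
- **ARACNE:** every fully connected node triple marks its strictly weakest
  edge (DPI tolerance ε = 0, configurable); marked edges are removed
  simultaneously after scanning all triples against the original MI values.
- **Orientation:** edges at the protein point into it; remaining edges run
  from lower to higher canonical node index — acyclic by construction.
- **Fit:** each node is regressed on its parents by OLS over rows complete
  in all network variables; residual SD from the OLS residuals. Fewer
  complete rows than max-parents + 2, or a rank-deficient design, is a
  recorded fit failure, never a silent imputation.
- **Prediction:** the protein's linear-Gaussian conditional mean given its
  parents' test values; missing parents are imputed with their training
  means; a parentless protein predicts its training mean (status
  `degenerate`).

Only ARACNE is implemented as the structure learner; the Gaussian test
family is a documented assumption where the original tooling's defaults
are unstated.

## Baselines

- **Random forest:** 100 CART trees (scikit-learn), mtry ∈ {5, 10, 25}
  features per split, all transcripts as features, training-mean imputation
  of missing values. mtry is tuned once per run (inner 3-fold CV pooled
  over up to 12 proteins) — one global optimum, matching how a single mtry
  is reported per dataset; per-protein tuning is available via `RFParams`.
  Training-side predictions for ensemble weighting are out-of-bag: refit
  predictions from a forest are ≈ perfectly correlated with the training
  labels and would drown the other methods' weights.
- **LASSO:** features are transcripts with no missing training values and
  nonzero variance; an empty pool is a recorded failed prediction. The
  penalty is parameterized as the fraction of the maximal L1 norm along the
  LARS-lasso path (the `caret`/`elasticnet` convention), grid 0.1…0.9,
  chosen by inner 5-fold CV on mean Pearson correlation (negative RMSE
  when correlation is undefined); features are standardized before the
  path fit. Interpreting the grid as absolute λ values is the alternative
  reading and is not implemented.

## Ensemble

Per (protein, fold), each method's weight is its training-set Pearson
correlation (OOB for the forest) clipped at zero and normalized to sum to
one over methods with usable predictions; all-nonpositive weights fall back
to equal weights, and failed methods are excluded with renormalization.
"Training accuracy" as correlation (rather than inverse error) and
zero-clipping of anti-predictive models are documented assumptions; the
clip prevents a negatively correlated model from flipping the sign of its
contribution. The ensemble prediction is the convex combination of the
component predictions and always lies within their per-sample min/max.

## Metrics

- Pearson correlation: undefined (NaN) under 3 complete pairs or a constant
  vector; the constancy check is on the exact range, not a floating `std`.
- NRMSE: RMSE / (max − min) of the test ground truth. The normalizer is not
  standard anywhere; range normalization is the default and SD
  normalization is available behind `nrmse_norm="sd"`. Reported NRMSE
  values are therefore comparable only within one convention.
- Medians pool all defined per-protein per-fold values (folds are not
  averaged per protein first).
- Top-k consistency: per fold, proteins are ranked by correlation
  (undefined values last, ties by ID); the table counts, per protein, the
  folds in which it reached the top k (default 100, clamped to the protein
  count with a warning).
- Accounting: ok + failed + degenerate records always equal
  n_proteins × n_folds per method.

## Synthetic cohorts

The generator emulates the downstream statistical structure of a matched
proteogenomic cohort, not the measurement chemistry: standard-normal
transcripts with AR(1) correlation blocks (size 10, ρ = 0.5 — giving the
DPI indirect edges to prune), proteins drawn from archetypes with disjoint
supports, per-entry missingness (default 5% proteins, 1% transcripts —
RNA-seq is near-complete, mass-spec is not), and an optional second
"institute" protein matrix (added noise, partial protein overlap).

Archetypes and default noise levels (chosen so the strongest transcript–
protein correlation of a signal archetype is ≈ 0.5, the regime reported for
real matched cohorts):

| archetype | model | default noise SD |
|---|---|---|
| linear_sparse | y = Σβⱼxⱼ + ε, β = (1, 0.7, 0.5) | 1.503 |
| chain | x₂ = ρx₁ + e, y = ρx₂ + e′, ρ = 0.9 | √(1−ρ²) |
| additive_and | y = (xₐ + x_b)/2 + ε | 0.707 |
| threshold_and | y = ±1 by sign(xₐ), sign(x_b), + ε | 0.5 |
| null | y = ε | 1.0 |

Default cohort: 120 samples × 200 transcripts × 60 proteins (30% linear,
15% chain, 20% additive, 15% threshold, 20% null) — large enough for
10-fold CV, small enough to run on a desk machine. A ground-truth manifest
records each protein's archetype and fully determines bit-identical
regeneration.

What the generator does **not** model: iTRAQ reporter-ion chemistry, RSEM
quantification noise, CNV dosage effects, batch structure, non-Gaussian
tails, or informative missingness. Passing tests therefore demonstrate that
each method recovers the relationship class it claims to capture under
clean conditions, not that it attains any particular accuracy on real
tumor data.

## Numerical choices and degenerate inputs

- All randomness flows from one seed through named substreams (CRC32 of
  stage keys into a `SeedSequence`), so adding a method never perturbs
  another's folds; matrices are canonicalized (sorted IDs) on pipeline
  entry, making output invariant to input row/column order.
- KDE bandwidth fallback for zero-spread windows follows `bw.nrd0`
  (SD, then |x₁|, then 1), so a point-mass window yields a narrow peak
  rather than an error.
- Quantiles inside the bandwidth rule use linear interpolation on sorted
  values (numpy's default definition, implemented directly for speed).
- The problem sizes used by the test-suite recovery checks are the ones a
  desk-scale study of these properties needs: n = 500 × 30 replicates for
  chain pruning, n = 200 for archetype recovery, a 24-protein mixed cohort
  for the ensemble property.

## Known limitations

- The ARACNE pre-filter threshold (p = 0.05, Gaussian test) and the DPI
  ε = 0 are assumptions; other choices change skeleton density.
- Fuzzy predictions are grid-quantized to 0.1·σ_y, bounding attainable
  correlation slightly below 1 even for perfect relationships.
- With many distractor transcripts among the top-8, the fuzzy intersection
  dilutes: informative local densities are min-ed against near-marginal
  ones. This is a property of the method, visible in the benchmark.
- LASSO's completeness filter interacts strongly with transcript-level
  missingness; at a few percent missing rate most transcripts are excluded
  for some protein, which is what produces the method's recorded failed
  predictions.
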