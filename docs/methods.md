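# Methods

This note documents the models, numerical choices, and limitations of
`fpconn`. It complements the README (which defines the headline
quantities) with the decisions a maintainer or reviewer would want spelled
out.

## Synthetic cohort model

Each subject's parcellated time series is multivariate normal per scan
half, with covariance assembled from unit-variance components:

```
Σ(subject, half) = fs·L_s L_sᵀ + gs·L_g L_gᵀ + Σ_b Δ_b(subject, half)
                   + Δ_cov(subject) + ν·I
```

- `L_s` (regions × `signature_rank`) is the subject-unique factor loading
  matrix, rows normalized to unit length so the component has unit marginal
  variance. It is shared by both halves: this is the fingerprint.
  `fs = fingerprint_share` is the variance fraction it carries.
- `L_g` is the analogous group-common structure (`gs = group_share`),
  shared by all subjects of a group.
- `ν = noise_sd²·(1 − fs − gs)` is isotropic noise; it doubles as the
  spectral budget for the hollow perturbations below.

**Block-localized stability differences.** A `StabilityBlock`
`(network_i, network_j, direction, magnitude)` adds, for every subject, a
zero-diagonal covariance perturbation `Δ_b = c·V` supported *only* on the
block's edges, where `V` has orthonormal rows (spectral norm 1). The group
named by `direction` as less stable regenerates part of it in the second
half, `V₂ = √(1−m)·V₁ + √m·V_fresh` with `m = magnitude`, which lowers the
test–retest reliability of exactly those edges while leaving marginal
variances — hence mean FC — unchanged. Because a purely cross-block
covariance is indefinite, positive definiteness is bought from the noise
floor: block strengths are auto-allocated from 60% of `ν` (configurable via
`block_strength`), with conservative spectral safety factors (1.6 for
between-network, 2.5 for within-network blocks, covering symmetrization and
half-mixing) and a hard Cholesky check at sampling time. When the larger
block dimension is a power of two, `V` is a randomized Hadamard design
whose entries all have magnitude `1/√n` — planted per-edge effects are then
homogeneous across the block, which is what makes high-sensitivity recovery
tests meaningful; otherwise a Gaussian partial isometry is used and
per-edge effect sizes are half-normal.

**Covariates.** Demographics emulate an elderly patient cohort with
age-matched controls (patients ≈ 68.5 ± 5.9 y, controls ≈ 64 ± 10.5 y,
roughly one-third male, education ≈ 16 ± 2.5 y). Reported onset age gets
N(0, 0.6) jitter around `age − duration`: the exact identity would make the
five-covariate regression design singular, and self-reported onset is
imprecise in practice. Optional `covariate_effects` add signed edge-
covariance shifts (per SD of the covariate) on a sparse random edge subset,
recorded in the ground truth.

**Clinical outcomes.** Baseline UPDRS-III is drawn near the moderate-stage
anchor (mean 37.8, SD 11.7, clipped to [10, 80]). Each patient's planted-
subnetwork connectivity score (mean |full-series FC| over the
controls-more-stable edges) enters a latent index
`outcome_coupling·z(score) + N(0,1)`; the top `round(responder_fraction·n)`
patients by this index are responders and receive a relative improvement
drawn from U(16.5, 45)%, the rest from U(−10, 13.5)%. The margins around
the 15% boundary make labels invariant to the 0.1-point score rounding; at
`outcome_coupling = 0` labels are independent of the features, and the
realized responder count always equals the target. The default
`responder_fraction = 13/23` matches the labeling used by the
classification analysis (a 10/23 count also appears in the literature for
the same boundary; the fraction is configurable rather than adjudicated).

**Defaults as study conditions.** 23 subjects per group, 100 regions in 7
networks of sizes (15,15,14,14,14,14,14) (the 400-region atlas is supported
but not needed for testing), T = 400 samples, `fingerprint_share = 0.5`,
`group_share = 0.1`, `signature_rank = 30`. The rank is the calibration
knob: with T = 400 it places within-subject split-half FC similarity near
0.6 while residualized between-subject similarity sits near 0, matching the
regime the analysis targets (residualized I_self ≈ 0.6, I_others ≈ −0.03,
mean edgewise ICC ≈ 0.6, SR = 100).

## What the generator does not emulate

Hemodynamics, autocorrelated BOLD noise, head motion, physiological
artifacts, preprocessing residue, spatial autocorrelation of the parcels,
and any geometry of the cortical sheet. Passing tests show the *pipeline*
recovers what was planted under Gaussian, temporally white signals — not
that real fMRI meets those assumptions.

## Statistical and numerical choices

- **Split convention:** odd scan lengths give the test half ⌊T/2⌋ samples.
- **No Fisher z-transform** before vectorization or identifiability (raw
  Pearson values correlate); exposed nowhere because downstream Pearson
  correlation of profiles is monotone-invariant enough in practice; signed
  FC is kept until graph construction.
- **Residualization** is per group and per half with the same covariates,
  intercept always included, residuals not re-inflated; constant columns
  are dropped, rank-deficient designs are an error. Scope is switchable to
  `pooled` in the pipeline. Per-group fitting is mildly anti-conservative
  in the edgewise permutation test at very small N (the per-group OLS
  projection removes ~p+1 of N degrees of freedom, making observed ICCs
  noisier than permuted mixtures); pooled residualization preserves
  exchangeability exactly. At N ≳ 20 per group the distortion is small.
- **I_diff-norm** uses sample variances (ddof 1) with n_within = N,
  n_between = N² − N. SR uses strict inequality over row *and* column
  cross-matches; ties fail. A row-only mode exists.
- **Bootstrap** (1000 iterations default) resamples subjects with
  replacement (a without-replacement mode exists); paired comparisons apply
  identical index draws to both matrices. Two-tailed p-values use the
  mean-centered bootstrap distribution as the null with plus-one
  correction, so p ≥ 1/(n_iter+1) and a degenerate zero-difference
  comparison yields p = 1.
- **ICC** keeps negative values (the estimator admits them; truncation
  would bias group differences), stores undefined edges (zero total mean
  square) and the diagonal as NaN sentinels excluded from every summary.
- **Permutation test** reassigns whole subjects (test and retest together)
  to pseudo-groups of the original sizes; per-edge two-sided p-values are
  plus-one corrected, then BH-adjusted across all edges as one family. The
  null can mirror the observed subsampling (default) or skip it (fast
  mode). With plus-one correction the smallest achievable adjusted p is
  `E/(k·(n_perm+1))` for k detections among E edges, so FDR-significant
  recovery at α = 0.01 needs permutation counts scaled to the edge count;
  the recovery tests use 5000 permutations at E = 325 with 40 subjects per
  group. Concordance of network rankings is the proportion of label pairs
  with equal relative order, with a one-sided shuffle null; ranking ties
  break by the canonical network order (VN, SMN, DAN, VAN, LN, FPN, DMN).
- **Graphs** use absolute FC weights by default (positive-only mode
  available) so all eight measures are defined on signed residual FC; path
  lengths use edge length 1/weight; MFPT is solved per target from
  `(I − Q)m = 1` on the largest connected component (the Kemeny
  fundamental-matrix solution is the test oracle); eigenvector centrality
  is the Perron vector by deterministic power iteration; modularity is
  seeded Louvain, and the participation coefficient uses that same
  partition (masked subgraphs span atlas networks, so atlas-based modules
  would be arbitrary); nodal measures are averaged over nodes to one scalar
  per subject; the rich-club scalar is the mean of the weighted rich-club
  curve over defined degree levels (max mode available); proportional
  thresholding keeps ⌈density·E⌉ edges of |FC| with stable tie-breaks by
  edge index.
- **Classifier:** inner 5-fold stratified grid search scored by accuracy
  (folds shrink automatically if a class is too small, never below 2);
  standardization is refit inside every outer fold; AUCs are computed on
  pooled held-out scores because LOOCV folds contain one sample.
  Single-combination grids bypass the search. Default grids: random forest
  {100, 300 trees × depth None/3/5}, gradient boosting {lr 0.05/0.1 × 100,
  300 trees × depth 2/3}, kNN {k 3/5/7 × uniform/distance}, and small
  standard grids for logistic regression, SVM, decision tree. MDI
  importances are averaged over outer folds and normalized to sum 1, ties
  broken alphabetically.
- **Group statistics:** Shapiro–Wilk gate at α = 0.05 (on differences for
  paired designs); Cohen's d uses the SD of differences for paired data and
  the pooled SD for independent data; chi-square without continuity
  correction; `t_from_summary` inverts a printed mean change and 95% CI to
  the paired t statistic via the t critical value at n − 1 df.
- **Reproducibility:** every stochastic stage draws a named seed from the
  pipeline master seed; rerunning a configuration reproduces byte-identical
  artifacts (fixtures are written at 17 significant digits and parsed with
  round-trip float precision).

## Problem sizes

Tests run at 21–50 regions, 8–40 subjects per group, 120–800 time points,
with 60–5000 permutations chosen to match each test's resolution needs; the
acceptance script uses the default 100-region, 23-per-group, T = 400
configuration. Full 400-region cohorts are supported by the same code
paths.

## Known limitations

- The permutation null for the differential test assumes group
  exchangeability of the (possibly residualized) edge vectors; see the
  residualization-scope caveat above.
- Louvain partitions are seed-stable but not canonical; modularity and
  participation values on near-degenerate partitions can differ across
  library versions.
- The synthetic outcome couples to a single scalar subnetwork score; real
  response heterogeneity is unlikely to be one-dimensional.
- Within-network stability blocks use symmetrized designs whose per-edge
  effects are less homogeneous than the between-network Hadamard case.
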