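# Methods

This note documents the statistical model behind `branchtf`, the defaults and
why they were chosen, what the synthetic generator does and does not emulate,
and the numerical decisions a maintainer would want written down.

## Input model

The unit of analysis is one trajectory branch: a genes × cells matrix of
non-negative normalized counts with a scalar pseudotime per cell, as produced
by any trajectory-inference method.  Trajectory inference itself is out of
scope; errors in the upstream pseudotime propagate into everything downstream,
which is the reason for the robustness gate described below.  Regulons come
from a TRRUST-dialect table (TF, target, mode ∈ {Activation, Repression,
Unknown}); gene identity is the bare case-sensitive symbol, with an optional
two-column ortholog map for cross-species tables (duplicate source symbols
keep the first mapping).  Regulons with fewer than `min_targets` (default 3)
annotated targets are dropped — relational enrichment on one or two scores is
meaningless.

## Pseudotime focusing

Cells are retained iff their pseudotime lies in
`[Q1 − f·IQR, Q3 + f·IQR]` with `f = iqr_factor` (default 1.5) and quartiles
under the linear-interpolation convention (`numpy.percentile` default).  The
fence is an interval, so the retained set is contiguous in pseudotime rank; no
extra contiguity rule is needed.  Focusing is idempotent for the continuous,
spread-out pseudotime distributions trajectory methods produce.  It is *not*
idempotent in pathological cases where most mass sits on a single value (the
IQR can collapse between passes); the property tests are scoped accordingly.

## Quantization

The retained range is divided into `n_bins` equal pseudotime increments
(half-open bins, last bin right-closed).  Each bin must hold at least
`min_cells_per_bin` cells (default 10, so one noisy cell cannot own a bin).
An under-populated bin merges into whichever adjacent neighbor holds fewer
cells (left on tie): merging into the *smaller* neighbor keeps the merged bins
balanced and stays closest to the equal-increment design — merging into the
larger one cascades and can collapse a branch to a single bin.  Per-gene bin
values are arithmetic means over member cells, so `Σ count·mean` per gene
equals the retained-cell total exactly (mass conservation, tested).
Branches with fewer than `2·min_cells_per_bin` cells are unbinnable.
`raw_bypass = true` skips quantization and treats each cell as a weight-1
pseudo-bin for high-resolution datasets.

## Spline model

Each gene's bin means `y` (weights = bin cell counts) are fit on the bin-index
axis with a cubic B-spline basis and a second-difference (P-spline) penalty
under a negative-binomial observation model with log link:

- the smoothing factor `s ∈ (0, 1]` maps to basis size
  `k = 4 + (1 − s)(min(n, 12) − 4)` and penalty weight `λ = 10^(3s − 1)` —
  one knob controlling both effective knots and stiffness, with heavier `s`
  meaning smoother fits;
- the NB dispersion α is re-estimated each IRLS step by moments,
  `α = Σw[(y−μ)² − μ] / Σw μ²`, clipped to [1e−8, 100];
- the NB likelihood uses the gamma-function continuous extension of the pmf,
  since bin means are continuous;
- when exact zeros are present, a scalar zero-inflation probability π is
  estimated by a short EM: the structural-zero posterior of each zero bin
  down-weights it in the next IRLS pass, and the reported likelihood is the
  ZINB mixture;
- if the IRLS produces non-finite estimates the fit falls back to a Gaussian
  penalized WLS clipped at zero, recorded in `SplineFit.family`;
- all-zero genes return a flagged flat-zero fit.

AIC is `2k − 2·loglik` with `k` = trace of the hat matrix (effective degrees
of freedom) plus one for the dispersion (plus one more for π under ZINB).
The log link guarantees non-negative fitted values; a constant series is
reproduced to machine precision because constants lie in the penalty null
space.

## Hyperparameter search and the robustness gate

The branch-level parameters (`n_bins`, smoothing factor) are chosen on the
`n_search_genes` (default 100) most variable genes at the reference binning
(smallest grid `n_bins`).  Each grid point is scored on 30 subsamples of 80%
of cells (without replacement): the mean AIC measures fit quality and the
coefficient of variation — mean over genes and coefficient positions of
sd/|mean| across subsamples, positions with |mean| < 1e−8 excluded — measures
robustness.  Subsamples whose re-binning lands on a different bin count (bin
merging can do this) are skipped, because coefficient vectors are only
comparable on a common basis; more than 50% skipped forces CV = ∞.  Mean AIC
is min-max normalized across the grid before combining (raw AIC and CV live on
incommensurate scales, so "distance to the origin" is only meaningful after
normalization), and the chosen point minimizes `sqrt(aic_norm² + cv²)` among
points with CV ≤ 1.0.  If no point qualifies the branch is **rejected** and
never analyzed — a branch whose smoothed representation changes materially
under 80% subsampling cannot support reproducible TF calls.  The default grid
is bins {4, 8, 16, 32, 64, 100} × smoothing {0.1, 0.3, 0.5, 0.7, 0.9};
a dense 4..100 sweep is configurable but is the expensive path (grid points
run in parallel and each derives its seed from a stable hash, so the thread
count never changes results).

## Concordance metrics

All metrics operate on the smoothed genes × bins profiles:

- **pearson / spearman** — squared correlation in [0, 1], squaring makes
  activators and repressors comparable to an unsigned background; the sign is
  kept separately for the direction filter.  Zero-variance profiles are
  unscorable and skipped.
- **dtw** — both profiles are rescaled to fractional form (value / series
  sum; an all-zero series becomes uniform) so different expression scales are
  comparable; the dynamic program minimizes cumulative |difference| under
  diagonal/left/down steps, tie-breaking toward the shorter path, and reports
  cost / path length.  Smaller is tighter alignment.
- **mi** — plug-in mutual information in nats on equal-frequency
  discretizations (default 8 bins via ordinal ranks, deterministic and
  symmetric; near-constant series give MI = 0 by convention).  The plug-in
  estimate is bounded by ln(bins).
- **rolling_{pearson,spearman,dtw,mi}** — rescan the base metric on
  `(x[:n−k], y[k:])` for lags k = 0..max_lag (default ⌈n_bins/4⌉), keep the
  best score and its lag, ties toward the smaller lag; overlaps shorter than
  3 bins are skipped.  Detects regulons whose targets respond after a shared
  delay — DTW tolerates per-target delays, rolling requires a common one.

The TF is never scored against itself; targets absent from the matrix are
dropped and counted.

## RSEA

Per branch × metric:

1. **Direction filter** (correlation metrics only): a target annotated
   Activation must correlate non-negatively, Repression non-positively;
   Unknown-mode targets always pass.
2. **Target focusing**: keep scores at or above the 25th percentile (at or
   below the 75th for DTW) — the top 75% most concordant targets.  Ties at
   the threshold are kept; if fewer than `min_targets` survive, the
   `min_targets` strongest are kept.
3. **Background**: one gene set of size equal to the largest testable regulon
   (mode `shared_max`; `per_tf` sizes it to each TF's own regulon), drawn
   uniformly from the branch's genes excluding all tested TF symbols, scored
   against the TF with the same metric and lag rules, and focused by the same
   percentile rule so the comparison is like-for-like.  Background sets carry
   no mode annotation, so they are not direction-filtered.
4. **KS test**: two-sided two-sample Kolmogorov–Smirnov of focused observed
   vs focused background scores.  The p-value is an exact permutation
   enumeration when `C(n+m, n) ≤ 20 000` (correct under ties), scipy's exact
   method when `n·m ≤ 10 000`, asymptotic beyond.  The direction (observed
   median above/below background) is reported separately; for DTW, *below* is
   the strengthening direction.
5. **Background averaging**: the p-value is the mean over
   `background_repeats = 5` independent draws (the first draw shared across
   TFs).  A single shared draw proved fragile: because every TF is tested
   against the same random set, one unlucky draw shifts all tests in the same
   direction, and on redundant gene pools the decoy false-positive count
   varied several-fold with the draw seed alone.  Averaging five draws makes
   planted-versus-decoy separation stable across draw seeds at ~5× metric
   cost.
6. **FDR**: Benjamini–Hochberg step-up across TFs within the branch × metric
   family.  The ensemble result per TF is the minimum FDR across metrics with
   the winning metric named; FDR < `alpha` (default 0.05) is significant.
   The ensemble minimum is reported as-is (no cross-metric correction), so
   its realized decoy rate is slightly above the per-metric level — the
   metrics are strongly correlated, which keeps the inflation small.

Untestable TFs (absent from the matrix, too few scorable or
direction-consistent targets, unscorable background) are listed with reasons,
never silently dropped.

## DE baselines and evaluation

`de_ttest` splits a branch into equal-count start/end halves at the median
rank (odd observation to the start half) — equal *pseudotime* spans produce
severely imbalanced halves on real branches — and runs a Welch t-test per
gene (raw cells after focusing, or smoothed bins), reporting fold change with
a 1e−9 pseudo-count, t, p, and BH FDR.  Identical constant halves get p = 1
by convention; perfectly separated zero-variance halves get ±∞ t and the
smallest positive float as p.  `de_targets` compares a regulon's |t| values
to a random background gene set with the same KS machinery.

`precision_recall` sweeps an FDR-ranked (TF, branch) list against a marker
set, grouping ties; positives count per (TF, branch) appearance.  AUC is the
trapezoid over achieved recalls anchored at recall 0 with the first group's
precision; early precision is the precision at the largest achieved recall ≤
0.1, or the first group's precision when no recall that small is achieved.
ROC (TPR/FPR) comes from the same sweep.  `build_tf_network` connects
significant TFs u → v when v is an annotated target of u, excluding
self-loops.

## Synthetic data

The generator emulates what a trajectory method hands this tool.  Pseudotime
is uniform on [0, 1]; planted outliers sit at 4.0, 5.0, ... — beyond any
1.5×IQR fence of the combined distribution, and the generator verifies that
the fence removes exactly them.  Each TF follows a smooth latent curve
(random sigmoid, Gaussian bump, or ramp, normalized to [0.05, 1]).  Targets
blend the TF latent with an independent latent at weight `effect`
(default 0.9), then are linearly rescaled back to the common [0.05, 1] range —
a linear map that leaves all correlation structure intact while ensuring
planted targets are not distinguishable from null genes by dynamic range
alone.  Lagged targets shift the TF latent by `lag_bins / reference_bins` of
pseudotime; repressed targets invert it (annotated Repression); nonlinear
targets pass it through a Gaussian bump; null genes are independent latents.
Observed counts are NB draws around `mean_scale` (default 20) × latent with
dispersion 0.3, then an independent Bernoulli dropout mask (default 0.1)
zeroes entries — the standard two-part picture of scRNA-seq zero inflation.

Decoy regulons take a null gene as the TF and draw targets uniformly from the
full gene pool minus TF genes.  This mirrors the null model of the
significance test: a decoy's target set is literally a random draw, so it
*should* be non-significant.  (Restricting decoy targets to unrelated genes
only would plant a detectable distribution shift whenever most of the pool
carries planted signal — the test would then correctly, but uselessly, flag
decoys as non-random.)  Default decoy size equals the planted
targets-per-TF.

What the generator does **not** emulate: library-size and gene-length biases,
batch effects, doublets, discrete cell subpopulations along the branch,
branching topology errors, or realistic genome-scale shape diversity — with
three latent families, distinct TFs can share near-identical programs, which
makes small synthetic fixtures *harder* for correlation metrics than
comparably sized real data.  Passing tests therefore demonstrate the
statistical machinery (calibration, recovery, determinism), not performance
on any real tissue.

## Problem sizes used in tests and the acceptance script

Signal recovery runs at 1500 cells × 300 genes with ten 20-target planted
regulons and twenty decoys; null calibration at 1000 cells × 500 genes with
200 decoys; lag recovery at 1500 cells with five 10-target lagged regulons;
the robustness gate on a 30-cell high-dispersion noise branch (rejected)
versus a 1500-cell smooth branch (accepted).  Grid searches in these runs use
bins {8, 16} × smoothing {0.3, 0.7} with 10 subsample repetitions — a
deliberately compact grid; the chosen points sit well inside the acceptance
region and the full default grid changes none of the qualitative outcomes.

## Numerical choices and degenerate inputs

- Quantiles everywhere use linear interpolation between order statistics.
- IRLS clips the linear predictor to ±20 and dispersion to [1e−8, 100];
  convergence tolerance 1e−8 on the predictor, 50 iterations max.
- CV uses the sample standard deviation (ddof = 1).
- DTW cost ties break toward the shorter path, making the normalized
  distance well-defined and equal to exhaustive path enumeration.
- KS p-values are clipped to (0, 1]; direction ties (equal medians) report
  "below".
- Majority direction across background draws breaks ties deterministically
  (count, then lexicographic).
- All randomness flows from explicit seeds; parallel tasks derive sub-seeds
  as `sha256(seed:tag) mod 2^31 − 1`, so results are independent of
  scheduling and thread count, and full runs are byte-identical across
  repeats (manifests deliberately contain no timestamps).

## Known limitations

- Coexpression is correlative: a significant TF may be a passenger of the
  program it marks, and pseudotime direction need not be causal time.
- One TF at a time; combinatorial regulation is not tested.
- The ensemble minimum-FDR across metrics is reported without cross-metric
  correction (the most-significant-metric convention), so ensemble decoy
  rates run slightly above the nominal per-metric level.
- The ZINB spline treats zero inflation as a scalar mixture per gene, not a
  function of pseudotime.
- Spearman² saturates on heavily smoothed profiles with few bins (any two
  monotone curves correlate perfectly), which is why very coarse binnings
  discriminate poorly and the grid search rarely chooses them.
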