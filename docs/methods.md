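# Methods

This note records the models, conventions and design choices behind
`urbwell`, in the spirit of a statistical package's methods appendix.
It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Natural-city delineation

Urban extents are defined from data rather than administrative lines:
bright connected components of a nighttime-light raster above a
head/tail-breaks threshold.

**Head/tail breaks.** The recursion starts from all finite cells;
each iteration computes the subset mean and keeps the strictly-above-
mean head ("above the mean" is implemented as a strict `>`). An exact
head = tail split is generally unattainable on real data, so the
recursion stops when `|head − tail| / subset ≤ balance_tol` (default
0.05), when the head empties, or at `max_iter = 20` (the trace is then
flagged non-converged). The trace records every iteration mean and the
fraction of *all* cells above it — the former is nondecreasing, the
latter strictly decreasing, and both are asserted as properties.
Thresholding is scale-equivariant: scaling the raster by c > 0 scales
every trace threshold by c and leaves the masks unchanged.

**Components and rings.** Components use 8-connectivity by default
(4 available) with a 4-cell minimum size. Year-ordered masks are
stacked by cumulative union — sensor noise can shrink a raw mask
between years, and nested rings require monotone boundaries — and ring
U_t collects cells first urban in year t. Areas come from
`cell_size²`, which assumes an equal-area projection; geographic
inputs must be projected first.

**Common threshold per city series.** Within the pipeline, one
threshold (the median of the per-year head/tail thresholds) is applied
to every year of a city's series. The per-year recursion's stopping
depth is discrete and can jitter between adjacent iterations; an
overshoot year would then swallow several later rings. A common cut
keeps annual boundaries comparable — defensible for a jointly
calibrated series — while `head_tail_threshold` itself remains a
strictly per-raster operation. Per-year thresholds remain available by
composing the primitives directly.

**City inclusion.** Downstream analysis keeps cities with more than
10 nonempty rings, at least 50 posts in every ring, and at least 2000
street-view sample points; each exclusion is logged with its reason.

## Well-being stratification

Posts carry a sentiment score in [0, 1]. Within each ring the levels
P1..P8 are the 10th–80th percentiles of the score multiset, computed
by linear interpolation between order statistics (numpy's default
"type 7" rule; the convention is recorded in CLI output because other
software defaults differ). Percentiles are monotone in the level index
and shift-equivariant, both asserted as properties.

The Gini coefficient is computed by the sorted-cumulative (Lorenz)
identity `G = Σ (2i − n − 1) x_(i) / (n²μ)`; the O(n²) pairwise form
is kept in the package as an independent oracle and the two are
asserted equal to 1e-12. Level trends are OLS of the level value on
the ring index, with the slope reported ×100 as percentage points per
gradient step (rings are one per year, so this is also percent per
year); a constant series returns slope 0 with p = 1. The disparity
statistic defaults to P8 − P1 per ring and is pluggable; the package
does not claim any particular published disparity value is this exact
statistic, and only relative changes are compared against planted
ground truth.

## Street ecology

GN/GY/OP/CR are sums over the N = 4 view angles of per-image pixel
fractions of the vegetation / built / open / mobile class groups
(19 Cityscapes-style classes; "ground" is accepted as a synonym of
"terrain" in input headers). When the classes tile every image,
GN + GY + OP + CR = N exactly; the indices are invariant to scaling
counts and totals together. `SE = (GN·OP)/(GY·CR)` is undefined at
GY·CR = 0 by default; an optional ε floor handles vegetation-only
points explicitly, because silently substituting a denominator would
move zone means. Zone aggregation defaults to the arithmetic mean of
per-point SE (matching the per-point definition); the SE-of-mean-
fractions alternative is a switch.

## Association battery

All factor columns are min–max normalized per run (idempotent by
construction). The factor registry holds the 11 candidates SE, NDVI,
AT, RD, POP, PS, GDP, GN, GY, OP, CR; "PD" is accepted as an alias of
POP, flagging a naming ambiguity in common usage.

**Stepwise regression.** Forward selection enters the candidate with
the largest partial F; its p-value is Bonferroni-adjusted over the
candidates scanned in that step and compared with `alpha_enter`
(default 0.05) — so `alpha_enter` is a family-wise false-entry rate
per step, which keeps pure-noise panels mostly empty and makes planted
active sets recoverable with high specificity. Backward elimination
removes retained variables whose t-test p exceeds `alpha_remove`
(default 0.10). A no-revisit guard on retained sets and a perfect-fit
guard (no F-tests on numerically zero residuals) guarantee
termination. Near-collinear candidate matrices (condition number
> 1e10) are rejected up front with the offending pairs listed. Factor
importance is the retention count across all city × level models, ties
broken alphabetically and flagged.

**Geodetector.** `q = 1 − SSW/SST` over a stratification; continuous
factors are discretized into k = 5 equal-frequency bins, interactions
overlay two stratifications via the label product, and strata below 2
observations are merged into a neighbour. Significance uses label
permutation (default 999 replicates; the pipeline uses 199 for its
demo scale) rather than the noncentral-F approximation — exact
small-sample behavior with no distributional tables. Refining a
stratification never decreases q; this monotonicity is asserted.

**Regression discontinuity.** Two independent lines are fitted
strictly left and right of a cutoff (default: midpoint of x; the
cutoff is an explicit parameter because no canonical choice exists),
and `δ = |left(c) − right(c)|`. δ below 0.05 is read as consistent
with a single linear relationship, justifying the linear stepwise
models.

Correlations are Pearson r with unadjusted two-sided p-values
(stars at p < 0.05), with an optional Benjamini–Hochberg switch;
zero-variance columns are flagged rather than raised.

## Synthetic cohort

The generator produces every input the analysis consumes, with
planted structure the pipeline must recover. One root seed feeds
fixed-offset child streams per stage, so any stage can be regenerated
in isolation, bit-identically.

* **Nighttime light.** Pareto background (shape 1.5 by default)
  saturated at 30% of the core intensity — real sensors are
  radiance-limited, so the rural tail is heavy but bounded — plus
  disk-shaped cores whose radius grows 1.5 cells/yr from 6 cells.
  Core brightness decays parabolically from center to rim; under the
  disk's area measure that makes core brightness uniformly
  distributed, so the head/tail recursion terminates at a spatially
  coherent inner-disk cut instead of chasing an asymmetric tail.
* **Sentiment.** Beta(mean·κ, (1−mean)·κ) per ring. The default
  schedule raises the mean 0.004/ring from 0.68 and the concentration
  κ by 1/ring from 25, planting an upward trend in every level that is
  strongest for P1, and a shrinking P8 − P1 disparity. Ground truth is
  analytic (Beta quantiles), not simulated.
* **Street scenes.** Multinomial counts over the 19 classes, 4 views
  per point, 1000 pixels per image (a fraction large enough for
  stable ratios, small enough for fast tests). Two optional realism
  knobs, both off by default so the exact conservation contract holds:
  per-point Dirichlet heterogeneity around the zone mixture, and a
  void (unlabeled) pixel share. The pipeline enables both (void 5%)
  — without a void share GN + GY + OP + CR is identically 4 and the
  factor matrix is exactly collinear, which real segmentation output
  is not.
* **Panel.** Factors i.i.d. Uniform(0, 1), response
  `P = β₀ + Xβ + ε` with a sparse planted β (default 0.5·SE +
  0.3·NDVI, σ = 0.05); the generating coefficients, active set and
  noise realizations are returned for recovery tests.

**What the generator does not emulate:** spatial autocorrelation in
covariates beyond smooth ramps, post-level confounding between
sentiment and the factor surfaces, sensor cross-calibration artifacts,
irregular city shapes, and temporal non-stationarity within the
acquisition window. Passing tests therefore demonstrate correctness
of the estimators and the pipeline's plumbing under the stated
generating laws — not robustness to every pathology of the real data
sources.

## Demo scale and determinism

The integration demo uses 3 cities on 120×120 grids, 15 annual rings,
200 posts and 170 street points per ring, and a 500-zone panel —
large enough that every inclusion criterion is met (more than 10
rings; at least 50 posts/ring; at least 2000 street points) and that
per-city stepwise has more rows than candidates + 2, small enough
that the full run completes in seconds. Deterministic: identical
configs produce byte-identical artifacts, asserted via report
checksums.

## Known limitations

* Head/tail breaks assumes a genuinely heavy-tailed raster; a near-
  constant raster is rejected as degenerate rather than thresholded.
* The stepwise importance ranking on the observed synthetic panels
  reflects which planted gradients survive min–max normalization and
  ring averaging — it is a plumbing check, not a substantive ranking.
* Geodetector permutation p-values are resolution-limited by the
  replicate count (1/(B+1)).
* Areas are only meaningful on projected grids; no reprojection is
  performed.
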