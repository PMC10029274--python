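# Methods

This note documents the models, procedures, parameter choices and known
limitations of `darshape`. It complements the README's overview with the
detail a user needs to judge what the package computes and what its tests
do and do not demonstrate.

## Data model and extraction pipeline

Input is a relocation table per cohort: individual ID, timestamp, planar
projected X/Y in meters (e.g. Israeli Transverse Mercator), and an
optional per-fix accuracy estimate (STD, meters). Coordinates are consumed
already projected; no geographic support is included, since the diel
geometry is entirely planar. Timestamps are stored UTC and interpreted in
one configured IANA timezone for the whole dataset (default
`Asia/Jerusalem`); the 10:00 diel boundary is a *local clock* time, so
daylight-saving transitions shift the UTC boundary with the zone. Whether
the boundary should follow standard or daylight time is not fixed by the
protocol; using the civil local clock is this package's choice, and the
zone is configurable.

Extraction stages, in order, with defaults (all configurable via
`RunConfig` / YAML):

1. **Accuracy filter** — drop fixes with STD > 50 m.
2. **Speed filter** — a sequential forward pass drops any fix implying
   > 15 m/s from the previously *retained* fix. The forward-pass form (not
   pairwise against the raw predecessor) is the standard telemetry
   cleaning behavior: after a spike is removed, the next fix is judged
   against the last trusted position.
3. **Diel segmentation** — fixes partition into [10:00 d, 10:00 d+1)
   windows, left-closed: a fix at exactly 10:00 opens the new night.
4. **Night quality** — a complete night has strictly more than 1000 fixes,
   starts before 21:00, and ends after 02:00 (next day). Comparisons are
   strict. The fix count is taken after the accuracy/speed filters
   (whether the published protocol counted before or after filtering is
   unstated; after-filtering is the conservative choice here).
5. **Individual inclusion** — individuals with strictly more than 30
   complete nights are retained.
6. **Flight/stop segmentation** — the reference implementation used by the
   original field protocol (`AdpFixedPoint` from an ATLAS toolbox) is not
   published in detail; `darshape` substitutes a simple, pluggable
   segmenter designed for the only property the pipeline needs: the
   positions of the first and last flight of the night. A fix is
   provisionally "move" when the median speed over a centered 60 s window
   exceeds 2 m/s; provisional runs shorter than 60 s are merged into their
   neighbors, shortest first, which is deterministic. With ±5 m
   accuracy at 8 s cadence, stationary jitter implies apparent speeds
   around 1 m/s, so the 2 m/s threshold separates roosting jitter from
   flight (owl commuting flight is several m/s) while occasionally
   producing a spurious short run at a night edge — which reproduces the
   documented NA mechanism below.
7. **Endpoint averaging** — the start point is the coordinate-wise mean of
   the n = 20 fixes immediately before the first move run; the end point
   the mean of the 20 fixes after the last move run. If fewer than 20 such
   fixes exist the endpoint is *missing*; rows with missing metrics are
   dropped before clustering (reported as a count). This is the intended
   NA mechanism: flight detected right at the window edge leaves no
   averaging buffer. Nights with no flight at all fall back to the first
   and last 20 fixes and carry a `no_flight` flag (these all-night roost
   stays are excluded from the size model by default, since a bird that
   never left its nest has no meaningful routine size; the exact exclusion
   rule is configurable).
8. **Subsampling** — one point per 5 min (first fix in each bin of a grid
   anchored at the night's first fix; deterministic, keeps a subsequence).
   The whole-path metrics are insensitive to the choice between 2 and
   10 min; the test suite verifies < 10% relative drift across that range.

## Whole-path metrics

Computed per DAR on the subsampled points with the averaged start and end
points included in the point set — that inclusion makes the invariant
chain net displacement ≤ max displacement ≤ max diameter and
width ≤ diameter hold unconditionally, and is numerically negligible
otherwise. Internal unit meters, reported unit km.

The diameter is found exhaustively (O(n²)) up to 500 points and via convex
hull above (every diameter endpoint is a hull vertex; the hull-restricted
search is exact, and degenerate collinear sets fall back to brute force).
Ties break to the lexicographically smallest index pair. The width uses
the *infinite* line through the diameter pair, with offsets signed by
left/right of the directed diameter, so "either side" is well defined; a
side with no points contributes zero.

A transverse routine is one whose width is less than a quarter of its
diameter. (The prose definition in the source literature inverts the
inequality — diameter "considerably less than" width — which contradicts
its own numeric tables; the tabulated pattern, width < diameter/4, is what
is implemented.)

## Clustering and the choice of k

The four metrics are z-scored ((x − mean)/sd, sd with ddof = 1, matching
R's `scale`) after dropping rows with any missing metric; a zero-variance
column is a hard error. Ward linkage on Euclidean distances uses the
criterion-correct (ward.D2) form, so R `hclust(method="ward.D2")` on the
same matrix reproduces the tree. Cuts are labeled 1..k in order of first
row occurrence; rows are sorted by DAR id first, making the whole pipeline
deterministic byte-for-byte.

wss(k) is recomputed by re-partitioning at each cut (the definition used
by the common R elbow-plot helpers), not from merge heights. The candidate
rule for k: every k whose relative slope change f(k) exceeds its preceding
neighbor's, ranked by f(k) descending; the smallest k with an f value
qualifies when f is positive (it has no preceding neighbor; a linear wss
decline therefore yields no candidates). The final choice of k is the
caller's — the heuristic deliberately returns a ranked list, because the
trade-off between ecological resolution and statistical power is not a
property of the data alone.

## PCA and the composite size variable

All four metrics are lengths in km, so the PCA is run on the *covariance*
of the raw km values (the R `prcomp` default). This matters: net
displacement correlates only weakly (< 1/3) with the other three metrics
in routine-dominated cohorts, which mathematically caps the first
component of a *correlation* PCA near 74% of variance; on the covariance
of same-unit values PC1 captures ~80–94% depending on the cohort, with the
qualitative structure that motivates the method — PC1 all-positive
(extent), PC2 dominated by net displacement (openness), PC3 contrasting
width with the displacement measures (elongation). A `scale=True` option
provides the correlation variant for comparison. Components are
sign-flipped so loading sums are positive; eigenvalues come from a 4×4
`eigh`, so scores·loadingsᵀ reconstructs the centered matrix to machine
precision.

The mixed model needs a nonnegative size variable so its square root is
real, but a PC1 *score* is centered and signed. Two conventions are
implemented: the default weights the raw km metrics by the PC1 loadings
(nonnegative by construction, linear, and identical to the PC1 score up to
an additive constant — so identical in rank); the alternative shifts the
PC1 score by its minimum. On small or degenerate cohorts PC1 can fail the
all-positive condition; the pipeline then falls back to the shifted-score
convention and records that in the run report.

## Cohort analyses

- **Quadrimesters** of the annual cycle: Feb–May (breeding), Jun–Sep
  (rearing), Oct–Jan (recovery), January attaching to the cycle that began
  the previous October.
- **Start locations**: k-means (k = 3 by default, 25 restarts, fixed seed)
  on DAR start points, with the inertia-vs-k curve returned for visual
  elbow inspection.
- **Distributions**: group × cluster counts and row-normalized
  frequencies, plus mean ± SD of per-individual frequencies; Pearson
  chi-squared without continuity correction, flagging tables with expected
  counts below 5. Cluster-distribution analyses use age at assignment;
  the mixed model uses age at the DAR's date when a birth date is known
  (young ≤ 1 year). Both conventions are available.
- **Size model**: a linear mixed model on √size with identity link and
  Gaussian errors — the square-root transform plus residual normality
  checks is what the "GLMM" amounts to. Random intercepts for individual
  (repeated measures) and calendar night (shared environmental conditions)
  enter as crossed variance components (statsmodels `MixedLM` on a single
  grouping); a reduced model with only the individual intercept is used
  for calibration simulations. Optimizers are tried in a fixed sequence
  (bfgs, lbfgs, powell, cg) until convergence; non-convergence is an
  error, never a silent result. Interaction (sex × age) fits report the ML
  AIC of the additive model alongside for the information-theoretic
  comparison. Residual diagnostics (histogram, normal QQ pairs, residual
  SD by fitted-value quintile) use marginal residuals, which are robust to
  boundary (zero-variance) random-effect estimates.

## Synthetic archetype generator

The generator emulates the *geometry and sampling regime* of reverse-GPS
owl nights, not behavior. Each night is: a stationary roost phase
(Gaussian jitter, default 5 m, matching the tracking system's nominal
accuracy) from 18:00; a waypoint excursion between 19:30 and 03:00 — out
via one lateral flank of the excursion axis, a long dwell at the far
point, back via the opposite flank, ending at a (possibly displaced) final
roost; then roost until 04:00. At the default 8 s cadence a night has
~4500 fixes and passes every completeness rule by construction. The
waypoint layout targets the whole-path metrics directly: far-point
distance = diameter, flank offsets = width, final-roost displacement =
net displacement. Dwells at the geometric extremes are what make the
metrics insensitive to subsampling, mirroring how a foraging bird
actually accumulates fixes at the places that define its routine's
extent. Flight legs run at 6 m/s (short hops slower, so every leg outlasts
the segmenter's 60 s minimum run).

The seven archetype presets target the published per-category means: max
diameter 0.79/1.7/2.4/3.6/3.5/6.1/4.8 km, the corresponding
width/diameter ratios, and net displacements 0.11/0.10/0.41/0.07/0.09/
0.13/4.1 km. Night-to-night variation is multiplicative jitter (5%
relative SD) on scale, width ratio and openness, with realized openness
proportional to the night's realized diameter. The jitter is deliberately
far below the within-*cluster* SDs of real data: the generator's contract
is that archetype centroids in z-scored metric space sit at least 3
within-archetype SDs apart, so clustering tests have unambiguous ground
truth. Consequently, passing recovery tests demonstrates pipeline
correctness on separable structure — they say nothing about how real,
overlapping routines would partition, where cluster identity is partly a
modeling choice. Other real-data features the generator omits: missing
stretches when animals leave receiver range, heavy-tailed localization
error, multi-trip nights, and any landscape or memory effects.

Cohort presets: `pure_archetype_cohort` (one individual per archetype —
exact ground truth for recovery tests) and `owl_cohort` (mixture with
realistic proportions 27/28/16/8/10/8/3%, modulated so males do relatively
more medium/large excursions and young more large excursions, giving the
size model a known direction to recover). A defect injector adds accuracy
outliers (STD 60), speed outliers (2 km jumps), and data gaps at given
rates for filter tests.

## Numerical and design choices

- All randomness flows through seeded `numpy` generators threaded into the
  specs; per-individual streams are derived as `default_rng([seed, index])`
  so cohorts are reproducible and order-independent.
- Determinism everywhere: mergesort for stable sorting, fixed tie-breaks
  (lexicographic diameter pair, smallest-merge Ward tie-break via scipy,
  first-occurrence label numbering, fixed k-means seeds).
- z-scoring uses ddof = 1; wss is computed in standardized space.
- Degenerate inputs: empty tracks and nights are legal (empty outputs);
  a single point has diameter 0; coincident diameter pairs give width 0;
  fewer than 2 fixes is a single stop segment; empty DARs are an error at
  the metric stage.
- Problem sizes in the test suite (7×50-night and 8×45-night cohorts,
  1000-replicate null and 200-replicate coverage simulations at 24×15 and
  40×100) were chosen as the smallest sizes at which the tested
  quantities' sampling noise is comfortably below the asserted margins.

## Known limitations

- The flight/stop segmenter is a stand-in for the unpublished reference
  algorithm; only the first/last flight boundaries it produces are
  consumed, but nights whose fine-grained move/stop structure matters
  should use a dedicated segmenter through the same interface.
- Metrics are scalar whole-path summaries by design; area coverage,
  tortuosity and step statistics are out of scope (they characterize
  sub-daily behavioral modes, not diel routines).
- The mixed model assumes Gaussian errors on the √ scale; strongly
  zero-inflated cohorts (many all-night nest stays) should be filtered, as
  the default configuration does, or modeled differently.
- Wald confidence intervals and p-values from `MixedLM` are asymptotic;
  the calibration tests bound their small-sample behavior only for the
  simulated designs described above.
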