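# Methods

## Model and procedure

`densitygate` treats clustering as peak finding on the event-count histogram.
The density model is nonparametric: populations are regions of high event
density separated by lower-density saddles, with no assumption on shape,
orientation or number.

**Binning.**  All axes share one bin number N; each axis spans its own
[min, max] with equal widths.  N is selected by exhaustively scanning
N = 1..N_max and maximizing the Bayesian equal-width-histogram posterior
(see README); the scan is exhaustive because the posterior can be multimodal,
and ties go to the smaller N.  N_max defaults to min(200, ⌈n^(1/D)⌉ + 50),
which comfortably brackets the optima observed on event data of 10⁴–10⁶
rows.  Bins are upper-edge inclusive — a value x lands in bin
⌈(x − lo)/w⌉ − 1, clipped — so the column minimum sits in bin 0, the maximum
in bin N − 1, and no event is dropped.  Binning depends only on each value's
position within its column's range, so any strictly increasing affine
transform of a channel leaves histograms, posteriors and the optimal N
unchanged.  Constant columns degenerate to a single occupied bin with a
warning.  Grids are stored sparsely (occupied bins only); dense arrays are
materialized only below 2·10⁷ cells.

**Cross sections and aggregates.**  The cross section at integer LEVEL is the
set of bins with content strictly greater than LEVEL; a histogram whose
fullest bin holds level_max events therefore has level_max distinct sections
(LEVEL = level_max − 1 … 0).  Aggregates are connected components under the
full diagonal-inclusive (Moore, 3^D − 1) neighborhood.  `label_aggregates`
implements the percolation-style three-step labeling: sentinel
initialization, one lexicographic raster scan that examines the causal half
of the Moore neighborhood (in 2D: up-left, up, up-right, left — the two
"next-nearest" diagonal links are what keeps elongated slanted aggregates
whole) and records label equivalences in a chain vector resolved to its
smallest member, then a second scan rewriting every cell to its root.

**The sweep.**  Levels are processed top-down.  Per aggregate of the current
section there are three cases: no tracked peak inside (a new peak emerges,
recorded with its characteristic position — the lexicographically first bin
of its emergence aggregate — and its top bin, the fullest one); exactly one
peak (growth, nothing to decide); several peaks (a merge).  At a merge, each
constituent that was still single is tested with the significance rule at the
merge level.  If every constituent was single and at most one is major, only
the highest peak (largest top level, ties to the smallest code) survives —
this absorbs the small nearby bumps that typically herald a major peak.
Otherwise small single peaks are eliminated, and each major single peak is
finalized: its aggregate from one level above the merge (its largest
still-separated cross section) is copied into the final label grid and the
merge level becomes its saddle L_s.  Peaks still single at level 0 contribute
their level-0 aggregate with L_s = 0.  Events in final-grid bins form the
clusters; all others stay unassigned.

Two engines share the per-aggregate dispatch.  The production engine
activates occupied bins in decreasing content order into a union-find forest,
visiting only the levels where the thresholded set changes — O(B·3^D + sort)
work in the number of occupied bins B.  A reference engine thresholds and
relabels every integer level from scratch.  The suite asserts bit-identical
registries, final grids and clusters between them; both order same-level
aggregates by their lexicographically first bin so peak codes are
deterministic.

**Significance rule.**  Bin contents are binomial, approximately Poisson once
the local mean exceeds ~10.  b̄ is estimated as the mean of a bin and its
existing face-adjacent neighbors (boundary bins average fewer terms).  b̄_p
is taken at the peak's top bin; b̄_s at the saddle bin, defined as the
fullest bridging bin — a bin present in the merged aggregate at the merge
level but in none of the constituents one level above.  The threshold
L_p − L_s > 2√(b̄_p + b̄_s) is strict, and b̄_p < 10 forces "small".  This is
a fixed two-standard-deviation heuristic, reproduced as such — no p-values or
multiplicity control.

**Reliability.**  f = (L_p − L_s)/L_p, reported per cluster; f = 1 for peaks
that never met a retained peak (including the degenerate L_p = 0 case).  It
measures how far above its highest saddle a peak stands: heavily overlapping
populations give small f.

**Cluster output.**  Clusters are sorted by descending population and coded
1, 2, …; summaries report code, L_p, L_s, C (events), bin count, f (3
decimals) and the per-channel mean of members.  Assignment files carry one
row per event with code 0 for unassigned.

**High dimensions.**  Direct histogramming is refused above the critical
dimension (default 5, configurable): run time, events needed for an adequate
histogram, and grid memory grow super-linearly with D.  Instead the data is
centered and projected onto the eigenvectors of its covariance matrix with
the largest eigenvalues (sign convention: largest-magnitude component
positive), clustered in the subspace, and memberships mapped back; centers
are recomputed in the original space.  The retained-variance fraction is
exposed as a diagnostic because the projection can fold separated peaks onto
each other and undercount clusters — there is no detection rule for this,
only the diagnostic.

## Synthetic data

Components are D-dimensional Gaussians with independent per-axis means and
SDs; a distorted component couples axis k1 quadratically onto axis k2,
X_k2 += s·(Δ₁·sd_k1)², with Δ₁ the k1 deviate of the same event.  Deviates
come from the Box–Muller transform of uniforms on (0, 1).  s ≈ 0.002–0.004
gives the banana-shaped populations typical of fluorescence channels; s = 0
is a plain Gaussian.  Everything is reproducible from a single seed.

Components accept an optional truncation radius on the standardized deviate
vector, applied by rejection (the retained density shape is exact — no
boundary pile-up).  Rationale: real cytometers acquire into a bounded ADC
range, so real populations have compact support, whereas an unbounded
Gaussian at any sample size leaves O(1) isolated single-event bins in the
density-falloff annulus around each population; the sweep faithfully reports
each such isolated bin as a one-event cluster.  The shipped benchmarks use
the 99.5% chi-square radius for their dimension.

Benchmark fixtures (defaults are the study conditions of the test suite):

* `four_gaussian_mixture_2d` — centers on the corners of a 420-unit square,
  per-axis SD 130 (separations 3.2 SD on the sides, 4.6 SD on the diagonal),
  fractions 0.3/0.3/0.2/0.2, s = 0.002, distortion axes (0, 1): four distinct
  peaks joined through nonzero saddles.
* `crescent_with_blob_2d` — a non-convex crescent (arc radius 250, radial SD
  30, angular SD 0.33 rad ≈ 98° span) plus a separated round blob.  The
  crescent's along-arc density scale (~83 units) is deliberately comparable
  to its radial SD: on a statistically *flat* crest (e.g. a uniform closed
  ring) the significance rule is scale-invariant in the bin content, so twin
  noise bumps split the crest at any sample size — a property of the method,
  not of the implementation.
* `add_uniform_background` — uniform contamination over the data's bounding
  box, for noise-robustness checks.
* `random_distorted_mixture` — eight 10D components with centers uniform in
  (0, 1000), per-axis SDs uniform in (0, 200), random distinct distortion
  axes, s = 0.004, ~5·10⁵ events: the high-dimensional benchmark.

What the generator does *not* emulate: spectral spillover/compensation,
doublets, boundary pile-up, autofluorescence or acquisition-time drift.
Passing tests demonstrate correct peak-finding on well-specified density
landscapes, not robustness to instrument artifacts; real data should be
compensated/transformed upstream.

## Numerical and degenerate-input choices

* Posterior evaluation sums log Γ over occupied bins only (empty bins cancel
  against the −N^D log Γ(½) term), so 5D grids at N ~ 60 are exact and cheap.
* The pipeline requires ≥100 events (configurable) and rejects all-identical
  data; a grid capacity error guards N^D beyond 64-bit flat indexing.
* Tie-breaks are lexicographic everywhere (characteristic position, top bin,
  saddle bin, retained peak at equal top levels) to keep output deterministic.
* Merges are detected through bridging bins, which always exist when
  aggregates coalesce; multi-way merges at one level are handled as one
  aggregate-level decision.
* Finalized aggregates are immutable; eliminated peaks are dropped from
  tracking entirely.

## Known limitations

* Two populations whose histogram shows a single peak are one cluster; a
  population split by a deep sampling dip can be reported as two.  The
  significance rule is a fixed 2-SD heuristic: on long statistically flat
  ridges it will split the ridge with seed-dependent frequency (see the
  crescent rationale above).
* A structure-free (flat) dataset is reported as **one** all-encompassing
  cluster — the method suppresses spurious *extra* peaks but always retains
  the highest one; it is not a test for the existence of structure.
* Tight clustering leaves saddle-region events unassigned by design; assigned
  fractions can be well below 1 for overlapping populations.
* Above the critical dimension, recovery depends on the principal-axis
  projection keeping peaks apart; undercounting is possible and only
  diagnosed, not corrected.
* The problem sizes exercised in the test suite — 10⁵-event 2D benchmarks,
  a 5·10⁵-event 10D benchmark, 10³ random labeling grids — were chosen as
  representative desk-scale workloads; the algorithms scale linearly in
  events and near-linearly in occupied bins beyond them.
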