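# Methods

This note documents the models, parameter choices, and numerical decisions
behind each `nichemech` module, and what the synthetic generators do and do
not emulate.

## FRET tension-sensor force mapping

**Model.** An RGD-presenting molecular tension sensor reports the force a
cell exerts on a single integrin attachment: stretching the sensor's elastic
domain separates the donor/acceptor pair, so FRET efficiency decreases
monotonically with force. Per pixel we compute the sensitized-emission
proximity ratio

    E = A′ / (A′ + γ·D′),    D′ = donor − bg_d,    A′ = acceptor − bg_a − β·D′

with donor bleed-through β (default 0) and detection ratio γ (default 1) as
explicit parameters, because the appropriate correction factors depend on
the filter set and camera. Pixels whose corrected total intensity `D′ + A′`
falls below an intensity floor are marked invalid, not clamped — a dim pixel
carries no usable ratio. Valid efficiencies are clamped to [0, 1].

**Calibration.** The force→efficiency relation is supplied as a table of
strictly increasing forces and strictly decreasing efficiencies and is
inverted by monotone piecewise-linear interpolation; efficiencies above the
zero-force node clamp to 0 pN and below the full-scale node to `F_max`.
This makes thresholding consistent by construction: selecting pixels with
force > F_t is identical to selecting E < cal(F_t). The packaged
`CalibrationCurve.default_synthetic()` (0 pN → 0.90 down to 10 pN → 0.15 in
six nodes) is a synthetic curve for tests and demonstrations, not a measured
property of any sensor construct; real analyses must supply their own
measured calibration.

**Adhesion segmentation.** Candidate pixels are valid, inside the cell
mask, and above the force threshold; 8-connected components smaller than
`min_area` are discarded. The default threshold corresponds to an
efficiency drop of 0.1 below the resting efficiency, and the default
`min_area` of 0.5 µm² mirrors the common "analyze particles, size =
0.5–infinity" convention for focal adhesions; both are plain parameters.
With splitting enabled, touching components are divided by a watershed on
the negated force map. Seeds are the h-maxima (prominence ≥ 0.5 pN by
default) of a σ = 1 px Gaussian-smoothed copy of the force map: the
smoothing prevents shot noise from spawning spurious seeds, the prominence
criterion makes a flat-topped adhesion yield exactly one connected seed
region, and seed regions closer than the configurable minimum separation
are merged. The flooded surface itself is the unsmoothed force map.

**Per-cell and group summaries.** A cell is force-producing when it has at
least one surviving adhesion. Its average adhesion force is pixel-weighted
by default (each adhesion pixel counts once), with an unweighted
per-adhesion mean as an option, since either convention is defensible and
they differ when adhesion sizes vary. A cell with no adhesions has an
*absent* average force (None), never 0 — including zeros would conflate
"no measurable adhesion" with "adhesions at zero force". Group comparisons
therefore default to force-producing cells only. Animal means are compared
by the two-tailed Mann–Whitney test; the proportion of force-producing
cells by the two-sided Fisher exact test on pooled cell counts. When the
2×2 table has a zero margin (e.g. every cell in both groups is
force-producing) no association is testable and the comparison is reported
as degenerate with p = 1.

## Assay quantifications

- Detachment (enzyme): percent remaining = 100 × (count after)/(count
  before), counts restricted to an ROI that excludes a border band
  (debris collects at well edges); the band width is a parameter (250 px in
  the original whole-well setup).
- Centrifugation: percent of area covered by cells inside a centered
  circular crop (radius parameter; 700 px originally), before vs after
  spinning. The remaining ratio is implemented as 100 × after/before so
  that, like the enzyme assay, larger values mean stronger adhesion; the
  opposite printed order appears in some protocol descriptions, and the
  orientation here is a deliberate consistency choice.
- Dispersion: the initial spot perimeter is the set of foreground pixels
  4-adjacent to background; the dispersion distance is the maximum
  pixel-center Euclidean distance from any cell pixel *outside* the initial
  mask to that perimeter, and 0 when no cell has left the spot. This is
  monotone non-decreasing for nested masks.
- Particle counting and masked intensity follow the explicit-threshold
  convention: thresholds are arguments, never silently auto-chosen (an Otsu
  helper exists for exploration). Watershed splitting of touching particles
  seeds from connected maxima of the Euclidean distance transform.

## Tracking

Detections are linked frame-to-frame by repeated mutual-nearest-neighbor
rounds: a track end and a detection pair when each is the other's nearest
feasible partner (ties to the lowest index, so linking is deterministic for
sorted input). A link is feasible within `max_displacement × (gap + 1)`,
and tracks may bridge up to `max_gap` missing frames. Track velocity is the
mean instantaneous path speed — total path length over duration — matching
the "track velocity" convention of commercial trackers; net-displacement
speed is available separately. Tracks shorter than `min_frames` (default 5)
are excluded as transient. This linker does not handle track splitting,
merging, or mitosis.

## Niche geometry

All geometry is 2-D on z-projected sections. Distances are minimum
point-to-segment Euclidean distances to the ventricle-border polyline
(shapely). The analysis band default of 200 µm from the ventricle wall
excludes striatal astrocytes. Boundary behavior is deterministic and
inclusive: a point on the border is at distance 0, inside the band, and
inside a region polygon. Marker panels are closed-world decision tables
(GFAP⁺/Ki67⁻ → qNSC/astrocyte, GFAP⁺/Ki67⁺ → aNSC; S100a6 analogous;
EdU⁺ cells are neuroblasts if DCX⁺ and aNSC/NPC if Ki67⁺/DCX⁻); anything
else is "unclassified", and vessel-adjacent cells — an input flag, set
manually upstream — are censored. EdU labeling efficiency is |EdU⁺|/|Ki67⁺|
within the SVZ.

## Single-cell signatures

Expression is CP10K log-normalized with the natural log,
`ln(1 + 10⁴·c/total)`; a cell's signature score is the sum of normalized
values over the gene set's members present in the matrix. Set members
absent from the matrix are dropped *with a reported count* rather than
silently, and an empty intersection is an error (a uniformly zero score is
indistinguishable from real silence). Scores are additive over disjoint
sets and invariant to gene column order. Downsampling a large group to a
smaller one's size is a seeded uniform draw without replacement and never
alters per-cell values. Decile association ranks genes by promoter
accessibility with a stable sort (ties keep input order), splits them into
10 equal-count bins (sizes differ by ≤ 1), and reports each bin's
expression distribution; it is descriptive, with no fitted model. The
bimodality report (Sarle's coefficient plus a histogram) is likewise
descriptive only — no calibrated test is claimed. Clustering, cell-cycle
scoring, and differential expression are out of scope; group and cell-type
labels are inputs.

## Statistics

All tests are two-sided. The Mann–Whitney statistic is
`U = #{x>y} + 0.5·#{x=y}` (mid-ranks); the exact branch is used whenever
`C(n+m, n) ≤ 2×10⁵` labelings, and the two-sided p doubles the smaller of
the two observed tail probabilities (capped at 1). For tie-free data the
labeling distribution is computed by the classical rank-sum counting
recursion — mathematically identical to listing all labelings, and cached
by (n, m); with ties the labelings are enumerated explicitly so ties are
handled exactly. The large-sample branch uses the normal approximation with
tie-corrected variance and a 0.5 continuity correction; at n = 15 per group
it agrees with the exact distribution to within 0.01 absolute. Fisher's
exact p sums hypergeometric probabilities of all tables (margins fixed) at
most as probable as the observed one, with a 1e-7 relative tolerance on the
probability comparison to absorb floating-point asymmetry between equally
probable tables. Wilcoxon drops zero differences, mid-ranks |d|, and
enumerates all 2ⁿ sign assignments up to n = 20, beyond which the
tie-corrected normal approximation applies. Every result records which
branch produced it. Reference-mean normalization divides each value by its
experiment block's reference-group mean. No multiple-testing correction is
provided; the assay comparisons are reported unadjusted.

## Synthetic generators

All randomness flows through numpy's PCG64 (`default_rng`); a fixed seed
reproduces every output byte-identically, and seeds are recorded in
outputs.

**Tension images.** Cells are disks (radius 6 µm by default) on a grid;
adhesions are ellipses rasterized at pixel centers with no anti-aliasing,
so ground-truth masks are exact. Semi-axes default to 0.5–1.2 µm by
0.4–0.6 µm (≈ 0.6–2 µm² — nascent-to-mature focal-adhesion sizes), and
placements keep adhesions inside the cell footprint and at least 0.5 µm
apart (focal adhesions are discrete complexes; separation keeps the ground
truth resolvable by segmentation); infeasible placements are resampled with
bounded retries. True efficiency is the resting value everywhere (the
sensor coats the whole substrate) except inside adhesions, where the
calibration maps the adhesion's force to its efficiency. Expected counts
are `donor = S(1−E) + B`, `acceptor = S·E + B` with S = 2,000 signal and
B = 100 background photons per pixel by default (conventional TIRF photon
budgets — no acquisition noise statistics were available to emulate);
observed images are Poisson draws. With noise disabled the expected values
are returned as floats so analytic round-trips are exact to 1e-9; the
nonnegative-integer-counts invariant applies to the (default) noisy images.
The default pixel size, 0.16 µm/px, is typical of a ×100 TIRF objective.
No PSF, drift, photobleaching, or camera read noise is simulated — passing
recovery tests therefore demonstrate correctness of the estimator under
shot noise, not robustness to optical blur or registration error.

**Migration.** Velocities follow a 2-D Ornstein–Uhlenbeck process
(relaxation time = persistence time, default 4 h) with exact per-substep
discretization (10 substeps per frame). Because a tracker measures speed
from positions sampled every `dt`, the per-component stationary scale is
calibrated analytically for the finite sampling interval (the variance
factor of the time-averaged velocity) so the mean *measured* step speed
equals the requested `mean_speed`. Cells start uniformly over a field that
scales with cell count (60 µm mean spacing) so that neighboring cells stay
distinguishable to a mutual-nearest-neighbor linker at the default
displacement gates.

**Other stages.** Detachment is i.i.d. Bernoulli retention of uniformly
placed cells. Sections place cells perpendicular to a uniformly random
point along the border polyline at distances drawn per group (constants,
gamma-parameterized (mean, sd) pairs, or any frozen distribution); the
recorded true distance is recomputed against the whole polyline, so it is
exact even near corners. Counts are negative-binomial with log-normal
per-gene base means, variance `µ + α·µ²` (Poisson at α = 0, default
α = 0.3), and the last-listed group's gene-set means scaled by
`exp(effect)`.

## Demonstration pipeline and problem sizes

The TOML-driven pipeline derives each stage's seed deterministically from
the run seed, so results are independent of stage selection, and numeric
report fields are rounded to 10 digits before serialization so reruns are
byte-identical. The shipped problem sizes — 20 cells × 3 adhesions for
force recovery, 500 cells × 41 frames for speed recovery, 100 repetitions
for power estimates, 200 seeds for detachment calibration, 1,000
point/polyline pairs for the geometry oracle, 10,000 null simulations for
Mann–Whitney type-I calibration — were chosen so each Monte-Carlo standard
error is comfortably below the tolerance being checked while the whole
verification completes in a few minutes on one core.

## Known limitations

- The efficiency model is a two-channel proximity ratio; acceptor-photobleaching
  FRET, flat-field correction, and channel registration are out of scope.
- The watershed split assumes adhesions are force maxima separated by lower
  ridges; adhesions merged at identical force with no valley cannot be split.
- The linker is greedy mutual-nearest-neighbor, not a global assignment; at
  high cell density or with crossing paths it can break or swap tracks.
- Geometry is strictly 2-D; distances in thick sections are projections.
- The exact-test enumeration caps (2×10⁵ labelings, 2²⁰ sign patterns)
  trade runtime for exactness; beyond them p-values are approximate and the
  output says so.
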