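# Methods

This note documents the models, parameter choices and numerical decisions
behind motility3d, and what the synthetic data do and do not establish.

## Input model

The unit of observation is a *track*: one cell's positions (µm) at strictly
increasing times (s).  Tracks carry a frame (imaging field) and tissue
label; a *TrackSet* groups them tissue → frame → cell.  Coordinates are
absolute within a frame; no cross-frame registration is attempted.  Tracks
with fewer than two points are dropped at load (counted, not silently).
Metrics with stricter needs (three points for turning angles and the MSD
fit) mark themselves undefined per cell rather than failing the set, and
undefined values propagate as NaN and are excluded pairwise — never imputed.

## Time-step normalisation

Step-based statistics (step speeds, turning angles, persistence) are only
comparable at a common sampling interval, and speed–turning-angle coupling
in particular is known to be sensitive to sampling rate.  All tracks are
therefore normalised to a nominal step (default **90 s**, tolerance 10 s)
before analysis.

A track whose median native step is already within tolerance passes through
unchanged.  A faster series is split into `k = round(target/native)`
interleaved subsamples: phase p starts at the p-th observation and greedily
takes, at each iteration, the sample nearest to (last time + 90 s),
stopping when no sample falls within the tolerance of the next nominal
time.  For an exactly regular series this reduces to strides
{t₀,t_k,t₂k,…}, {t₁,t_{k+1},…}, …, which partition the observations: every
point is used exactly once and none is fabricated (there is no
interpolation, by design).  Phase tracks inherit the cell id with a `.p<i>`
suffix and are treated as independent tracks downstream; phases left with
fewer than two points are dropped and counted.  Greedy nearest-time
selection (rather than a global assignment) is simple, deterministic, and
exact on regular or mildly jittered clocks; across a genuine acquisition
gap a phase simply ends.

The per-tissue report of realised steps uses the population (ddof=0)
standard deviation over all pooled consecutive intervals.

## Per-cell metrics

**Speeds.**  Cell-based speed is path length over elapsed time;
displacement speed uses only the first and last positions.  Times are kept
in seconds and positions in µm internally; speeds are converted to µm/min
at computation (×60).  The identity `meandering_ratio × cell_speed =
displacement_speed` holds algebraically and is asserted to machine
precision in the tests.

**Turning angles.**  The angle between consecutive displacement vectors,
in [0°, 180°].  Vectors of zero length leave the angle undefined; such
triples are skipped and counted.  An angle's *associated speed* is the
mean of its incoming and outgoing step speeds; angles with associated
speed below **1 µm/min** are flagged excluded (configurable), because a
nearly stationary cell's "turns" reflect localisation noise and pixel
quantisation rather than locomotion.  The symmetric in/out mean was chosen
over either single step because the threshold expresses "the cell is
moving" at that moment; the same associated speed is the quantity averaged
in the speed-vs-angle profile.  Histograms and profiles use **9°** bins;
the profile reports the per-bin population sd and sd/8, the conventional
half-error-bar for these heavily populated bins.

**Persistence likelihood.**  All consecutive same-cell step-speed pairs of
a tissue are pooled (m pairs).  For speed bin i (width 1 µm/min, top bin
open-ended at 12 µm/min by default), the ratio (m·m_ab)/(m_a·m_b) estimates
P(next speed in bin | current speed in bin) / P(next speed in bin).  Bins
with m_a·m_b = 0 are undefined.  Under independent speeds all ratios
converge to 1; autocorrelated speeds push the diagonal above 1, which is
exactly what the tests assert with i.i.d. and AR(1) sequences.  The pooled
pair count (rather than a per-track count) is the only denominator
consistent with the probabilistic definition.

**MSD exponent.**  Squared displacements from the *first* point,
d²_{1,k}, regressed on log elapsed time (least squares) for elapsed times
in (0, **10.5 min**]; zero displacements are excluded (log undefined) and
at least three usable points are required.  Only origin-anchored
displacements are used — no time-averaged overlapping windows — so the
exponent is exactly 2 for straight constant-speed motion, ≈1 for a random
walk, and invariant to logarithm base and rigid-body motion.  The cap
keeps long tracks from dominating the fit and makes exponents comparable
across tracks of different lengths.

**Confinement.**  Two related quantities in a **5 µm** ball with a
**150 s** dwell threshold.  *Confined ratio*: an anchor scan — the anchor
starts at the first position; the dwell runs while positions stay within
the radius of the anchor; when the dwell (anchor to last position inside)
exceeds the threshold the entire dwell counts as confined, and the scan
restarts at the exit position.  Counting the whole dwell, not just the
excess over 150 s, follows from defining the dwell interval itself as
confined time.  *Confined time*: for every position as anchor, the time
until the track first leaves the ball around it, averaged over all
positions (minutes).  Anchors whose ball is never exited contribute the
censored time to track end; censoring (rather than dropping) was chosen so
that fully confined tracks report their observed duration instead of
vanishing from the statistic.

**Patrolled volume.**  The track is translated so its bounding box is
centred in a **400 µm** cubic domain carved into **2.5 µm** voxels
registered to the domain origin.  A voxel is patrolled when its centre
lies within **5 µm** of any observed position or of any point sampled
every voxel/2 = 1.25 µm along the straight segments joining successive
positions; the sampling interval is below the voxel edge, so no reachable
voxel centre can be skipped between samples (verified against an
exhaustive grid scan, which the tests require to agree exactly).  Volume
is the marked count × voxel³; the rate divides by tracked time (µm³/s).
Because the grid is fixed while the track is translated, counts carry a
sub-voxel grid-phase sensitivity of order one voxel shell; the exhaustive
oracle uses the same registration.  A track wider than the domain leaves
the rate undefined for that cell (counted and reported).

## Group statistics

Cells are the sampling unit.  Pairwise tissue comparisons use the
two-sided **Mann–Whitney U** test — exact when both groups are below 50
values and tie-free, otherwise the normal approximation with continuity
and tie corrections — with **Bonferroni** multiplication by the number of
unordered pairs actually tested (6 for four tissues), capped at 1.  The
two-sample **Kolmogorov–Smirnov** test supplements the rank-sum for the
patrolled-volume distribution, where two tissues can share a median while
differing in shape.

Intra-tissue heterogeneity uses one-way fixed-effects ANOVA with imaging
frames as groups; inter-tissue ANOVA pools frames within tissues.  Groups
need at least two values, and zero pooled within-group variance is a
degenerate-input error rather than an infinite F.

**Outlier-frame reduction.**  Within a tissue (≥3 frames), frames are
removed greedily: at each step the frame whose exclusion most increases
the intra-tissue ANOVA p-value is dropped (ties broken by frame id), and a
removal is accepted only if the p-value does not decrease, making the
reported p trajectory non-decreasing by construction.  Iteration stops
when p ≥ 1e-4, when 55 % of the frames have been removed, or when no
removal helps (flagged as non-converged).  The criterion and stop rule are
this package's own formalisation of "remove the most variable frames";
both are configurable.

## Synthetic cohorts

`simulate` provides seedable walker populations with known ground truth:
*ballistic* (fixed heading), *brownian* (i.i.d. isotropic headings),
*persistent* (heading perturbed by a von Mises–Fisher draw with
concentration κ; vMF was chosen as the canonical rotationally symmetric
family on the sphere with a single concentration parameter and a cheap
exact sampler), *back_and_forth* (heading reversed with probability
`reversal_prob`, jittered by the same vMF family), and *confined*
(isotropic proposals rejected outside a tether ball; a cell with no
admissible step stalls in place, yielding stop-and-go behaviour).  Step
speeds are normal, truncated at zero, optionally with a per-cell mean
drawn from a population distribution (cell-level heterogeneity, which is
what makes persistence ratios exceed 1).  Cohorts organise walkers into
tissues and frames; each frame draws one speed offset, creating the
frame-level heterogeneity that the ANOVA and reduction stages consume.
Identical spec + seed reproduces the TrackSet bit for bit.

The default `study_cohort_spec` mirrors a four-tissue intravital study:
LN (40 frames × 110 cells, fast persistent walkers, strong frame
heterogeneity), villi (10 × 43 at 45 s sampling, exercising the
phase-complete resampler), lung-flu (5 × 71, reversing walkers with a
turning-angle mode near 160°, mixed with tether-confined walkers), and
lung-LPS (3 × 64, near-Brownian and confined walkers, negligible frame
heterogeneity).  Track lengths are 6–30 points at 90 s (11–59 at 45 s),
matching the short, variable tracks of two-photon imaging.

**What the generator does not emulate.**  Each synthetic cell keeps one
motility mode for its whole track, whereas real lung T cells alternate
confined and running phases; a single-mode walker therefore cannot be
simultaneously fast (path speed ≈ 5 µm/min) and half-confined the way
real lung cells are, and the synthetic lung tissues land slower and less
confined than their biological counterparts while preserving every
qualitative ordering (LN/villi fast, straight, superdiffusive,
large patrolled volume; lung slow, reversing/confined, sub-Brownian,
small patrolled volume).  Localisation noise, tissue boundaries, cell–cell
interactions and drift are likewise out of scope.  Passing tests on these
cohorts establish the correctness of the *computations* and the expected
behaviour of the statistics under known ground truth — not biological
conclusions about any real tissue.

## Problem sizes

The default test suite runs cohorts at 3–20 % of study scale and the
distributional checks at 10⁴–10⁵ samples, which keeps the whole suite
under a minute while leaving every assertion tolerance comfortably wider
than the corresponding sampling error.  `scripts/acceptance.py` runs the
full study-scale cohort (~5,400 cells, ~90,000 steps) in about a minute.

## Known limitations

- The greedy resampler optimises each step locally; a pathological clock
  could admit a better global assignment.
- Patrolled-volume counts are grid-phase sensitive at the sub-voxel level
  (inherent to voxel counting with a fixed grid).
- The outlier-frame criterion is one reasonable formalisation; ANOVA-based
  alternatives (e.g. leave-one-out variance ratios) would select similar
  frames but are not implemented.
- Confined walkers realise a lower path speed than their nominal
  speed parameter because inadmissible steps stall; the nominal speed is
  an upper bound for that model.
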