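# Methods

This note documents the models the package implements, the numerical choices
behind them, what the synthetic generator does and does not emulate, and the
places where the design was genuinely open.

## Trajectory model and basic features

A trajectory is a strictly time-ordered sequence of positions for one
animal, in one of three dialects: planar coordinates, geographic
longitude/latitude (step metrics by haversine distance on a 6,371,000 m
sphere and initial azimuth), or displacement increments that are integrated
from the origin. Timestamps are normalized to seconds internally. Tracks
are linearly interpolated onto a uniform grid at the analysis time unit;
gaps wider than 60 time units (configurable) are never interpolated across
— the track is split there, because filling a long outage with a straight
line would fabricate a fast, perfectly directed movement bout.

The analysis time unit and moving-average window default to the median
recording duration divided by 1000 and 100 respectively, snapped to a
1–2–5 grid and floored at the native sampling interval. Species presets
(worm 1 s/12 s, penguin 1 min/20 min, seabird 1 min/10 min, rat 1 s/20 s,
fly 0.25 s/no window, bat 8 ms/no window) override the rule, because real
analyses sometimes deviate from it (the worm window is 12 s, not 6 s).

Per frame, velocity is step length per time unit and bearing is the step
heading clockwise from +y (planar) or true north (geographic), in
[0, 360). Zero-displacement frames carry the previous bearing forward; an
undefined heading must not inject missing values into the differential
streams. The wrapped bearing change *dB* lives in (−180°, 180°]. Moving
statistics use a centered window with an odd number of frames; bearing uses
the circular mean and the mean squared wrapped deviation (deg²) so that the
0/360 seam cannot create spurious variance. Feature values undefined at the
edges (differentiation and window losses) are carried as NaN, keeping every
stream aligned 1:1 with trajectory frames.

Histograms pool all animals of a cohort; binning uses the
Freedman–Diaconis rule floored at 30 bins. A feature whose pooled spread is
at floating-point noise level relative to its parent quantity's scale
(velocity scale for V/dV features, 360° for bearing features) is flagged
unusable rather than handed to the mixture machinery.

## Mixture fitting and model selection

The EM implementation is 1-D and deliberately simple: log-domain E-step,
closed-form M-step, convergence at a relative log-likelihood change below
1e-6 or 500 iterations, σ floored at 1e-6 of the data range. Fits take the
best of 10 restarts; the first restart starts from evenly spaced data
quantiles (almost always already near the optimum), the rest from random
data points. The per-iteration log-likelihood path is retained and is
non-decreasing — asserted in the tests.

The cluster number grows from 1. Each candidate N is scored by 10-fold
cross-validated held-out mean log-likelihood with the folds fixed across
candidates, and growth stops when the improvement over N−1 fails a paired
one-sided t-test at the 5% level. A bare "did the CV mean improve" rule is
not usable: chance-level improvements of order 1e-3 nats continue growth
indefinitely on perfectly well-separated two-component data. CV fold fits
use 3 restarts and a slightly looser tolerance (1e-5, 300 iterations) than
final fits; selection and fitting subsample very large pooled histograms to
5,000 and 20,000 seeded values respectively (a 1-D mixture is estimated to
far better precision than the downstream labeling needs at these sizes),
while per-frame labeling always uses every frame.

## Separation index and feature selection

A histogram's score is s(H) = (1 − Ov) + min(N, Mx)/N. Ov integrates
min(πₐφₐ, π_bφ_b) over adjacent mean-sorted component pairs on a
4,096-point grid spanning [μ₁ − 4σ_max, μ_N + 4σ_max], summed and clipped
to [0, 1] (pairwise overlaps of many broad components can nominally sum
above 1). Mx counts peaks of a Gaussian KDE (Silverman bandwidth,
1,024-point grid) whose height *and prominence* exceed 0.1% of the peak
density; plain height thresholding counts every ripple riding on a broad
component as a peak, while prominence filtering keeps exactly the maxima a
reader would call visible.

Which histograms may win required two decisions beyond the score itself:

* **Single-cluster histograms do not compete.** With N = 1, Ov = 0 and
  Mx ≥ 1 give a vacuous s = 2; one cluster cannot be "separated".
* **Concentric mixtures do not compete.** A fitted mixture whose adjacent
  components share their location (|μₐ − μ_b| < min(σₐ, σ_b)) is a scale
  mixture — one narrow and one broad component stacked on the same center,
  which is how a Gaussian mixture models heavy tails, not distinct states.
  Its weighted overlap can nevertheless be small, so without this guard a
  kurtotic but unimodal feature (the windowed mean of bearing change is the
  canonical case) can outscore genuinely bimodal ones.
* **The absolute-bearing average competes only in a meaningful frame.**
  B_Ave is the single basic feature that is not invariant under rotating
  the arena: its clusters record which way each animal happened to head,
  not what it was doing, and pooled heading occupancy across animals is
  reliably lumpy. It therefore enters selection only for geographic cohorts
  (compass bearings of migrating animals are meaningful) or by explicit
  opt-in.

All eight histograms are always scored and reported; the rules above only
decide which ones may be *selected*. Ties break by smaller overlap, then by
a fixed feature order. If nothing competes, estimation raises a
no-structure error carrying the full score table.

## Labels, smoothing, extension, grouping

Frames are labeled by maximum posterior responsibility under the selected
model; components are sorted by mean so "cluster 0" is stable. Because
averaging categorical labels is meaningless, the "moving average over
labels" is a centered sliding majority vote with ties resolved in favor of
the incumbent center label; it removes label runs shorter than about half
the window. NaN-edge frames inherit the nearest labeled frame.

Boundary extension — growing every cluster-0 run by half the window on each
side — compensates a real artifact: a centered moving window smears a
sudden feature change across half a window on both sides of a state
boundary. The correction is exact when state bouts are much longer than the
window (the original worm setting: 12 s window against minute-scale runs)
but erases genuine short bouts when bout length is comparable to the
window, so the package applies it only on request (`extend="auto"` or an
explicit cluster id), not by default.

For two-state readings (run vs pirouette), components are merged into two
groups at the largest gap between adjacent component means scaled by the
geometric mean of their sigmas — generalizing the manual "cluster 0 vs
clusters 1–4" grouping to something reproducible.

## Information gain and the extracted set

Candidate thresholds are midpoints between consecutive distinct sorted
values; the gain of the best split is found exhaustively (ties go to the
smaller threshold) and equals a brute-force oracle bit for bit in the
tests. Rows missing a value are excluded for that feature only.

"Positive information gain" cannot literally mean gain > 0 for continuous
features: the best stump on pure noise has strictly positive gain with
probability ~1, so a raw rule would extract every column. The package
therefore reports the raw maximal gain but gates the *extracted* set with
the Fayyad–Irani MDL acceptance criterion for the best binary split, which
is what makes the null calibration behave (0% of 333 features extracted on
a label-shuffled cohort at the default sizes, versus the planted
run-duration effect ranking first). The null utility assigns pseudo-
condition labels to segment rows of a single simulated cohort; simulating
two independent "identical" cohorts instead measures real cohort-level
drift (notably in odor-concentration features, which inherit each cohort's
random-walk geography), not the extraction procedure's false-positive rate.
No multiple-testing correction is applied beyond the MDL gate; a
permutation-null utility is provided for calibration.

## Worm-specific machinery

Turns are 1-s movements with |wrapped bearing change| > 90°. The inter-turn
interval histogram (log-spaced bins) is fitted with a₁e^(−t/τ₁) + a₂e^(−t/τ₂)
by multi-start least squares on log-density, parameters optimized in log
space for positivity, residuals weighted by √count since log-density noise
scales as 1/√count; two-exponential fits are ill-conditioned and the
weighting roughly halves the t_crit estimation error. The crossing time
t_crit = ln(a₁/a₂)/(1/τ₁ − 1/τ₂) separates runs (longer intervals) from
pirouettes (shorter intervals plus their bounding turns); a fit whose fast
component does not dominate at t = 0 cannot cross and is flagged so a
configured fallback can be used.

Directedness of a segment is net displacement over path length, in [0, 1].
The weathervane index is the mean signed curving rate (degrees per unit
path length) with the sign positive when the path bends toward the local
up-gradient direction of a supplied odor field; odor fields are a pluggable
interface with linear-gradient and static-Gaussian implementations
(measured dynamic gradients belong to the user).

The 333-column segment feature scheme is configuration-driven, since the
printed total does not follow from any naive product of the listed feature
classes. The default scheme: six series features {V, dV, B, dB, C, dC} ×
{Ave, Med} × periods {Ini, Mid, Ter, All} × windows 1–6 s (periods are the
first/central/last w seconds and the whole segment; the series is smoothed
with a w-frame moving average so the All cells also depend on w) = 288;
directedness as a trailing-w-window per-frame series summarized by
{Ave, Med} over {Ini, Mid, Ter} (36) plus one whole-segment scalar per
window computed on the w-smoothed path (6); and WV, Clst0Dur, Clst1Dur (3).
Cells whose period is shorter than the window are missing, not imputed.

The 42-column bat flight scheme evaluates eleven features (3-D speed,
horizontal/vertical bearing, distance and bearing to the nearest obstacle
edge point, longitudinal and lateral distances to the chain array, and the
differentials dV, dB, ddB, dH at 1/125 s frames) at four analysis time
points (0.3/0.2/0.1 s before and while passing the array plane), minus the
two cells degenerate at passage (the longitudinal distance, identically
zero there, and the bearing to the nearest edge point). Early/middle/late
session terms are carried as a per-flight metadata column.

## Evaluation

The matching matrix gives sensitivity, specificity, false positive/negative
rates and accuracy of binary frame labels; predicted clusters are grouped
onto reference states by majority frame overlap (ties toward the lower
state id). Event-level tallies count a reference event as matched when
predicted-positive frames cover at least half of it — the 50% threshold is
this package's convention, stated rather than inherited.

## The synthetic generator

Animals are correlated random walks switching between discrete states;
within a state the heading gains Normal(0, turn_sd) noise per frame plus,
with probability large_turn_prob, a reversal-scale turn uniform in ±(90°,
180°], and step lengths are Normal(speed_mean, speed_sd) floored at 0. Bout
durations are exponential (rounded up to whole frames), matching the
two-timescale picture of turn-interval statistics. The default run/pirouette
cohort: runs with 30 s mean duration, 10°/frame heading noise; pirouettes
with 5 s mean duration, 30°/frame noise and large-turn probability 0.5;
both states at speed 1.0 ± 0.1 per frame so that turning dynamics are the
only discriminating signal. Condition effects are multiplicative shifts on
named state parameters.

What the generator does *not* emulate: arena boundaries (walks drift
unboundedly, so position-derived quantities such as odor concentration have
heavier cohort-level variation than a 9-cm plate would allow), posture,
tracking noise and dropout, inter-animal variability in state parameters,
and any feedback from stimulus to behavior (turning statistics do not
depend on the odor gradient, so chemotaxis-style modulation is absent).
Passing tests on this generator therefore demonstrate that the estimator
recovers planted kinematic structure and planted condition effects — not
that it handles tracking artifacts or closed-loop behavior.

At the documented study scale (50 animals × 600 one-second frames,
selection on seeded subsamples as above) the end-to-end pipeline runs in
under a minute on one CPU; the acceptance script's full recomputation takes
a few minutes.

## Known limitations

* Model selection by CV likelihood finds spurious location structure in the
  heavy-tailed windowed-variance features of *any* stochastic walk, so a
  truly homogeneous (single-state) cohort does not reliably fail over to
  "no structure"; only degenerate (noise-free) cohorts are guaranteed to.
  The score report always accompanies the selection so such cases can be
  inspected.
* The separation index compares mixtures against visible histogram peaks;
  with fewer visible peaks than components (typical for skewed variance
  features) the second term saturates below 1 and the ranking is driven by
  overlap, which is sensitive to the fitted N.
* Per-segment feature rows of one animal are not independent; the MDL gate
  assumes they are, so extraction on strongly animal-clustered features
  should be cross-checked against the permutation null.
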