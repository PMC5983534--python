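# Methods

This note documents the models implemented in `gazeclean`, the defaults and
their units, the design choices made where the design was genuinely open, and
what the synthetic-data generator does and does not emulate.

## Screen geometry

All pixel/visual-angle conversions use the full-angle formula
`angle = 2·atan(span/(2·distance))` rather than the small-angle approximation:
only the exact form reproduces, with a single pixel pitch, both a 0.657° dot of
20 px diameter and the 3.28°/2.29°/1.642° angles of the 100/70/50 px stimulus
spacings at 60 cm. The default geometry is a 1366×768 screen at 600 mm with a
pitch of ≈0.344 mm/px, anchored on the 20 px/0.657° pair; all values are
overridable. (The digit font sizes quoted in degrees for the smaller spacings
are mutually inconsistent with every other quoted pixel/degree pair by a
constant ≈0.03°; the spacing-anchored pitch is used and the discrepancy left
unresolved.)

## Fixation extraction

I-VT classification: a sample is a fixation sample when its incoming
point-to-point velocity is below the threshold; the first sample of a trace
inherits the classification of the second. The threshold default is 20 in
px/sample — the conventional threshold value is quoted without units, so the
unit interpretation is exposed in config (`deg_per_s` via the geometry is the
alternative). At 30 Hz and the default geometry, 20 px/sample ≈ 20°/s, so
either reading separates dwells from saccadic jumps.

Two standard I-VT post-processing steps are applied:

* **Minimum duration** — runs shorter than 4 samples (~133 ms at 30 Hz) are
  discarded as spurious.
* **Adjacent-fixation merging** — runs separated by at most 2 saccade-labelled
  samples whose centroids lie within 30 px (~1° at 60 cm) are fused, gap
  samples included. Without this step, Gaussian dispersion at the level of a
  low-cost tracker (σ ≈ 8 px gives a ~21% chance that any single step exceeds
  the threshold) shreds every dwell into 4–6-sample fragments that no
  windowed filter can smooth. Both gates are configurable;
  `merge_max_gap=0` disables merging and recovers the bare maximal-run
  semantics.

## Graph-signal smoothing

Within each window the proximity graph uses the squared-exponential kernel
`exp(−d²/θ²)` gated at distance `th` (the linear-distance variant `exp(−d/θ²)` sometimes written for this kernel is
available via `kernel="literal"`).

Two numerical choices depart from the bare formulas, both needed for the
penalty `‖t − At‖²` to act as a smoothness term:

* **Self-loops and row normalization.** With the raw adjacency, a vertex with
  no neighbours is mapped to `G/(1+α)` — shrunk toward the screen *origin*,
  which no filtering rationale supports. Unit self-loops plus row
  normalization make A row-stochastic: constant signals are exact fixed points
  and isolated vertices pass through unchanged.
* **Adaptive scale.** A fixed threshold of 1 px leaves essentially every
  real window edgeless (within-fixation steps are an order of magnitude
  larger). With `adaptive_th` (default on), `th` and `θ` are set per window to
  the median pairwise distance — a dispersion-scaled graph that connects the
  bulk of a fixation cloud at any noise level. The fixed nominal values remain
  available with `adaptive_th=False`.
* **Balanced windows.** A chunk of n samples is cut into ⌈n/L⌉ windows whose
  sizes differ by at most one sample instead of leaving a short remainder: a
  trailing window of 1–4 points carries too sparse a graph to smooth and would
  leak effectively raw samples into the filtered output. Each window's graph
  is built and solved at its actual size.

Defaults: L = 10, α = 5, θ = th = 1 (superseded per window when adaptive).
The closed-form solve is `S_t = (I + α(I−A)ᵀ(I−A))⁻¹G`; the system matrix is
symmetric positive definite by construction, so the solve cannot fail.

## Kalman filtering with AR(3) velocity dynamics

A 4-component state (position and velocity per axis) cannot realize
a third-order velocity autoregression; the implemented state is the minimal
8-dimensional realization `(x, y, vx, vy, vx₋₁, vy₋₁, vx₋₂, vy₋₂)`. The AR
weights are fitted per session by conditional least squares (statsmodels
`AutoReg`, lags 3, constant trend) on the velocities of the graph-filtered
chunks — the stage ordering places the graph filter first, so its output is
what the Kalman stage sees. Sessions with fewer than 30 pooled velocity
samples fall back to a = (0.4, 0.2, 0.1). The AR intercept is absorbed into
the zero-mean process noise.

Noise covariances (free parameters of the model; set as follows):

* **Process noise** excites only the current-velocity states. Its variance per
  axis is `phi1_scale ×` the AR fit's own innovation variance (the velocity
  model's estimate of its one-step unpredictability), with `phi1_scale = 4`:
  the innovation variance is estimated on graph-filtered velocities and hence
  understates the variability the filter must accommodate, so a multiplier
  above 1 keeps the filter responsive rather than over-smoothing. Fits that
  report no variance (degenerate series, fallback coefficients) use
  2500 (px/s)², roughly the one-step velocity variability of 1–2 px of
  fixational jitter at 30 Hz.
* **Measurement noise** is isotropic, `phi2_scale = 25 px²` (a 5 px RMS
  tracker), on the position measurements.
* **Initialization**: first posterior mean = first measurement with zero
  velocities; initial covariance has the measurement variance on positions and
  a large variance (10⁴) on the velocity states. The posterior covariance is
  re-symmetrized after every update.

With zero process noise and an exact static model the filter reduces to the
running mean of the measurements; with vanishing measurement noise it returns
the input — both limits are covered by tests.

## Correction transforms and the determinant measure

A correction is a pure 2×2 linear map on row vectors — no translation term, so
correctable drift is limited to linear maps about the screen origin. This
restriction is kept deliberately: it is exactly the class that a global linear
distortion of screen coordinates can invert.

**Fitting.** Given a fixation chunk and a single ground-truth position, the
transform is fitted to carry the chunk *centroid* onto the target: T minimizes
`‖x̄·T − c‖²` by Nelder–Mead simplex search from the identity (2000 iterations,
1e-8 tolerance, one polishing restart). Pairing every sample with the same
constant target instead would admit the rank-one global minimizer that
collapses the fixation dispersion onto the target — its determinant is ~0
regardless of data quality, which would make the determinant useless as a
validity measure. With the centroid objective an already-exact chunk yields
the identity (M = 1) and a drifted chunk yields a near-identity solution whose
determinant is diagnostic. When per-sample desired coordinates are supplied
(an (n,2) array), the fit is the fully determined least-squares problem and
the simplex solution coincides with the closed-form normal-equations solution,
which the tests verify independently.

**Validation.** M = det(T). A calibration transform with M < 0.8 is replaced
by the elementwise mean of the transforms of its 2 nearest calibration points
with M ≥ 0.8; more than 3 failures demand a fresh calibration. The rule is
deliberately one-sided: M can neither flag area-preserving distortions
(det diag(2, 0.5) = 1) nor inflating maps (M > 1), a known limitation of the
measure. In practice a corrupted dwell is caught when fitting it to its
target requires heavy shrinkage; a corruption that requires magnification
passes the one-sided rule.

**Paths.** The pseudocode labelling is used: A = 1 nearest calibration point,
B = 4 nearest with inverse-distance weighting (the running text swaps these
names; `path_label_convention="prose"` swaps them back). C and D fit fresh
transforms against the 4 and 2 nearest stimulus positions treated as
presumptive ground truth and combine them with the same weighting. The
inverse weighing function uses w_i = 1/d_i^p, p = 2, normalized to sum to 1;
a zero distance short-circuits to that neighbour alone.

## Metrics and AOIs

Chunk radius is the maximum distance from the centroid (95th-percentile
variant available); closeness is implemented exactly as the mean of *squared*
distances (units px²). A filtered chunk collapsed below 1e-9 px radius maps to
an SR of +inf with a warning rather than an exception, so batch evaluation
continues.

AOI sizing (only the three shapes are fixed by the evaluation protocol; their
dimensions are free): the rectangle is the stimulus's rendered bounding box padded by a
quarter of the free gap to the nearest neighbouring entity per side, capped at
the midline so rectangles never overlap; the ellipse inscribes the rectangle
and the circle inscribes the ellipse, so circle ⊂ ellipse ⊂ rectangle and the
rectangle ≥ ellipse ≥ circle accuracy ordering holds structurally. Padding to
*half* the gap was rejected: it would tile the digit row with contiguous
cells, abolishing the "no-man's land" region that the evaluation partition
(correct region / wrong region / neither) requires, and would make
nearest-stimulus snapping incapable of ever changing an AOI assignment.

## Synthetic sessions

The generator emulates the study's three screens: the 9-point calibration grid
(8% margins; the centre point at the screen centre), the single-row
number-gazing (NG) strip — 9 digits anchored 100 px from the left screen edge
at y = 150 px with 100/70/50 px spacing and the fixed 2:1 spacing-to-font
ratio — and the 2-column recall-recognition (RR) word grid. The NG anchoring
is a layout choice (the original screen coordinates are not recoverable);
with origin-referenced linear distortions the anchoring determines how much
drift the distortion induces at the stimuli, and left-anchoring keeps a
5%-scale distortion in the regime where raw accuracy degrades but
nearest-stimulus correction remains informative — matching the raw accuracy
levels the method was reported against (~60% for the densest spacing).

A session follows a plan of (target, dwell) pairs: clean coordinates are
piecewise-constant with 2–3-sample linear saccadic ramps (or constant-speed
pursuit sweeps at 1.92°/s for the calibration ball; pursuit samples are
excluded from calibration fitting). The observed trace is
`clean·D + N(0, σ²I)` plus artifact bursts; a click is logged at the end of
each test dwell. Defaults: σ = 8 px (a plausible sample-to-sample dispersion
for a 30 Hz consumer tracker; the velocity-threshold convention of 20
px/sample only makes sense if real dispersions sit below ~10 px), artifacts of
200 px lasting 3 samples at 1% per-sample probability, D = identity. All
randomness flows through one seeded generator; equal seeds give bit-identical
sessions.

**Long sessions and fatigue.** The 15-minute variant strings random 4-digit
gaze-and-click pins at the densest spacing. Fatigue is modelled as a growing
rate of large transient artifacts — minute m carries exactly
`round(3·(1 + ramp·m))` isolated 3-sample 200 px bursts at seeded positions
inside dwells — rather than as growth of the Gaussian dispersion σ. The reason
is structural: every stage of the cleaning chain after fixation extraction is
(approximately) linear, so filtered closeness scales with σ² exactly as raw
closeness does, and *no* filter of this class could hold its output constant
under a σ ramp that visibly degrades the raw signal. Abrupt large-amplitude
glitches (head jerks, blink recoveries) are also what exhausted participants
actually contribute; they inflate raw closeness while the I-VT velocity gate
excises them (bursts are shorter than the minimum fixation duration and are
never merged across, since their displacement far exceeds the merge distance
gate), leaving the filtered closeness flat.

What the generator does **not** emulate: main-sequence saccade kinematics
(real saccades at 30 Hz span ≲2 samples, so linear ramps suffice),
physiological tremor/microsaccade spectra, pupil size, blinks as tracker
dropouts, or region-dependent calibration drift (the distortion is one global
linear map, so the supervised paths can in principle invert it exactly).
Consequently, passing tests demonstrate that the chain removes the error
classes it models — dispersion, isolated artifacts, global linear drift — not
that it handles every failure mode of real recordings.

## Evaluation protocol choices

Pipeline runs segment the trace into 2-second windows before each click and
take the longest fixation chunk per window as the gaze event on the clicked
target. Calibration uses the central 60% of each dwell window, trimming
entry/exit transients. For long-session monitoring, raw closeness is computed
per dwell window on unprocessed samples and filtered closeness on the same
window's fixation samples after the full chain, pooled around the window's
filtered centroid (pooling per gaze event rather than per fragment keeps the
measure independent of how artifacts happen to split a dwell); minutes
aggregate their windows weighted by sample count.

Problem sizes used by the acceptance checks — nine-digit sessions (≈660
samples each, 5 seeds), 50-seed/200-sample filter recovery runs, 100-instance
oracle-equivalence batches, and one 15-minute session (≈27,000 samples) — are
chosen so each check exercises the full chain at the study's sampling rate
while the complete suite runs in well under a minute per module.

## Known limitations

* The correction class has no translation term; a pure offset drift is only
  approximately correctable, and better so far from the screen origin.
* M = det(T) is blind to area-preserving and inflating distortions (kept as
  specified; see above).
* A transform learned at one calibration point constrains only 2 of the 4
  degrees of freedom of the local drift; recovery of a full 2×2 distortion
  from a single dwell is information-theoretically impossible, which is
  precisely why the multi-neighbour paths (B/C/D) outperform the single-
  neighbour path A away from the calibration points.
* At 30 Hz a velocity threshold cannot detect microsaccades; the chain targets
  fixation-level cleaning only.
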