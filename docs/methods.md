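# Methods

`fallsense` reimplements, end to end, a mobile-phone fall detection and
fall-type classification pipeline: a belt-worn phone on the lower back
records tri-axial acceleration at a variable 15–25 Hz; falls of four
directional classes are distinguished from each other and from the hardest
non-fall events of everyday wear using a large time-series feature bank and
standard classifiers. Because the original human-subject recordings are not
available, the package includes a first-class synthetic-data generator that
reproduces the statistical structure of both data sets, so every stage is
testable without any download.

## Sensor model and conventions

An accelerometer reports specific force: at rest the axis pointing up reads
+9.8 m/s². With the phone centred on the lower back, the sensor axes map to
body directions x = up, y = left, z = backward. The post-fall lying
orientation therefore determines which axis carries gravity afterwards:

| fall class     | posture after | gravity-bearing axis |
|----------------|---------------|----------------------|
| trip (forward) | prone         | z ≈ +9.8 m/s²        |
| slip (backward)| supine        | z ≈ −9.8 m/s²        |
| lateral-left   | left side     | y ≈ −9.8 m/s²        |
| lateral-right  | right side    | y ≈ +9.8 m/s²        |

## Synthetic falls

Each trial follows a four-phase model: quiet upright stance → freefall →
directional impact → lying still. The gravity direction is spherically
interpolated from upright to the lying orientation over the
freefall-plus-impact interval; the specific-force magnitude eases from 9.8
down to a per-trial minimum of 0.5–1.5 m/s² during freefall (always below
the 3 m/s² ceiling), plateaus at a 20–35 m/s² peak through the 0.1–0.2 s
impact, and returns to 9.8 while lying. Six raw protocol types are
generated — slip, trip, and left/right lateral in active and faint variants
— and the lateral variants are merged post hoc into the four reported
classes. Faints descend with a 2× slowed freefall and no pre-impact
flailing; active falls get extra movement noise ("flailing", sd 1.5 m/s²)
in the half-second before impact. Additive white Gaussian sensor noise
(sd 0.3 m/s²) and a per-trial random body/phone tilt (sd 5°) model sensor
noise and imperfect mounting.

Phase durations are drawn uniformly from the configured ranges (stance
2–4 s, freefall 0.3–0.5 s, impact 0.1–0.2 s, lying 2–4 s). Because those
ranges can sum to less than the 10 s analysis window, the generator extends
the quiet stance and lying phases so that at least 5.5 s of signal exists
on each side of the impact — physically this is just the subject standing
still before the trial and remaining down after it. Phase boundaries and
the fall instant are emitted as annotations, which is what the tests use to
verify the freefall dip against the generator's own ground truth.

## Synthetic daily wear

Wear streams alternate quiet postures (upright, supine, left/right side;
drawn 0.60/0.15/0.125/0.125) of 5–30 min with walking bouts whose length
targets the configured walking fraction (default 0.15). Walking adds a
dominant ~2 Hz oscillation on the up-axis with weaker components on y and
z. Posture transitions smooth the gravity direction over ~1.5 s, carry
extra movement noise, and half of them end with an impact-like landing bump
(8–22 m/s², dropping onto a chair or bed) aligned with the new posture —
without these, the mined negative events were trivially separable from
falls, which contradicts the field observation that the hardest everyday
events genuinely resemble falls. Independent "jolts" (12–30 m/s² additive
spikes, optionally double-contact, Poisson at 2/hour) model knocks and
bumps; by construction they contain no sustained sub-3 m/s² freefall dip
and return to the prior orientation within a second, which is exactly the
structure a detector must exploit. Timestamps are drawn with per-gap
uniform jitter so the instantaneous rate stays in the 15–25 Hz band.

What the generator does **not** emulate: real gait variability and
pathological gaits, stair/vehicle dynamics, phone repositioning, sensor
saturation and temperature drift, or genuinely ambiguous events (sitting
onto the floor, diving onto a bed). Passing tests therefore demonstrate
that the pipeline recovers the structure this model encodes — not that the
reported accuracies would transfer to arbitrary real-world wear data.

## Preprocessing

Variable-rate streams are linearly interpolated per axis onto an exact
20 Hz grid anchored at the first timestamp, with no extrapolation.
Analysis clips are 10 s / 200 samples, half-open `[start, start+10 s)`,
centred on the grid point nearest the requested time; a window that would
overrun a recording edge is shifted minimally to fit, never zero-padded
(padding would corrupt moment and spectral features).

## Event mining

The mining score at sample *i* is Σ over axes of (a_i − a_{i−1})²
(rotation-invariant; defined as 0 at the first sample), smoothed with a
centred 2 s (40-sample) running mean using symmetric edge reflection.
Recordings are split into sessions at timestamp gaps > 1 s first, so
battery-off periods cannot create spurious jerk spikes. Each session is
partitioned into consecutive whole hours and the argmax of the smoothed
score within each hour becomes one candidate (ties break to the earliest
sample; trailing partial hours yield nothing). Whether the original
procedure smoothed the squared change of each axis or of the magnitude is
not decidable from its description; the per-axis sum is this package's
choice.

## Feature bank

178 features per clip in a frozen, axis-major registry order (group sizes
15, 12, 9, 12, 27, 96, 1, 3, 3):

- **moments** (15): per axis mean, |mean|, sd, skew, kurtosis. Population
  (biased) moments; kurtosis is m₄/m₂² (non-excess); skew and kurtosis of a
  zero-variance signal are defined as 0.
- **difference moments** (12): the same four moments (no |mean|) of the
  199-sample successive-difference series.
- **smoothed RMS** (9): RMS of the raw, gravity-inclusive signal after
  boxcar smoothing with 1-, 5- and 10-point kernels (symmetric reflection
  keeps length 200). Raw rather than mean-removed, matching the
  "9.8 m/s² at rest" anchor.
- **extremes** (12): per axis min, max, |min|, |max|.
- **histogram** (27): per axis, counts in 9 unit-width z-score bins centred
  at −4…+4 (edges ±4.5), using the clip's own mean/sd; outliers clip into
  the extreme bins; a zero-variance axis puts all 200 counts in the centre.
  The 9×3 layout is the only reading of "±4 z-score bins" consistent with
  27 values.
- **Fourier** (96): per axis, the one-sided DFT magnitude spectrum
  (101 bins, DC included) linearly interpolated at 32 evenly spaced
  frequencies over [0, 10 Hz]. Magnitudes are used because they are
  phase-invariant, which suits detection; "32 samples from the spectrum"
  underdetermines the construction, so this is a documented package choice.
- **magnitude** (1): mean Euclidean norm — 9.8 m/s² at rest.
- **cross products** (3 + 3): means of the elementwise products xy, xz, yz
  and their absolute values.

Every group is cross-checked against independently coded brute-force
oracles (direct moment sums, cumulative-sum boxcars, explicit cos/sin DFT)
at 1e-9 relative tolerance on 100 random clips.

## Classifiers and crossvalidation

Features are normalized to zero mean, unit variance with statistics fitted
on training folds only (zero-variance features get scale 1), so no test
information leaks into the transform. Five families, implemented on
scikit-learn estimators behind a uniform `ClassifierSpec` surface:

- **RBF-SVM** (`SVC`, one-vs-one multiclass) with soft-margin C and kernel
  width γ;
- **SMLR**: multinomial logistic regression with an L1 penalty λ on the
  non-intercept coefficients (objective mean NLL + λ‖w‖₁, mapped to
  scikit-learn's `C = 1/(nλ)`, saga solver, tol 1e-6, max_iter 2000) — the
  penalty performs embedded feature selection and its sparsity is monotone
  in λ;
- **Gaussian naive Bayes** (variance floor 1e-9);
- **decision tree** (Gini, grown to purity, fixed split seed);
- **kNN** (Euclidean majority vote, default k = 3).

Hyperparameters are chosen by grid search over 10^x for integer x in
[−5, 5] (121 C×γ combinations for the SVM, 11 λ values for SMLR) maximized
on stratified 10-fold CV accuracy; ties keep the first candidate in
ascending order. For kNN a power-of-ten grid makes no sense for a
neighbour count, so small odd integers 1–15 are searched instead. Two CV
schemes are provided: pooled stratified 10-fold (shuffled, seeded) and
subject-wise leave-one-subject-out, the strictest reading of "subject-wise
crossvalidation". Hyperparameters are selected once on the pooled data and
held fixed across folds by default (the widely used, if slightly
optimistic, reporting convention this pipeline mirrors); per-fold refitting
can be done by calling `grid_search` inside a custom loop.

The reference hyperparameter values carried as `ClassifierSpec` defaults
(C = 10, γ = 0.1, λ = 1e-4, k = 3) are tunings for the original
recordings; on the synthetic study γ = 0.1 makes every RBF kernel entry
vanish in 178 standardized dimensions, so accuracy work always goes
through the grid search, which selects γ in the 1e-4–1e-2 range here.

## Experiments and problem sizes

- **Fall-type classification**: 15 subjects × 18 trials = 270 clips, 4
  classes, clip centred on the annotated fall instant.
- **Detection**: the 270 fall clips (positive) versus one mined fall-like
  clip per whole recorded hour from 9 wear subjects × 24 h = 216 negatives;
  the natural class imbalance is kept and reported. The 24 h per subject is
  this package's default emulation of "portions of a week" of wear.

Per-task seeds are derived from the master seed with fixed offsets, so each
experiment reproduces independently and bit-identically under a fixed seed.
The acceptance script (`scripts/acceptance.py`) regenerates both studies
from scratch at the given seed and reports grid-searched RBF-SVM pooled
10-fold accuracies; the test suite runs the same checks at a fixed seed,
plus exact structural checks and the property suites (oracle equivalence,
count conservation, no-leakage, sparsity monotonicity, classifier ranking
with naive Bayes strictly worst, permutation-null accuracy at chance).

## Known limitations

- The generator's four-phase fall model is deliberately minimal; it
  reproduces the signatures the classifiers exploit (orientation change,
  freefall dip, impact spike) but not biomechanical detail.
- Synthetic classes are cleaner than human data: near-ceiling accuracies
  here indicate a correctly wired pipeline, not expected field performance.
- Only accelerometry is modelled — no gyroscope or magnetometer channels.
- Event mining is rank-based per hour by design; it provides hard
  negatives, not a calibrated false-alarm rate.
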