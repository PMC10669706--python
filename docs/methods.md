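# Methods

This note records the models, parameter choices, and numerical conventions
behind posturekit, and what the synthetic-data generators do and do not
emulate.

## COP from four uni-axial load cells

The plate is treated as rigid, with the four cells at the corners of an
axis-aligned rectangle measuring only vertical force. Under these
assumptions the COP is the force-weighted mean of the sensor positions,
which is always inside the sensor hull for non-negative forces; the
implementation asserts this per sample. Shear forces and the free moment
are not measurable with uni-axial cells and are not modelled.

- **Minimum-load threshold** (`min_total_force_n`, default **50 N**):
  below roughly 5 kg of load the denominator of the weighted mean makes
  the COP numerically meaningless (an unloaded plate); such samples are
  dropped and counted in provenance, or raised as errors on request.
- **Negative-force tolerance** (−1 N): cells cannot pull, but ADC noise
  can dip slightly below zero; anything beyond 1 N of pull is treated as
  a sensor fault.
- **Axis convention**: +x is the subject's right (ML), +y anterior (AP),
  coordinates in mm in the plate frame; channel order is tied explicitly
  to sensor order in `PlateGeometry`, never to positional convention.
- **Plate size** is always user-supplied (default fixture 500 × 500 mm).

### Centering

Directional excursions need a stance origin. The default subtracts the
mean COP of the trial's **first 1 s** (`origin.window_s`), the quiet hold
before an excursion begins; trials shorter than twice the window fall
back to the whole-trial mean. Both choices make centering idempotent.

### Filtering

Off by default — the acquisition chain applies no analogue filtering and
the metric battery is defined on raw trajectories. A 4th-order zero-phase
Butterworth low-pass (default cutoff 10 Hz) is available for noisy data;
zero-phase filtering preserves trajectory length and DC.

## Sway-metric battery

- **Duration** is counted as inter-sample intervals, `(n − 1)/fs`, so the
  velocity identity `mean_velocity × duration = total_path` is exact.
- **Sway area** uses the large-sample 95% ellipse,
  `π · χ²₂(0.95) · √det(S)` with the `n − 1` sample covariance; at 100 Hz
  a trial has thousands of samples, so the chi-square quantile (5.991) is
  appropriate. The small-sample F-based prediction ellipse
  (`2(n−1)/(n−2) · F₂,ₙ₋₂`) is available via `ellipse.method: f`.
  Clouds whose covariance determinant is ≤ 10⁻¹² of the squared largest
  variance are reported as degenerate with area 0.
- **Directional maxima** are floored at 0 for directions never visited,
  so all four report non-negative magnitudes.
- **"Mean velocity"** is the planar path over duration by default.
  Some platforms report the sum of the two axis velocities instead; the
  published normative values are consistent with neither convention
  exactly, so the ambiguity is kept explicit as a config option
  (`velocity.mode: planar | axis_sum`) rather than resolved.

## Excursion (MVE) protocol

The assessment records three consecutive excursion trials, tested twice
per direction, read as a cap of **6 trials per direction** — the sentence
admits other readings, so the cap is a config key
(`mve.max_trials_per_direction`). The headline per-subject value is the
pooled field-wise mean over all trials ("computed for each trial and then
averaged"); per-direction sub-aggregates are retained.

For game calibration, per-direction stability limits are derived
direction-matched: R/L from trials exercising the ML axis, A/P from the
AP axis, and within those only from trials that actually targeted the
direction (per-trial maximum at least half the session's best toward it).
Averaging in a leftward trial's residual rightward sway would otherwise
dilute the right-side limit.

Trial duration is nowhere prescribed; synthetic assessment trials default
to 60 s (see the battery calibration below) and real files of any length
are accepted.

## Synthetic data

### Quiet stance

Per-axis Ornstein-Uhlenbeck process with the exact discretization
`x[k+1] = x[k]·e^(−θΔt) + σ√((1−e^(−2θΔt))/2θ)·ε`, started from a
stationary draw, plus white measurement noise. Defaults: relaxation rate
θ = 1 s⁻¹, intensity σ = 4 mm/√s (stationary sway SD ≈ 2.8 mm per axis,
typical of quiet stance), measurement noise 0.1 mm, 100 Hz. OU is the
simplest process with stationary, tunable sway variance; it does not
reproduce the two-regime (persistent/anti-persistent) structure of real
stabilograms, which none of the computed metrics depend on.

### Directed excursion trials

Deterministic half-cosine ramp → settle → return profiles along one
direction, with optional overshoot and superimposed OU sway. With no
noise and no overshoot the directional maximum equals the target
amplitude exactly, which anchors the metric tests.

### The multi-directional excursion battery

Published normative batteries are internally consistent in a telling
way: the ML sway range equals the sum of the right and left maxima, the
AP range the sum of anterior and posterior maxima (to 0.01 mm), and the
total path lies strictly between the larger axis path and the axis-path
sum. Single-axis trials cannot reproduce this jointly under any
aggregation rule — pooled averaging halves the directional maxima, and a
single-axis trial's 95% ellipse is nearly degenerate, collapsing the
sway-area row. A limits-of-stability assessment trial that visits all
four directions reproduces all of it at once, so the battery generator
emulates exactly that: interleaved excursions toward R/L/A/P separated by
quiet holds, one maximal excursion per side, the rest sub-maximal.

The young-adult defaults are calibrated in closed form, not by search:

- direction amplitudes = the normative maximal excursions
  (R, L, A, P) = (130.30, 134.24, 81.26, 105.61) mm;
- each out-and-back excursion of amplitude *a* contributes 2*a* of axis
  path, so the per-side repetition scale follows from the normative axis
  paths (2530.42 mm ML, 2857.69 mm AP) with 5 ML and 8 AP excursions per
  side;
- occupancy sets the ellipse: a half-cosine ramp contributes 0.375 a², a
  hold a² per second, giving per-axis variances (and hence
  `π·5.991·σₓσᵧ` ≈ 26 000 mm²) from the 0.5 s ramps, 0.2 s holds, and
  60 s trial length. The trial duration and hold time were chosen from
  this budget.

Per-excursion amplitudes get ±3% uniform jitter and a small two-tone
(0.25/0.40 Hz, ≈1 mm) residual sway is superimposed; white noise is off
here because real COP is band-limited and broadband noise would inflate
path lengths nonphysically. What passing the envelope check shows is that
the generator, pipeline, and metric definitions are mutually consistent
at realistic magnitudes — not that the generator reproduces human
kinematics.

### Inverse force model

Body weight is distributed over the cells with the bilinear-interpolation
weights of the COP in the sensor rectangle: non-negative, summing to the
weight, and an exact right-inverse of the COP computation (machine
precision), which gives the pipeline a round-trip oracle. Weight is
constant per trial (no vertical dynamics).

### Cohorts

For the statistics pipeline, cohorts are simulated at the metrics level:
per subject and parameter, (pre, post) are bivariate normal with group
baseline mean/SD, the group's training effect added post, the observed
post SD, and test-retest correlation ρ = 0.7 (typical for posturographic
retest; a config key, as no empirical value is available for this
protocol). Defaults encode a trained elderly group (n = 15) against an
untrained control (n = 14) with published six-week game-based training
effects, e.g. +75.58 mm ML sway range against ≈50–60 mm SDs. Negative
draws of positive-valued metrics are clipped at 0 and counted (<1% at
defaults); BBS is clipped to its 0–56 scale (≈5% of post draws), which
slightly compresses the simulated post-training mean. Control-group
clinical baselines are not separately published and reuse the
experimental baselines with zero effect. Parameters are drawn
independently — real sway metrics are strongly cross-correlated — so the
cohort simulator supports per-parameter inference only, not multivariate
analyses.

## Game surrogate

The original racer is replaced by a minimal deterministic surrogate with
the training-relevant dynamics. Constants (no published values exist):

| constant | default | meaning |
|---|---|---|
| `a_fwd` | 2 m/s² | forward-lean acceleration gain |
| `a_brake` | 4 m/s² | backward-lean braking gain |
| terrain drag | 0.2–0.5 s⁻¹ | per-segment linear drag |
| `speed_max` | 15 m/s | speed clamp |
| `k_steer` | 0.5 | lateral displacement per metre advanced at full lean |
| `capture_radius` | 1 m | herring pickup distance |
| `step_hz` | 100 Hz | fixed step, matching the plate |

The joystick mapping normalizes each direction by the subject's own
stability limit (equal game demand ↔ equal relative postural challenge)
and applies a radial deadzone with magnitude `(r − dz)/(ℓ − dz)` along
the COP's ray, continuous at the deadzone boundary; a hard-zero deadzone
is available. Explicit-Euler integration at a fixed step has the exact
fixed point `a_fwd·v/drag`, so held forward lean converges to the
closed-form terminal speed. The player-initiated reset is emulated by an
auto-reset counter (speed < 0.01 m/s for 5 s while unfinished); it keeps
position and cannot end a run, so a zero-input stream finishes only by
time limit. Score is 10 per herring plus the remaining whole seconds when
the course is completed. Streams at other sampling rates are linearly
resampled; jumps and cosmetics are out of scope.

## Statistics

Student's pooled-variance t is the primary independent-samples test
(Welch optional). The mixed ANOVA is computed from first principles so
its algebraic structure is checkable: with difference scores
`d_i = post − pre` and subject means `s_i`,

- interaction: `SS = (d̄₁ − d̄₂)² / (2(1/n₁ + 1/n₂))`,
- time: `SS = 2·((d̄₁ + d̄₂)/2)² / (1/n₁ + 1/n₂)` (unweighted/type-III
  cell means, so unbalanced groups are handled consistently),
- group: `SS = 2·(s̄₁ − s̄₂)² / (1/n₁ + 1/n₂)`,

with within error `Σ(dᵢ − d̄_g)²/2` and between error `2Σ(sᵢ − s̄_g)²`,
each on N − 2 df. The interaction F equals the squared pooled two-sample
t on difference scores for any group sizes — the built-in oracle — and
the implementation is additionally cross-checked against an independent
reference implementation on a balanced fixture. Zero-variance inputs use
the F = 0, p = 1 convention. Tests are reported per parameter at raw
p < 0.05 (α configurable), matching common practice in this literature;
Holm adjustment is available but off by default. Subjects missing a phase
are excluded listwise with a logged warning.

## Verification problem sizes

The acceptance checks use 1000 random trajectories for the COP
round-trip, 10⁵-sample Gaussian clouds for ten random covariances
(ellipse analytics), 1000 random walks for the velocity identity, 100
random fixtures for the ANOVA identity, 500 null and 200 effect cohort
replicates for type-I rate and power, and a 12-trial battery session for
the normative envelopes. These sizes put Monte-Carlo noise well inside
the asserted tolerances while keeping the full run to a few seconds.

## Known limitations

- Synthetic excursion profiles are smooth and stereotyped; real COP
  trajectories show tremor, corrective sub-movements, and fatigue drift.
  Passing tests demonstrate algorithmic correctness and statistical
  calibration, not validity on human data.
- The cohort simulator draws parameters independently and cannot support
  multivariate or correlated-outcome analyses.
- No COM estimation, no shear/free-moment mechanics, no musculoskeletal
  (ankle/hip torque) modelling.
- The published normative "Mean velocity" convention is ambiguous (see
  above); comparisons across toolkits should state which convention they
  use.
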