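# Methods

## Signal model and conventions

The sensor is modeled at the seventh thoracic vertebra (T7), axes x
anteroposterior, y mediolateral, z superoinferior. Internal units are fixed
once at the I/O boundary: specific force in g, angular rate in deg/s, time
in seconds from trial start, velocity in m/s positive downward, angles in
degrees. At upright rest the vertical accelerometer channel reads −1 g; in
ideal free fall all channels read 0. Standard gravity is taken as
9.81 m/s² everywhere, including unit conversion at ingest, so a file
declaring m/s² with a_z = −9.81 maps exactly to −1 g.

Traces are uniform 100 Hz series; ingest rejects sampling jitter beyond 1%
of the nominal interval, samples outside the ±16 g / ±2000 deg/s sensor
ranges, and traces shorter than the three samples the velocity recurrence
needs. Timestamps are regularized to `k/fs` after the jitter check, since
all downstream quantities (detection and lead times) are within-trial
differences.

## Pipeline

**Low-pass filter.** All six channels pass through a causal single-pass
2nd-order Butterworth at 5 Hz. Zero-phase (two-pass) filtering is
deliberately not offered: the detector must be runnable sample-by-sample
before impact. The filter state is seeded with the first sample
(`lfilter_zi · x[0]`), which preserves exact causality (truncating the
input reproduces a prefix of the output) and linearity while avoiding a
startup transient. The ~45 ms group delay this filter introduces at low
frequency is one of the two delays the velocity correction factor absorbs.

**Orientation.** Per axis, the gyro rate is integrated with a
proportional–integral correction toward the accelerometer tilt
(`pitch_acc = atan2(a_x, −a_z)`, `roll_acc = atan2(−a_y, −a_z)`); pitch
rates use the exact Euler-rate mapping `θ' = q·cosφ − r·sinφ` for the
y-then-x rotation order. Defaults Kp = 1.0 (1/s), Ki = 0.1 (1/s²) in the
degrees domain; the closed-loop error dynamics `e'' = −Kp e' − Ki e` then
have poles at −0.11/s and −0.89/s, so a constant gyro bias produces a
bounded transient (≈0.83° peak per deg/s of bias) that decays over tens of
seconds. The accelerometer branch (and its integrator) is frozen whenever
the specific-force norm deviates from 1 g by more than 0.5 g: in free fall
and under impact the accelerometer carries no tilt information, and the
filter becomes purely gyro-driven exactly then. With Kp = Ki = 0 the update
reduces to pure gyro integration, which the tests exploit.

The detector's vertical angle is the combined tilt
`VA = acos(cosφ·cosθ)` rather than pitch alone: falls can be lateral, and
the combined tilt is yaw-invariant and symmetric in the sign of either
angle. One numerical subtlety: tilt extraction computes `atan2(0−a, 0−a)`
rather than `atan2(−a, −a)` so that exactly-zero channels give 0 rather
than ±180° (signed-zero behavior of atan2).

**Kinematics.** Specific force is rotated to the global frame with the
roll/pitch Euler matrix (orthonormal to machine precision; the property
suite checks 1e−12), gravity is compensated by `a_v = a_z,g + 1`, and the
vertical velocity follows the gated Simpson recurrence with gate 0.24 g,
attenuation 0.9 per sample, correction 1.2 and Δt = 10 ms. The literal
recurrence advances `v_t` from `v_{t−2}` at every sample, so two
interleaved Simpson chains coexist and mix whenever the attenuation branch
fires; for constant unit `a_v` both chains follow `v = 1.2·g·t` exactly at
even samples. A non-overlapping "strided" variant is available through
`IntegrationConfig.mode` for sensitivity analysis. The estimate is clamped
at zero from below — it is a downward-speed estimate, and push-off in a
jump must not bank negative "fall speed". The first two samples are the
warm-up of the three-point rule and are zero.

**Detector.** `fire = (VA > 40° ∧ VV > 1.8 m/s) ∨ (VV > 5 m/s)`, evaluated
every sample with no arming stage, latching on the first firing sample
(angle branch reported when both disjuncts hold). A configurable
N-consecutive-sample confirmation exists for robustness studies but
defaults to 1: airbag deployment is one-shot. Raising any threshold can
only delay or lose a detection, never advance one; latching and causality
are property-tested.

## Evaluation and tuning

A trial is detected if the detector fires anywhere in its trace.
Sensitivity, specificity and accuracy are exact rational ratios in
percent. Lead time = collision time − detection time, in ms; detections
after the collision still count toward sensitivity but are flagged
separately as negative leads and excluded from lead statistics (the
pre-impact use case makes them worthless for actuation but they are not
misses). For recorded data without a marked collision, the loader can fall
back to the time of peak filtered acceleration magnitude.

Tuning evaluates accuracy over the 4 × 21 grid of VA thresholds
{25, 30, 35, 40}° and VV thresholds 1.0–3.0 m/s in 0.1 steps, with the
5 m/s velocity-only branch held fixed. Every maximal-accuracy cell is a
candidate; the candidate with the longest mean lead on a held-out
validation suite wins, ties broken toward the larger angle threshold.
Because a lower VV threshold always fires no later, mean lead is
monotone in the VV threshold among equally accurate candidates; on the
synthetic suites the angle thresholds are crossed well before the velocity
thresholds in topples, so (40°, 1.8 m/s) beats (35°, 1.9 m/s) exactly as
in the published tie-break. Note that the synthetic suites are more
cleanly separable than human data — on default noise *every* grid cell can
reach 100% accuracy — so the acceptance comparison applies the selection
rule to the four published candidate combinations.

The correction-factor calibration runs the pipeline with the correction
forced to 1 on free-fall trials at 1, 1.5 and 2 m, takes the ratio of
ground-truth to estimated speed at the last sample before floor contact
(the ground-truth velocity is discontinuous across the impact pulse, so
both quantities are read at the same pre-impact sample), and averages the
per-trial ratios. On default generator conditions the fitted factor is
≈1.11 — gate onset plus filter delay recovered from cleaner signals than a
physical sensor sees, hence somewhat below the 1.2 used by the detector.

## Synthetic motion generator

Every trial is an explicit kinematic script of the trunk sensor: roll and
pitch profiles plus the world-frame sensor acceleration (z down-positive).
The virtual accelerometer reads the rotated specific force
`R(φ,θ)ᵀ · (a_world − g)/g`; the gyroscope reads the exact body rates for
the y–x Euler order. White noise (0.01 g accelerometer, 0.5 deg/s gyro) and
a per-trial constant gyro bias (uniform ±1 deg/s) are added, channels are
clipped inside the sensor ranges, and all randomness flows from one seeded
generator, so suites are bit-reproducible.

Fall templates:

* **Vertical fall** — quiet standing, instantaneous release, zero specific
  force for `sqrt(2h/g)`, then a half-sine deceleration pulse (amplitude
  capped inside the accelerometer range). Impact time and speed have
  closed forms.
* **Forward fall** — inverted point-mass pendulum about the feet (sensor
  lever arm 0.75 × stature; initial lean 2°, push 5 deg/s) integrated with
  an adaptive ODE solver to 90°, then a ballistic drop of the platform
  height to 0.15 m sensor clearance. Sensor speed obeys
  `v = sqrt(2 g · drop)` throughout (energy conservation is tested against
  an independent fixed-step integrator).
* **Worksite scenarios** — scaffold: scripted partial tilt to ~22° (below
  the angle threshold) then a near-vertical fall; roof: lean to ~28°, slow
  slide with sub-gate vertical acceleration, then the eave drop; ladder:
  backward pendulum of radius equal to the working height, caught by the
  angle branch mid-rotation. The scripted slide phases are not
  energy-conservative and are excluded from the conservation test.
* **Jump down (≤1 m, non-fall)** — crouch dip, step-off ballistic descent
  of the platform height, 150 ms landing deceleration, then a knee-flexion
  pitch peak (~22°) a quarter second after touchdown. The descent speed
  estimate peaks near 3.9 m/s — high, but the trunk stays far below 40°
  while it does, and the attenuation has erased it by the time the flexion
  peak arrives. This ordering is what makes the (40°, 1.8 m/s) and 5 m/s
  thresholds jointly feasible.

Non-fall occupational templates (sitting, floor sitting, stairs, ladder
and scaffold climbing, pickaxe, shovel, three lifting directions, beam
walking with and without load, stretching, elevator) are built from
smoothstep angle ramps, windowed oscillations and short transient bursts
chosen so that each class exercises a specific failure mode of naive
detectors: deep lifts exceed 40° tilt at near-zero descent speed,
elevator plateaus stay below the 0.24 g gate entirely, tool transients are
mostly removed by the 5 Hz filter, climbing oscillations open the gate only
briefly. Subject stature is drawn from N(1.74 m, 0.049 m); phase durations
and amplitudes get uniform ±10% jitter.

What the generator does **not** model: human balance reactions and
knee-first landings (which shorten real lead times), deformable bodies
(the physical mannequin flexes; the surrogate is rigid), horizontal gait
dynamics, and magnetometer channels. Passing suites therefore demonstrate
the correctness and internal consistency of the pipeline and its operating
points under idealized rigid-body kinematics with MEMS-grade noise — not
field performance on humans.

## Problem sizes and numerical choices

Default suite sizes mirror the study designs: tuning 10 subjects × 10
motion classes × 3 reps (300 trials), evaluation 20 × 16 × 3 (960),
mannequin 2 fall types × 3 heights × 5 reps, worksite 3 scenarios × 3
heights. The mixed suite for orientation scoring uses 6 subjects × 2 reps.
A full acceptance run is a few seconds of CPU.

Phase arrays place sample k of a phase at `release + k·Δt`, so the release
instant is the last sample of the preceding phase; collision times are
kept continuous (not snapped to the grid) and detection times are sampled,
which quantizes lead times to 10 ms. Pendulum phases use `solve_ivp`
(RK45, rtol 1e−9) with a terminal event at the release angle; sampled peak
speeds therefore sit up to one sample interval below their closed forms,
and tests account for that. Ties in the tuning grid are resolved
deterministically (longest lead, then largest angle threshold). Angles are
wrapped to [−180°, 180°]; the vertical angle is clipped into the valid
arccos domain before evaluation.

## Known limitations

* The literal interleaved Simpson recurrence mixes two integration chains;
  its error versus a clean integrator is absorbed into the empirical
  correction factor rather than analyzed separately.
* The PI gains (Kp = 1.0, Ki = 0.1) are conventional values for 100 Hz
  trunk tracking, not fitted; the orientation-accuracy suite (mean
  absolute VA error ≤ 5.2°) gates any retuning.
* Collision-time inference for recorded data (peak filtered |a|) is a
  heuristic; synthetic trials always carry exact impact times.
* Lead times for the worksite surrogates depend on scripted pre-fall
  phases (slide speeds, tilt angles) that are plausible but not fitted to
  measured falls.
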