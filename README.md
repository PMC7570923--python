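# ffhdetect

Pre-impact detection of falls from heights (FFH) from a single trunk-worn
inertial measurement unit, for wearable protective airbags.

Industrial falls from elevated workplaces are among the deadliest
occupational accidents. A wearable airbag can mitigate the impact, but only
if the fall is recognized *before* floor contact — roughly 100 ms are needed
to inflate the bag. This package implements a threshold-based pre-impact FFH
detector driven by two quantities computed causally from a 100 Hz
accelerometer/gyroscope stream at the seventh thoracic vertebra:

* **Vertical angle (VA)** — tilt of the trunk axis from the gravity
  vertical, `VA = acos(cos φ · cos θ)`, with roll φ and pitch θ estimated by
  a complementary filter whose accelerometer/gyro fusion error is corrected
  by a PI controller (the integral term absorbs gyro bias; the accelerometer
  branch is gated out in free fall and during impacts).
* **Vertical velocity (VV)** — downward speed obtained by conditionally
  gated Simpson integration of the gravity-compensated vertical
  acceleration `a_v = a_z,global + 1 g`:

  ```
  v_t = v_{t-2} + 1.2 · g · (a_{t-2} + 4 a_{t-1} + a_t) · Δt / 3   if a_t > 0.24 g
  v_t = 0.9 · v_{t-1}                                             otherwise
  ```

  The 0.24 g gate suppresses integration drift, the 0.9 attenuation resets
  the estimate between movements, and the 1.2 correction factor compensates
  the onset delay introduced by the gate and the causal 5 Hz low-pass filter.

The detector latches at the first sample where `VA > 40° and VV > 1.8 m/s`
(topples, forward falls) **or** `VV > 5 m/s` (vertical falls with no angle
change). The package also provides the threshold-tuning procedure (accuracy
over a 4 × 21 VA/VV grid with a lead-time tie-break), trial-level
sensitivity/specificity/accuracy and lead-time evaluation, and a
physics-based synthetic motion generator (occupational activities, jumps,
rigid vertical/forward falls, scaffold/roof/ladder scenarios) with
ground-truth orientation, velocity and impact times, so the entire pipeline
is testable without recorded data.

## Worked example

```python
import numpy as np
from ffhdetect import MotionSpec, run_detector, evaluate_suite, metrics
from ffhdetect.synthetic import simulate_vertical_fall, make_suite

trial = simulate_vertical_fall(2.0, MotionSpec(), np.random.default_rng(42))
result = run_detector(trial.trace)
print(f"detected={result.detected} branch={result.branch} "
      f"detection_time={result.detection_time:.2f} s")
print(f"collision_time={trial.collision_time:.3f} s  "
      f"lead={1000*(trial.collision_time - result.detection_time):.1f} ms")

suite = make_suite("mannequin", seed=0)   # 2 fall types x 3 heights x 5 reps
counts, leads = evaluate_suite(suite)
m = metrics(counts)
print(f"mannequin suite: sensitivity={m.sensitivity:.0f}%  "
      f"lead={leads.mean_ms:.1f} +/- {leads.sd_ms:.1f} ms (min {leads.min_ms:.1f})")
```

prints

```
detected=True branch=velocity-only detection_time=1.52 s
collision_time=1.679 s  lead=158.6 ms
mannequin suite: sensitivity=100%  lead=393.1 +/- 173.1 ms (min 158.6)
```

A 2 m rigid drop reaches the 5 m/s velocity-only threshold about 0.47 s
after release — the ~0.05 s lag behind the ideal crossing at
`5 / (1.2 · 9.81) ≈ 0.42 s` is the filter and gate delay — leaving a 159 ms
lead before the computed floor contact at `sqrt(2·2/9.81) ≈ 0.64 s` after
release. Across the whole mannequin-surrogate suite every fall is caught,
with shorter leads for low vertical drops and longer ones for topples,
which the angle branch catches early in the rotation.

The same pipeline is scriptable from the shell:

```sh
ffhdetect simulate --design experiment-1 --subjects 10 --reps 3 --seed 1 --out suite/
ffhdetect detect suite/experiment-1_s00_forward_ffh_r0.csv
ffhdetect evaluate suite/manifest.csv
ffhdetect tune suite/manifest.csv --grid-csv grid.csv --heatmap grid.png
```

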