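# damperopt

Two-level design optimization of a passive damper-clutch knee exoskeleton
on a reduced-order planar gait model.

A knee damper that a clutch engages only during selected gait phases can
offload the biological knee joint. Finding the best damping coefficient
`c` and clutch engagement pattern (any nonempty subset of the five gait
phases Early Stance, Late Stance, Lift Off, Swing, Landing — 31 patterns)
is a mixed continuous-categorical design problem. This package implements
the full two-loop architecture at desk scale:

- **outer loop** — Bayesian optimization (Gaussian process with a Matern
  kernel, acquisition drawn per-iteration from LCB / EI / PI) over
  `(c, pattern)`, with brute-force grid validation (41 damping values x
  31 patterns = 1271 designs) and multi-seed restarts;
- **inner loop** — CMA-ES adaptation of a parametric gait (Fourier joint
  trajectories + stride/pelvis parameters + stance load threshold),
  warm-started and box-constrained at the no-device baseline solution;
- **gait model** — prescribed-kinematics planar Newton-Euler inverse
  dynamics producing joint moments, intersegmental knee force, GRFs, a
  five-phase gait segmentation, a metabolic-power proxy, the top-percentile
  knee-load statistic, and cost of transport;
- **fixtures** — packaged level/downhill baseline gait presets, scripted
  phase-machine traces, and a noisy synthetic design-cost surface with a
  known optimum for end-to-end validation.

The design cost is `w1 * KL/KL_base + w2 * COT/COT_base` (knee load and
cost of transport normalized by the device-free baseline; invalid gaits
get a fixed penalty).

## Layout

| module | contents |
| --- | --- |
| `damperopt.device` | damper torque law, clutch patterns, design grid |
| `damperopt.phases` | five-phase state machine, stride detection |
| `damperopt.gait_model` | kinematics synthesis, inverse dynamics, simulation pipeline |
| `damperopt.inner_loop` | movement cost, CMA-ES, controller optimization |
| `damperopt.outer_loop` | design cost, Bayesian optimizer, brute force, restarts |
| `damperopt.reporting` | gait-cycle normalization, peak tables, heat-map CSV |
| `damperopt.fixtures` | presets, scripted traces, known-optimum surrogate |

## CLI

```sh
# optimize and export the no-device baseline gait
damperopt baseline --scenario level --out results/

# best-of-5 Bayesian design optimization (gait model; slow)
damperopt optimize --scenario downhill --seeds 0,1,2,3,4 --out results/

# quick end-to-end check on the synthetic known-optimum surface
damperopt optimize --surrogate --seeds 0,1,2,3,4 --out results/

# brute-force design grid -> long-format heat-map table
damperopt grid --surrogate --n-c 41 --out results/

# summarize restart best costs (median, quartiles, extremes)
damperopt report --traces results/ --out results/
```

Traces are written as CSV (`iteration, c, pattern_mask, pattern_names,
cost, best_cost, acquisition`), run metadata as JSON with a config hash.

## Notes on the reduced model

Gait is prescribed, not forward-simulated: joint angles are truncated
Fourier series, the left leg runs half a stride out of phase, and ground
reaction forces are whatever closes the whole-body equations of motion,
split between feet by a smooth logistic weight on foot clearance. The
device torque (`-c * omega` while engaged, exactly zero otherwise) is a
pure couple between thigh and shank, so the biological knee moment is the
net inverse-dynamics moment minus the device torque. Absolute magnitudes
are not calibrated to human data; the design cost uses baseline-normalized
ratios only.
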