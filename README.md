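# cbmfit

Constructing and validating conductance-based neuron models (CBMs):
simulate reduced Hodgkin–Huxley neurons, fit their free parameters to
electrophysiology feature targets with multi-objective genetic
optimization, and quantify how models trained on one stimulus class
(steps, ramps, colored noise) generalize to stimuli they never saw.

## Who this is for

Cellular electrophysiologists and modellers who constrain biophysical
neuron models from current-clamp recordings and want a principled answer
to *which stimuli are worth injecting*: a model that merely reproduces
its training responses may be badly over-fit, and the honest measure of
its validity is its error on held-out stimuli.  `cbmfit` packages the
whole loop — stimulus design, simulation, feature-based scoring,
NSGA-II fitting, acceptance, generalization matrices, and
parameter-space zone analysis — plus a surrogate-data generator that
emulates repeated recordings from a known ground-truth cell so every
step can be tested end to end without animal data.

## The core machinery

- **Model.** Soma + passive cable, eight somatic conductances (Nat, Kd,
  Kp, Kv3.1, Ca, SK, Ih, Im) in HH form; 11 free parameters (8 maximal
  conductance densities ḡᵢ, leak reversal E_leak, somatic and dendritic
  leak densities).  Implicit integration at dt = 0.025 ms with tabulated
  Rush–Larsen gating (numba-compiled).
- **Distances.**  For step/ramp responses, per-feature errors
  |f_model − f̄_exp| / SD_exp over six step features (AP count, first-AP
  latency, accommodation index, AP half-width, AP height, AHP depth)
  plus amplitude slopes for ramps.  For noise responses, the gamma
  coincidence factor Γ — chance-corrected spike coincidences within
  ±2 ms, normalized by the intrinsic reliability of repeated
  recordings (Γ = 1: as precise as the neuron itself; Γ = 0: Poisson
  chance).
- **Optimization.**  NSGA-II (Pareto domination, crowding distance, SBX
  crossover, polynomial mutation), 300 × 1500 × 10 repeats at production
  scale → 3000 candidate models, of which those within **2 experimental
  SDs on every feature** are accepted.
- **Generalization.**  Five training plans (4 steps / 4 ramps /
  2 steps + 2 ramps / noise 1 / noise 2, 8 s of stimulus each) scored on
  held-out steps, ramps and both noise types; plus grid-based
  consistency masks quantifying how stimuli carve zones in parameter
  space and how those zones shrink and intersect.

See `docs/methods.md` for assumptions, numerics and limitations.

## Worked example

Generate surrogate "recordings" (10 noisy repetitions of a 150 pA step)
from the shipped ground-truth model, then score a perturbed candidate:

```python
import numpy as np
from cbmfit import (SimulationConfig, Morphology, simulate, detect_spikes,
                    extract_step_features, make_step, feature_error)
from cbmfit.surrogate import generate, ground_truth_parameters, NoiseModel

morph = Morphology()
config = SimulationConfig(dt=0.1, settle_ms=100.0)
stim = make_step(150.0, onset_s=0.1, duration_s=1.0, tail_s=0.05, dt_ms=0.1)

dataset = generate(battery={"step150": stim}, n_reps=10,
                   noise=NoiseModel(sigma_pA=10.0), seed=3,
                   morphology=morph, config=config)
targets = dataset.feature_targets("step150")

candidate = ground_truth_parameters().with_values(gbar_nat=0.45)
trace = simulate(candidate, morph, stim, config)
fv = extract_step_features(trace, detect_spikes(trace), stim)
errs = {f: feature_error(fv[f], targets, f) for f in targets.features()}
```

Output:

```
feature            mean      sd
n_ap                  11.00   0.500
latency_first_ap       5.45   1.000
accommodation_index    -0.00   0.010
ap_halfwidth           0.34   0.050
ap_height_mean        37.61   1.069
ahp_depth_mean       -83.07   0.500

candidate errors (SD units):
n_ap                 0.00
latency_first_ap     0.13
accommodation_index   0.16
ap_halfwidth         0.36
ap_height_mean       0.76
ahp_depth_mean       0.24
max error: 0.76 -> accepted
```

The target table is the "experiment": feature means and SDs over the 10
repetitions.  Raising ḡ_Nat from 0.40 to 0.45 S/cm² leaves every feature
within 0.8 experimental SDs — this candidate passes the 2-SD acceptance
criterion.  `cbmfit.generalization.train` runs the same scoring inside
NSGA-II to find all such models, and `evaluate` measures their error on
held-out stimuli.

A `cbmfit` command-line tool wraps the workflow
(`simulate | make-surrogate | fit | evaluate | grid`); see
`cbmfit --help`.

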