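# Methods

## The model

`cbmfit` builds conductance-based models (CBMs) of single neurons: a
reduced morphology — a cylindrical soma (20 × 20 µm by default) attached to
an unbranched passive dendritic cable (10 compartments of 100 × 2 µm) —
with eight Hodgkin–Huxley-style conductances in the somatic membrane:

| channel | gates | reversal | role |
|---|---|---|---|
| Nat | m³h | +50 mV | transient Na⁺, spike upstroke |
| Kd | n⁴ | −85 mV | delayed rectifier, repolarization |
| Kp | m²h | −85 mV | slow-inactivating persistent K⁺ |
| Kv3.1 | m | −85 mV | fast non-inactivating K⁺ |
| Ca | m²h | +120 mV | high-voltage-activated Ca²⁺ |
| SK | z(Ca) | −85 mV | Ca²⁺-dependent K⁺, adaptation |
| Ih | m | −45 mV | hyperpolarization-activated cation |
| Im | m | −85 mV | M-type K⁺, slow adaptation |

Specific capacitance is 1 µF/cm² and axial resistivity 150 Ω·cm.  Membrane
voltage obeys the cable equation with channel currents
I = ḡ·∏xᵢ^pᵢ·(V−E); each gate relaxes as dx/dt = (x∞(V) − x)/τ(V).
Internal calcium is a single somatic pool with first-order decay
(τ = 80 ms, resting 0.1 µM) fed by the Ca channel current; SK activation
reads this pool through a Hill curve (EC₅₀ 0.43 µM, coefficient 4.8).

The **eleven free parameters** are the eight maximal conductance densities
(S/cm²), the leak reversal potential E_leak (mV), and separate somatic and
dendritic leak densities (S/cm²).  Default bounds are broad physiological
ranges for neocortical somata and are configuration, not measurements.

### Kinetics

Gate curves are declarative: Boltzmann steady states
x∞ = 1/(1+exp(−(V−V½)/k)) and constant, bell-shaped or sigmoidal time
constants, serializable to JSON.  The shipped parameter values are
representative of the named channel families in cortical pyramidal
neurons (e.g. Kv3.1 activating near +19 mV with sub-ms kinetics at spike
potentials; Na half-inactivation near −60 mV; Im/Kp time constants of
tens to hundreds of ms).  They are design defaults chosen so the model
family displays the relevant physiology — transient and sustained K⁺
currents, spike-frequency adaptation, sag — and can be replaced wholesale
by any published kinetics via `ChannelSet.from_json`.

### Numerics

Voltage uses an implicit θ-method (backward Euler by default, θ = 1;
Crank–Nicolson optional) over the tridiagonal cable system at
dt = 0.025 ms; gates use the exponential-relaxation (Rush–Larsen) update
with x∞ and exp(−dt/τ) pre-tabulated on a 0.1 mV grid over
[−120, +60] mV, removing transcendentals from the inner loop (compiled
with numba).  Simulations start from the steady-state initialization
(gates at x∞(V_hold), calcium at rest) followed by a 200 ms settle window
that is discarded.  Backward Euler at this dt reproduces the isopotential
passive closed form to < 0.1 mV and halving dt changes subthreshold
traces by < 1 mV.  A non-finite state aborts with the failing step index.
Desk-scale fitting runs use dt = 0.1 ms with a 100 ms settle; targets and
candidates are always evaluated at the same dt, so fitting is
self-consistent at either resolution.

## Stimuli

The battery mirrors a standard current-clamp protocol: six 2 s
depolarizing steps (100–225·k pA), five 2 s rising ramps (0→125–250·k pA;
only the rising phase is used), two 20 s Ornstein–Uhlenbeck colored-noise
currents with 2 ms correlation time — type 1: mean 50·k, SD 100·k pA;
type 2: mean 100·k, SD 50·k pA — and subthreshold chirps.  k is a
per-cell scale factor bringing firing into the 2–20 Hz range.  (Parts of
the literature label the noise types the other way around; this package
follows the generating definition: type 1 = low mean / high SD.)

The OU generator uses the exact discretization
x_{t+dt} = µ + (x_t−µ)e^{−dt/τ} + σ√(1−e^{−2dt/τ})·ξ with the initial
sample drawn from the stationary law, so every sample has exactly the
nominal mean and SD and realizations are bit-reproducible per seed.

## Features and distances

Spikes are upward crossings of −20 mV (linear sub-sample interpolation,
1 ms refractory).  Step responses yield six features: AP count, latency
to first AP from stimulus onset, accommodation index
A = (1/(N−k−1))·Σ (ISIᵢ−ISIᵢ₋₁)/(ISIᵢ+ISIᵢ₋₁) with the first
k = min(4, ⌊N/5⌋) intervals skipped, mean AP half-width (at half of
peak−threshold-base; flanks linearly interpolated), mean AP peak height,
and mean AHP depth (minimum between consecutive spikes).  Ramp responses
add least-squares slopes of AP height and AHP depth against spike index.
AP peaks and AHP minima are parabolic-interpolated around the extremal
sample; without this, peak quantization at coarse dt (~1–3 mV at
dt = 0.1 ms) dominates the error budget.  Latency is measured at the
threshold crossing, not the peak.

Features that a response cannot define (no spikes, too few spikes) are
NaN, never zero; a model with an undefined feature scores a fixed penalty
(250 SD units) so it remains comparable but dominated.

Targets are per-feature means and sample SDs (n−1) over 10 repetitions.
SDs are floored at max(per-feature absolute floor, 0.5 % of |mean|) —
e.g. 0.5 spikes, 1 ms latency, 0.5 mV amplitudes — because noiseless
repetitions would otherwise make the SD-unit distance
|model−mean|/SD singular.

For noise stimuli the distance is the **gamma coincidence factor**:
Γ = (N_coinc − 2νΔN_data) / (½(N_model+N_data)) / (1 − 2νΔ) per
reference train (Δ = 2 ms, greedy one-to-one matching in time order,
chance level at the model's rate ν), normalized by the mean pairwise Γ
among the experimental repetitions.  1 means the model matches the data
as well as repetitions match each other; 0 means Poisson chance.  The
coincidence window and the mean (rather than minimum) intrinsic
normalization are conventions of the coincidence-factor literature; both
are configurable.

## Optimization

Fitting is multi-objective: one objective per (stimulus, feature) pair —
kept unreduced, no weight vector — or 1−GCF per noise stimulus.  An
optional aggregation mode averages each feature across stimuli; Pareto
selection pressure degrades as objectives multiply, so the aggregated
layout suits small populations.

The optimizer is NSGA-II with its canonical real-coded operators:
binary tournament on (rank, crowding), simulated binary crossover
(rate 0.9, η = 15), bounded polynomial mutation (rate 1/n, η = 20),
parents+offspring pooled and truncated by rank then crowding.  The
production configuration is 300 individuals × 1500 generations, repeated
10× from independent seeds and pooled into 3000 candidate models; tests
use 40 × 100 × 3.  A fixed generation budget is the only stopping rule.
Accepted models are those within **two experimental SDs on every
feature** (GCF ≥ 0.8 for noise objectives); thresholds configurable.

`train()` additionally enables Deb's constraint-domination with the
acceptance thresholds as the feasibility rule: models meeting every
threshold outrank all others, infeasible models rank by total excess.
With mutually consistent targets (as surrogate data are) the Pareto
front degenerates toward the ideal point and plain crowding actively
disperses small populations away from the acceptance region; anchoring
the ranking on the selection criterion keeps the final population inside
it.  `evolve()` defaults to pure Pareto ranking.

## Surrogate data

Because repeated recordings of a real cell are not distributable, the
surrogate module plays the role of the rig: a frozen ground-truth
parameter set (firing ~6–14 Hz on the steps, ~2.5–7.5 Hz on the ramps,
~8 Hz on the noise currents — the moderate 2–20 Hz regime) is simulated
against the battery, 10 repetitions per stimulus, each with an
independent additive OU current (σ = 10 pA, τ = 2 ms) as the
trial-to-trial variability source.  This produces realistic spike-time
jitter and feature spreads (e.g. ~0.5–1 mV AP-height SD) while the true
parameters remain known, enabling parameter-recovery and solution-space
tests.  What surrogate data do **not** emulate: electrode artifacts,
slow drift, channel stochasticity, morphological error, and model
mismatch — on real cells the model class itself is wrong to some degree,
so passing these tests demonstrates that the machinery works, not that
any particular cell is fit correctly.

## Generalization analysis

Five training plans (four steps; four ramps; 2 steps + 2 ramps; noise 1;
noise 2 — each 8 s of stimulus) are evaluated on held-out conditions
(remaining step and ramp intensities, both noise types); training and
test sets are disjoint by construction and overlap raises immediately.
Feature tests report mean ± SD of the pooled model × stimulus × feature
errors; noise tests report mean ± SD GCF across models.  Noise plans
consume their entire noise realization for training, so their
within-kind matrix cell is the training accuracy.  Significance between
error distributions, when wanted, is assessed with Mann–Whitney tests
(the harness exposes the raw per-model errors).

Grid analysis simulates every point of a regular parameter grid (default
9 points/axis over a chosen 2-axis subset, full bounds) against each
stimulus once and marks it consistent with a stimulus set when all
feature errors pass the criterion.  Zone areas are consistent-cell
counts; intersections |A∩B|/|A| quantify the probability that a model
consistent with stimulus set A also matches B — the generalization
asymmetry.  Adding a stimulus can only shrink a zone (mask intersection),
which the tests assert as the formal core of the analysis.

## Desk-scale test problem sizes

The shipped tests choose sizes that keep the full suite in the tens of
minutes on one core: fitting fixtures use the default morphology at
dt = 0.1 ms with 1 s steps/ramps and 10 repetitions; parameter recovery
frees 3 conductances (population 40 × 100 generations × 3 repeats,
5 seeds); the generalization-trend check frees 6 conductances
(24 × 40 × 3, 5 seeds) — with only 3 free dimensions a single stimulus
already pins the model and the trend flattens; grid tests use 9 × 9
two-axis grids.  The production-scale configuration (full battery at
dt = 0.025 ms, 300 × 1500 × 10, 11 free parameters, high-dimensional
grids) is the library default outside tests.

## Known limitations

- Shipped kinetics are representative, not cell-type calibrated; all
  recovery claims are relative to the shipped ground truth.
- Dendrites are passive and unbranched; no active dendritic channels.
- Calcium is a single pool with fixed influx coefficient; no buffering,
  no GHK flux.
- The greedy coincidence matcher is exact for sorted trains with a
  symmetric window but the chance-correction term assumes Poisson
  statistics at the model's rate.
- Constraint-domination makes acceptance overwhelmingly likely when a
  feasible model exists; it does not certify the zone is exhaustively
  sampled — grid analysis serves that purpose.
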