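"""Surrogate "experimental" datasets from a known ground-truth model.

Real constraining data are repeated somatic recordings of one neuron's
response to each stimulus.  This module emulates that protocol: a fixed
ground-truth parameter set is simulated against a stimulus battery, each
stimulus repeated n times (default 10, within the experimental 10–20
range) with an independent low-amplitude Ornstein–Uhlenbeck current added
per repetition as the trial-to-trial variability source.  Feature means
and SDs — and, for noise stimuli, repeated spike trains — then feed the
fitting machinery exactly as recorded data would, with the advantage that
the true parameters are known, enabling parameter-recovery and
solution-space tests.

Regeneration from the same master seed is bit-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .channels import ChannelSet, default_channelset
from .features import (
    FeatureStatistics,
    SpikeTrain,
    detect_spikes,
    extract_ramp_features,
    extract_step_features,
    summarize_repetitions,
)
from .model import (
    ParameterVector,
    SimulationConfig,
    VoltageTrace,
    default_bounds,
    simulate,
)
from .morphology import Morphology
from .stimuli import StimulusProtocol, _ou_path, default_battery

__all__ = [
    "NoiseModel",
    "SurrogateDataset",
    "ground_truth_parameters",
    "generate",
]

#: Frozen ground-truth parameter set for the shipped channel kinetics and the
#: default reduced morphology; fires at 2–20 Hz across the default battery
#: (steps ~6–14 Hz, ramps ~2.5–7.5 Hz, OU noise ~8 Hz).
GROUND_TRUTH = {
    "gbar_nat": 0.4,
    "gbar_kd": 0.15,
    "gbar_kp": 0.005,
    "gbar_kv31": 0.6,
    "gbar_ca": 0.004,
    "gbar_sk": 0.03,
    "gbar_ih": 1e-4,
    "gbar_im": 2e-3,
    "e_leak": -75.0,
    "g_leak_soma": 3e-5,
    "g_leak_dend": 3e-5,
}


def ground_truth_parameters(bounds=None) -> ParameterVector:
    return ParameterVector.from_dict(GROUND_TRUTH, bounds or default_bounds())


@dataclass(frozen=True)
class NoiseModel:
    """Trial-to-trial variability: additive OU current at the electrode.

    ``sigma_pA`` = 0 reproduces the deterministic model exactly (identical
    repetitions, feature SDs at the floor).
    """

    sigma_pA: float = 10.0
    tau_ms: float = 2.0

    def __post_init__(self):
        if self.sigma_pA < 0 or self.tau_ms <= 0:
            raise ValueError("noise sigma must be >= 0 and tau > 0")


class _NoisyStimulus:
    """A stimulus with a realized additive noise path (duck-typed)."""

    def __init__(self, base: StimulusProtocol, noise_pA: np.ndarray):
        self.dt = base.dt
        self._i = base.current_pA() + noise_pA

    def current_pA(self) -> np.ndarray:
        return self._i


@dataclass
class SurrogateDataset:
    """Repeated voltage responses of the ground-truth model per stimulus."""

    params: ParameterVector
    battery: dict[str, StimulusProtocol]
    traces: dict[str, list[VoltageTrace]]
    noise: NoiseModel
    seed: int
    morphology: Morphology
    config: SimulationConfig
    warnings_: list[str] = field(default_factory=list)

    @property
    def n_reps(self) -> int:
        return len(next(iter(self.traces.values())))

    def spike_trains(self, name: str, threshold: float = -20.0) -> list[SpikeTrain]:
        return [detect_spikes(tr, threshold) for tr in self.traces[name]]

    def feature_targets(self, name: str) -> FeatureStatistics:
        """Per-feature mean/SD over the repetitions of one step or ramp."""
        stim = self.battery[name]
        if stim.kind not in ("step", "ramp"):
            raise ValueError(f"feature targets undefined for kind {stim.kind!r}")
        extract = extract_step_features if stim.kind == "step" else extract_ramp_features
        vecs = [
            extract(tr, detect_spikes(tr), stim) for tr in self.traces[name]
        ]
        return summarize_repetitions(vecs)

    def manifest(self) -> dict:
        return {
            "seed": self.seed,
            "n_reps": self.n_reps,
            "noise": {"sigma_pA": self.noise.sigma_pA, "tau_ms": self.noise.tau_ms},
            "params": self.params.to_dict(),
            "morphology": self.morphology.to_dict(),
            "dt": self.config.dt,
            "stimuli": {k: v.to_dict() for k, v in self.battery.items()},
            "warnings": list(self.warnings_),
        }

    # ---- persistence ---------------------------------------------------
    def save(self, h5_path, manifest_path=None) -> None:
        import h5py

        with h5py.File(h5_path, "w") as f:
            f.attrs["manifest"] = json.dumps(self.manifest())
            for name, reps in self.traces.items():
                grp = f.create_group(name)
                grp.attrs["dt"] = reps[0].dt
                for i, tr in enumerate(reps):
                    grp.create_dataset(f"rep{i:03d}", data=tr.voltage)
        if manifest_path is not None:
            with open(manifest_path, "w") as fh:
                json.dump(self.manifest(), fh, indent=2)

    @classmethod
    def load(cls, h5_path) -> "SurrogateDataset":
        import h5py

        with h5py.File(h5_path, "r") as f:
            man = json.loads(f.attrs["manifest"])
            traces = {}
            for name in man["stimuli"]:
                grp = f[name]
                dt = float(grp.attrs["dt"])
                traces[name] = [
                    VoltageTrace(dt=dt, voltage=grp[key][...])
                    for key in sorted(grp.keys())
                ]
        return cls(
            params=ParameterVector.from_dict(man["params"]),
            battery={k: StimulusProtocol.from_dict(v)
                     for k, v in man["stimuli"].items()},
            traces=traces,
            noise=NoiseModel(**man["noise"]),
            seed=man["seed"],
            morphology=Morphology.from_dict(man["morphology"]),
            config=SimulationConfig(dt=man["dt"]),
            warnings_=list(man.get("warnings", [])),
        )


def generate(
    ground_truth: ParameterVector | None = None,
    battery: dict[str, StimulusProtocol] | None = None,
    n_reps: int = 10,
    noise: NoiseModel | None = None,
    seed: int = 0,
    morphology: Morphology | None = None,
    config: SimulationConfig | None = None,
    channelset: ChannelSet | None = None,
) -> SurrogateDataset:
    """Simulate the ground truth against each battery stimulus, n_reps times.

    Each repetition draws an independent OU noise current (seeded from the
    master seed via a spawn tree keyed on battery order), added to the
    stimulus before injection.  A warning is recorded in the manifest when
    a step or ramp stimulus elicits no spike.
    """
    if n_reps < 2:
        raise ValueError("need at least 2 repetitions per stimulus")
    params = ground_truth or ground_truth_parameters()
    battery = battery if battery is not None else default_battery()
    noise = noise or NoiseModel()
    morphology = morphology or Morphology()
    config = config or SimulationConfig()
    chans = channelset or default_channelset()

    stim_seeds = np.random.SeedSequence(seed).spawn(len(battery))
    traces: dict[str, list[VoltageTrace]] = {}
    warns: list[str] = []
    for (name, stim), ss in zip(battery.items(), stim_seeds):
        rep_rngs = ss.spawn(n_reps)
        n = stim.n_samples
        reps = []
        for r in range(n_reps):
            rng_seed = rep_rngs[r]
            if noise.sigma_pA > 0:
                path = _ou_path(0.0, noise.sigma_pA, noise.tau_ms, n, stim.dt,
                                np.random.default_rng(rng_seed))
                s = _NoisyStimulus(stim, path)
            else:
                s = stim
            reps.append(simulate(params, morphology, s, config, chans))
        traces[name] = reps
        if stim.kind in ("step", "ramp"):
            if len(detect_spikes(reps[0])) == 0:
                msg = f"ground truth does not spike on stimulus {name!r}"
                warns.append(msg)
                warnings.warn(msg, stacklevel=2)

    return SurrogateDataset(
        params=params, battery=battery, traces=traces, noise=noise,
        seed=seed, morphology=morphology, config=config, warnings_=warns,
    )
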