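"""Readers and writers for traces, protocols, populations and reports.

Plain-text formats throughout: CSV for traces (time_ms, voltage_mV),
waveforms (time_ms, current_pA) and pooled populations; JSON/YAML for
configuration and score payloads; HDF5 (via :mod:`cbmfit.surrogate`) for
multi-trace datasets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .channels import PARAM_NAMES, ChannelSet, default_channelset
from .model import ParameterVector, SimulationConfig, default_bounds
from .morphology import Morphology
from .optimizer import AcceptanceCriterion, EvolutionResult, GAConfig
from .stimuli import StimulusProtocol, default_battery

__all__ = [
    "RunConfig",
    "write_trace_csv",
    "read_trace_csv",
    "write_waveform_csv",
    "write_population_csv",
    "read_population_csv",
    "load_run_config",
]


def write_trace_csv(path, trace) -> None:
    pd.DataFrame({"time_ms": trace.times, "voltage_mV": trace.voltage}).to_csv(
        path, index=False)


def read_trace_csv(path):
    from .model import VoltageTrace

    df = pd.read_csv(path)
    t = df["time_ms"].to_numpy()
    dt = float(t[1] - t[0]) if t.size > 1 else 1.0
    return VoltageTrace(dt=dt, voltage=df["voltage_mV"].to_numpy())


def write_waveform_csv(path, stimulus: StimulusProtocol) -> None:
    pd.DataFrame({
        "time_ms": stimulus.times_ms, "current_pA": stimulus.current_pA(),
    }).to_csv(path, index=False)


def write_population_csv(path, result: EvolutionResult,
                         free: tuple[str, ...], labels) -> None:
    cols = {f"param_{n}": result.params[:, i] for i, n in enumerate(free)}
    for j, (stim, feat) in enumerate(labels):
        cols[f"err_{stim}_{feat}"] = result.objectives[:, j]
    cols["rank"] = result.ranks
    pd.DataFrame(cols).to_csv(path, index=False)


def read_population_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_feature_table_csv(path, vectors) -> None:
    """Feature table: one row per repetition, one column per feature."""
    rows = [{**fv.values} for fv in vectors]
    pd.DataFrame(rows).to_csv(path, index_label="repetition")


def write_feature_stats_json(path, stats) -> None:
    import math

    clean = lambda d: {k: (None if isinstance(v, float) and math.isnan(v) else v)
                       for k, v in d.items()}
    payload = {
        "kind": stats.kind,
        "mean": clean(stats.mean),
        "sd": clean(stats.sd),
        "n": stats.n,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def write_objectives_json(path, objective_vector) -> None:
    """ObjectiveVector with its (stimulus, feature) layout."""
    payload = [
        {"stimulus": s, "feature": f, "kind": k, "value": float(v)}
        for (s, f), k, v in zip(objective_vector.labels,
                                objective_vector.kinds,
                                objective_vector.values)
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class RunConfig:
    """Workflow configuration loaded from YAML/JSON.

    Optional file references (channels, morphology) must exist at load
    time; everything else has library defaults.  The seed is recorded in
    every output manifest together with the config hash.
    """

    seed: int = 0
    k: float = 1.0
    dt: float = 0.025
    settle_ms: float = 200.0
    out_dir: str = "runs"
    channels_file: str | None = None
    morphology: dict = field(default_factory=dict)
    bounds: dict = field(default_factory=dict)
    battery: dict = field(default_factory=dict)  # kwargs for default_battery
    ga: dict = field(default_factory=dict)
    criterion: dict = field(default_factory=dict)
    n_reps: int = 10
    noise_sigma_pA: float = 10.0
    free: list[str] = field(default_factory=lambda: list(PARAM_NAMES))
    ground_truth: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict, repr=False)

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.raw.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def channelset(self) -> ChannelSet:
        if self.channels_file:
            return ChannelSet.from_json(self.channels_file)
        return default_channelset()

    def make_morphology(self) -> Morphology:
        return Morphology(**self.morphology)

    def make_bounds(self) -> dict:
        b = default_bounds()
        b.update({k: tuple(v) for k, v in self.bounds.items()})
        return b

    def make_battery(self) -> dict[str, StimulusProtocol]:
        kw = dict(self.battery)
        kw.setdefault("k", self.k)
        kw.setdefault("dt_ms", self.dt)
        return default_battery(**kw)

    def make_sim_config(self) -> SimulationConfig:
        return SimulationConfig(dt=self.dt, settle_ms=self.settle_ms)

    def make_ga(self) -> GAConfig:
        kw = dict(self.ga)
        kw.setdefault("seed", self.seed)
        return GAConfig(**kw)

    def make_criterion(self) -> AcceptanceCriterion:
        return AcceptanceCriterion(**self.criterion)

    def make_ground_truth(self) -> ParameterVector:
        from .surrogate import GROUND_TRUTH

        vals = dict(GROUND_TRUTH)
        vals.update(self.ground_truth)
        return ParameterVector.from_dict(vals, self.make_bounds())


def load_run_config(path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
    data = data or {}
    known = {f for f in RunConfig.__dataclass_fields__ if f != "raw"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    cfg = RunConfig(**data, raw=dict(data))
    if cfg.channels_file and not Path(cfg.channels_file).exists():
        raise FileNotFoundError(f"channels file not found: {cfg.channels_file}")
    return cfg
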