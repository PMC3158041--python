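"""Conductance-based neuron simulator.

A reduced-morphology model in the Hodgkin–Huxley formalism: eight active
somatic conductances, passive dendrites, and a single-pool internal calcium
mechanism feeding the SK channel.  The eleven free parameters are the eight
maximal conductance densities, the leak reversal potential, and the somatic
and dendritic leak conductance densities.

Voltage integration is implicit (backward Euler by default) at dt = 0.025 ms
with Rush–Larsen gating updates; see :mod:`cbmfit._kernel`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .channels import (
    PARAM_NAMES,
    V_TABLE_MAX,
    V_TABLE_MIN,
    ChannelSet,
    default_channelset,
)
from .morphology import Morphology

__all__ = [
    "ParameterVector",
    "SimulationConfig",
    "VoltageTrace",
    "IntegrationError",
    "simulate",
    "steady_state_init",
    "default_bounds",
]

log = logging.getLogger(__name__)

N_PARAMS = 11


class IntegrationError(RuntimeError):
    """Raised when the integrator produced a non-finite state."""

    def __init__(self, step: int, time_ms: float):
        self.step = step
        self.time_ms = time_ms
        super().__init__(
            f"non-finite voltage at integration step {step} (t = {time_ms:.3f} ms)"
        )


def default_bounds() -> dict[str, tuple[float, float]]:
    """Default allowed ranges for the 11 free parameters.

    Conductance densities in S/cm², leak reversal in mV.  These are broad
    physiological ranges for neocortical somata; they are configuration
    defaults, intended to be overridden when known ranges exist.
    """
    return {
        "gbar_nat": (0.0, 1.0),
        "gbar_kd": (0.0, 1.0),
        "gbar_kp": (0.0, 0.2),
        "gbar_kv31": (0.0, 2.0),
        "gbar_ca": (0.0, 0.01),
        "gbar_sk": (0.0, 0.1),
        "gbar_ih": (0.0, 0.001),
        "gbar_im": (0.0, 0.01),
        "e_leak": (-90.0, -60.0),
        "g_leak_soma": (1e-5, 3e-4),
        "g_leak_dend": (1e-5, 3e-4),
    }


@dataclass(frozen=True)
class ParameterVector:
    """The model's 11 free parameters with per-entry bounds.

    Conductance densities are somatic, in S/cm²; ``e_leak`` in mV applies to
    soma and dendrite alike; the two leak densities (S/cm²) are separate for
    soma and dendrite.
    """

    values: np.ndarray
    bounds: dict[str, tuple[float, float]] = field(default_factory=default_bounds)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != (N_PARAMS,):
            raise ValueError(f"parameter vector must have length {N_PARAMS}")
        for i, name in enumerate(PARAM_NAMES):
            if name.startswith("g") and vals[i] < 0:
                raise ValueError(f"{name} must be non-negative")
            lo, hi = self.bounds[name]
            if not (lo <= vals[i] <= hi):
                raise ValueError(
                    f"{name} = {vals[i]:g} outside bounds [{lo:g}, {hi:g}]"
                )

    @classmethod
    def from_dict(cls, d: dict, bounds=None) -> "ParameterVector":
        vals = np.array([d[name] for name in PARAM_NAMES], dtype=float)
        return cls(vals, bounds or default_bounds())

    def to_dict(self) -> dict:
        return dict(zip(PARAM_NAMES, self.values.tolist()))

    def __getitem__(self, name: str) -> float:
        return float(self.values[PARAM_NAMES.index(name)])

    def with_values(self, **updates) -> "ParameterVector":
        d = self.to_dict()
        d.update(updates)
        vals = np.array([d[name] for name in PARAM_NAMES], dtype=float)
        return ParameterVector(vals, self.bounds)


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings.

    ``v_init`` of None holds the model at the leak reversal potential; the
    settle window is simulated with zero current and discarded so traces
    start from (approximate) rest.
    """

    dt: float = 0.025  # ms
    integrator: str = "backward_euler"  # or "crank_nicolson"
    v_init: float | None = None
    settle_ms: float = 200.0
    record_calcium: bool = False

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.settle_ms < 0:
            raise ValueError("settle time must be non-negative")
        if self.integrator not in ("backward_euler", "crank_nicolson"):
            raise ValueError(f"unknown integrator {self.integrator!r}")

    @property
    def theta(self) -> float:
        return 1.0 if self.integrator == "backward_euler" else 0.5


@dataclass(frozen=True)
class VoltageTrace:
    """Somatic voltage sampled at uniform dt, settle period already removed."""

    dt: float  # ms
    voltage: np.ndarray  # mV, length round(duration/dt) + 1
    calcium: np.ndarray | None = None  # mM, same length, optional diagnostic

    def __post_init__(self):
        v = np.asarray(self.voltage, dtype=float)
        object.__setattr__(self, "voltage", v)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(v)):
            raise ValueError("voltage trace contains non-finite samples")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.voltage.size) * self.dt

    @property
    def duration(self) -> float:
        return (self.voltage.size - 1) * self.dt


# --------------------------------------------------------------------------
# compiled-kernel argument packing, cached per (channelset, morphology, dt)

_TABLE_DV = 0.1  # mV resolution of the gating lookup tables
_pack_cache: dict = {}


class _Packed:
    """Immutable per-configuration arrays consumed by the kernel."""

    def __init__(self, chans: ChannelSet, morph: Morphology, dt: float):
        chans.validate()
        n_v = int(round((V_TABLE_MAX - V_TABLE_MIN) / _TABLE_DV)) + 1
        vgrid = V_TABLE_MIN + _TABLE_DV * np.arange(n_v)

        gate_chan, gate_power, gate_is_ca = [], [], []
        inf_rows, relax_rows = [], []
        sk_relax = 1.0
        sk_ec50, sk_hill = 4.3e-4, 4.8
        ca_chan = -1
        erev, gbar_keys, names = [], [], []
        for ci, ch in enumerate(chans.channels):
            erev.append(ch.erev)
            gbar_keys.append(ch.gbar_key)
            names.append(ch.name)
            if ch.carries_calcium:
                ca_chan = ci
            for g in ch.gates:
                gate_chan.append(ci)
                gate_power.append(g.power)
                gate_is_ca.append(1 if g.calcium else 0)
                if g.calcium:
                    sk_ec50, sk_hill = g.ec50, g.hill
                    sk_relax = float(np.exp(-dt / g.tau["value"]))
                    inf_rows.append(np.zeros(n_v))
                    relax_rows.append(np.zeros(n_v))
                else:
                    inf_rows.append(g.x_inf(vgrid))
                    relax_rows.append(np.exp(-dt / g.tau_x(vgrid)))

        self.channelset = chans
        self.morph = morph
        self.dt = dt
        self.n_v = n_v
        self.vgrid = vgrid
        self.erev = np.asarray(erev)
        self.gbar_keys = tuple(gbar_keys)
        self.gate_chan = np.asarray(gate_chan, dtype=np.int64)
        self.gate_power = np.asarray(gate_power, dtype=np.int64)
        self.gate_is_ca = np.asarray(gate_is_ca, dtype=np.int64)
        self.tab_inf = np.ascontiguousarray(inf_rows)
        self.tab_relax = np.ascontiguousarray(relax_rows)
        self.sk_ec50, self.sk_hill, self.sk_relax = sk_ec50, sk_hill, sk_relax
        self.ca_chan = ca_chan
        self.areas = morph.areas_cm2()
        self.cm = morph.capacitances_nF()
        self.g_ax = morph.axial_conductances_uS()
        self.soma_area = self.areas[0]


def _packed(chans: ChannelSet, morph: Morphology, dt: float) -> _Packed:
    key = (id(chans), id(morph), dt)
    p = _pack_cache.get(key)
    if p is None:
        p = _Packed(chans, morph, dt)
        if len(_pack_cache) > 64:
            _pack_cache.clear()
        _pack_cache[key] = p
    return p


def _absolute_conductances(params: ParameterVector, pk: _Packed):
    """Densities (S/cm²) -> absolute µS at the soma; leak per compartment."""
    pd = params.to_dict()
    gbar = np.array([pd[k] for k in pk.gbar_keys]) * pk.soma_area * 1e6
    g_leak = np.empty(pk.morph.n_comp)
    g_leak[0] = pd["g_leak_soma"] * pk.areas[0] * 1e6
    g_leak[1:] = pd["g_leak_dend"] * pk.areas[1:] * 1e6
    return gbar, g_leak, pd["e_leak"]


def steady_state_init(
    params: ParameterVector,
    morphology: Morphology,
    config: SimulationConfig,
    channelset: ChannelSet | None = None,
):
    """Full model state at the holding potential.

    Every gating variable is set to its steady-state value at ``v_init``
    (the calcium gate at the resting calcium concentration) and all
    compartments to ``v_init``.  Idempotent by construction.

    Returns ``(v, x, ca)``: per-compartment voltage, gating vector, calcium.
    """
    chans = channelset or default_channelset()
    v_hold = config.v_init if config.v_init is not None else params["e_leak"]
    v = np.full(morphology.n_comp, float(v_hold))
    x = []
    ca0 = chans.calcium.rest
    for ch in chans.channels:
        for g in ch.gates:
            x.append(float(g.x_inf_ca(ca0)) if g.calcium else float(g.x_inf(v_hold)))
    return v, np.asarray(x), np.array([ca0])


def simulate(
    params: ParameterVector,
    morphology: Morphology,
    stimulus,
    config: SimulationConfig | None = None,
    channelset: ChannelSet | None = None,
) -> VoltageTrace:
    """Somatic voltage response to an injected current.

    ``stimulus`` is a :class:`cbmfit.stimuli.StimulusProtocol` (anything with
    ``current_pA()`` and ``dt`` works).  The current is injected at the
    soma.  The settle window precedes the stimulus and is discarded.

    Raises :class:`IntegrationError` if the state becomes non-finite.
    """
    config = config or SimulationConfig()
    chans = channelset or default_channelset()
    pk = _packed(chans, morphology, config.dt)

    i_pa = np.asarray(stimulus.current_pA(), dtype=float)
    stim_dt = float(stimulus.dt)
    if abs(stim_dt - config.dt) > 1e-12:
        warnings.warn(
            f"resampling stimulus from dt={stim_dt} ms to dt={config.dt} ms",
            stacklevel=2,
        )
        t_old = np.arange(i_pa.size) * stim_dt
        t_new = np.arange(0.0, t_old[-1] + config.dt / 2, config.dt)
        i_pa = np.interp(t_new, t_old, i_pa)

    n_settle = int(round(config.settle_ms / config.dt))
    i_nA = np.concatenate([np.zeros(n_settle), i_pa * 1e-3])

    gbar, g_leak, e_leak = _absolute_conductances(params, pk)
    v, x, ca = steady_state_init(params, morphology, config, chans)

    n_steps = i_nA.size - 1 if i_nA.size > 1 else 0
    out_v = np.empty(n_steps + 1)
    out_ca = np.empty(n_steps + 1)
    bad = _kernel.integrate(
        v, x, ca, i_nA[:n_steps], config.dt, config.theta,
        pk.cm / config.dt, g_leak, e_leak, pk.g_ax,
        gbar, pk.erev,
        pk.gate_chan, pk.gate_power, pk.gate_is_ca,
        pk.tab_inf, pk.tab_relax,
        V_TABLE_MIN, 1.0 / _TABLE_DV, pk.n_v,
        pk.sk_ec50, pk.sk_hill, pk.sk_relax,
        pk.ca_chan, chans.calcium.rest, chans.calcium.tau, chans.calcium.k_influx,
        out_v, out_ca,
    )
    if bad != _kernel.OK:
        raise IntegrationError(bad, (bad - n_settle) * config.dt)

    volt = out_v[n_settle:]
    cal = out_ca[n_settle:] if config.record_calcium else None
    return VoltageTrace(dt=config.dt, voltage=volt, calcium=cal)
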