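"""Declarative Hodgkin–Huxley channel kinetics.

Each channel is described by a reversal potential and a list of gating
variables.  A voltage-dependent gate carries a Boltzmann steady-state curve
x_inf(V) and a time-constant curve tau_x(V) (constant, bell-shaped or
sigmoidal); a calcium-dependent gate (the SK channel's activation) instead
carries a Hill curve in the internal calcium concentration with a fixed time
constant.  Definitions are plain parameter dictionaries, round-trippable
through JSON, so the shipped set can be swapped for any other published
kinetics without touching the simulator.

The shipped default set covers the eight channel families present in the
modelled soma of neocortical neurons: transient sodium (Nat), delayed
rectifier potassium (Kd), slow inactivating persistent potassium (Kp), fast
non-inactivating potassium (Kv3.1), high-voltage-activated calcium (Ca),
calcium-dependent potassium (SK), hyperpolarization-activated cation (Ih)
and M-type potassium (Im).  Curve parameters are representative values for
these families in cortical pyramidal neurons; they are design defaults, not
measurements.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "ChannelSet",
    "default_channelset",
    "PARAM_NAMES",
]

#: canonical ordering of the 11 free parameters
PARAM_NAMES = (
    "gbar_nat",
    "gbar_kd",
    "gbar_kp",
    "gbar_kv31",
    "gbar_ca",
    "gbar_sk",
    "gbar_ih",
    "gbar_im",
    "e_leak",
    "g_leak_soma",
    "g_leak_dend",
)

V_TABLE_MIN = -120.0  # mV, tabulation window for gating curves
V_TABLE_MAX = 60.0


@dataclass(frozen=True)
class GateSpec:
    """One gating variable x with dynamics dx/dt = (x_inf - x) / tau_x."""

    var: str
    power: int = 1
    #: Boltzmann steady state: 1 / (1 + exp(-(V - vhalf)/slope)).
    #: slope < 0 yields an inactivation curve.  Ignored for calcium gates.
    inf: dict = field(default_factory=dict)
    #: tau curve, one of
    #:   {"kind": "constant", "value": tau_ms}
    #:   {"kind": "bell", "base": t0, "amp": A, "vmax": Vp, "sigma": s}
    #:       tau(V) = t0 + A * exp(-((V - Vp)/s)**2)
    #:   {"kind": "sigmoid", "base": t0, "amp": A, "vhalf": Vh, "slope": k}
    #:       tau(V) = t0 + A / (1 + exp(-(V - Vh)/k))
    tau: dict = field(default_factory=dict)
    #: if set, the gate reads internal calcium (mM), not voltage:
    #: x_inf = 1 / (1 + (ec50/ca)**hill), tau from tau["value"]
    calcium: bool = False
    ec50: float = 4.3e-4
    hill: float = 4.8

    def __post_init__(self):
        if self.power < 1 or self.power != int(self.power):
            raise ValueError(f"gate {self.var}: power must be a positive integer")

    def x_inf(self, v):
        """Steady-state activation at voltage v (mV), vectorized."""
        if self.calcium:
            raise ValueError("calcium gate steady state depends on [Ca], not V")
        vh, k = self.inf["vhalf"], self.inf["slope"]
        return 1.0 / (1.0 + np.exp(-(np.asarray(v, float) - vh) / k))

    def x_inf_ca(self, ca):
        ca = np.maximum(np.asarray(ca, float), 1e-12)
        return 1.0 / (1.0 + (self.ec50 / ca) ** self.hill)

    def tau_x(self, v):
        """Time constant (ms) at voltage v, vectorized; strictly positive."""
        v = np.asarray(v, float)
        t = self.tau
        kind = t.get("kind", "constant")
        if kind == "constant":
            out = np.full_like(v, float(t["value"]))
        elif kind == "bell":
            out = t["base"] + t["amp"] * np.exp(-(((v - t["vmax"]) / t["sigma"]) ** 2))
        elif kind == "sigmoid":
            out = t["base"] + t["amp"] / (1.0 + np.exp(-(v - t["vhalf"]) / t["slope"]))
        else:
            raise ValueError(f"unknown tau kind {kind!r}")
        return np.maximum(out, 1e-3)


@dataclass(frozen=True)
class ChannelSpec:
    """An ionic conductance: g = gbar * prod_i x_i^p_i, I = g * (V - erev)."""

    name: str
    gbar_key: str  # which entry of the parameter vector scales this channel
    erev: float  # mV; for the calcium channel this is a fixed nernst-like value
    gates: tuple[GateSpec, ...]
    carries_calcium: bool = False  # contributes to internal calcium influx


@dataclass(frozen=True)
class CalciumSpec:
    """Single-pool internal calcium: d[Ca]/dt = -k_influx*I_Ca - ([Ca]-rest)/tau.

    I_Ca in nA (inward negative, so -k_influx*I_Ca >= 0 during influx),
    concentrations in mM, tau in ms.  k_influx folds the shell volume and
    Faraday constant into one coefficient.
    """

    rest: float = 1e-4  # mM
    tau: float = 80.0  # ms
    k_influx: float = 5e-5  # mM / (ms * nA)


@dataclass(frozen=True)
class ChannelSet:
    channels: tuple[ChannelSpec, ...]
    calcium: CalciumSpec = field(default_factory=CalciumSpec)

    def __post_init__(self):
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError("duplicate channel names")

    @property
    def n_gates(self) -> int:
        return sum(len(c.gates) for c in self.channels)

    def validate(self) -> None:
        """Check the spec invariants on [V_TABLE_MIN, V_TABLE_MAX]."""
        v = np.linspace(V_TABLE_MIN, V_TABLE_MAX, 721)
        for ch in self.channels:
            for g in ch.gates:
                if g.calcium:
                    continue
                xi = g.x_inf(v)
                if not (np.all(xi >= 0.0) and np.all(xi <= 1.0)):
                    raise ValueError(f"{ch.name}.{g.var}: x_inf out of [0, 1]")
                if not np.all(g.tau_x(v) > 0.0):
                    raise ValueError(f"{ch.name}.{g.var}: tau not positive")

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "calcium": vars(self.calcium).copy(),
            "channels": [
                {
                    "name": c.name,
                    "gbar_key": c.gbar_key,
                    "erev": c.erev,
                    "carries_calcium": c.carries_calcium,
                    "gates": [
                        {
                            "var": g.var,
                            "power": g.power,
                            "inf": dict(g.inf),
                            "tau": dict(g.tau),
                            "calcium": g.calcium,
                            "ec50": g.ec50,
                            "hill": g.hill,
                        }
                        for g in c.gates
                    ],
                }
                for c in self.channels
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelSet":
        try:
            channels = tuple(
                ChannelSpec(
                    name=c["name"],
                    gbar_key=c["gbar_key"],
                    erev=float(c["erev"]),
                    carries_calcium=bool(c.get("carries_calcium", False)),
                    gates=tuple(
                        GateSpec(
                            var=g["var"],
                            power=int(g["power"]),
                            inf=dict(g.get("inf", {})),
                            tau=dict(g.get("tau", {})),
                            calcium=bool(g.get("calcium", False)),
                            ec50=float(g.get("ec50", 4.3e-4)),
                            hill=float(g.get("hill", 4.8)),
                        )
                        for g in c["gates"]
                    ),
                )
                for c in d["channels"]
            )
        except KeyError as e:  # pragma: no cover - message path
            raise ValueError(f"channel definition missing field {e}") from None
        return cls(channels=channels, calcium=CalciumSpec(**d.get("calcium", {})))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path) -> "ChannelSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


E_NA = 50.0
E_K = -85.0
E_CA = 120.0
E_H = -45.0


def default_channelset() -> ChannelSet:
    """The shipped eight-channel somatic complement."""
    bell = lambda base, amp, vmax, sigma: {
        "kind": "bell", "base": base, "amp": amp, "vmax": vmax, "sigma": sigma,
    }
    sig = lambda base, amp, vhalf, slope: {
        "kind": "sigmoid", "base": base, "amp": amp, "vhalf": vhalf, "slope": slope,
    }
    const = lambda value: {"kind": "constant", "value": value}
    boltz = lambda vhalf, slope: {"vhalf": vhalf, "slope": slope}

    channels = (
        ChannelSpec(
            "Nat", "gbar_nat", E_NA,
            gates=(
                GateSpec("m", 3, boltz(-43.0, 6.0), bell(0.05, 0.4, -43.0, 30.0)),
                GateSpec("h", 1, boltz(-60.0, -7.0), bell(0.5, 7.0, -55.0, 20.0)),
            ),
        ),
        ChannelSpec(
            "Kd", "gbar_kd", E_K,
            gates=(GateSpec("n", 4, boltz(-30.0, 9.0), bell(0.5, 4.0, -45.0, 30.0)),),
        ),
        ChannelSpec(
            "Kp", "gbar_kp", E_K,
            gates=(
                GateSpec("m", 2, boltz(-40.0, 11.0), bell(1.0, 10.0, -50.0, 25.0)),
                GateSpec("h", 1, boltz(-65.0, -11.0), const(500.0)),
            ),
        ),
        ChannelSpec(
            "Kv3.1", "gbar_kv31", E_K,
            gates=(GateSpec("m", 1, boltz(18.7, 9.7), sig(0.05, 4.0, -46.6, 44.1)),),
        ),
        ChannelSpec(
            "Ca", "gbar_ca", E_CA,
            gates=(
                GateSpec("m", 2, boltz(-20.0, 6.0), bell(0.5, 1.0, -20.0, 20.0)),
                GateSpec("h", 1, boltz(-45.0, -12.0), const(80.0)),
            ),
            carries_calcium=True,
        ),
        ChannelSpec(
            "SK", "gbar_sk", E_K,
            gates=(GateSpec("z", 1, tau=const(1.0), calcium=True),),
        ),
        ChannelSpec(
            "Ih", "gbar_ih", E_H,
            gates=(GateSpec("m", 1, boltz(-90.0, -7.0), bell(10.0, 60.0, -80.0, 25.0)),),
        ),
        ChannelSpec(
            "Im", "gbar_im", E_K,
            gates=(GateSpec("m", 1, boltz(-35.0, 9.0), const(60.0)),),
        ),
    )
    return ChannelSet(channels=channels)
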