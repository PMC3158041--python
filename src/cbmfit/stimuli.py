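"""Somatic current-injection protocols.

Four waveform families are supported: depolarizing steps, rising ramps,
Ornstein–Uhlenbeck (OU) colored noise emulating summed synaptic drive, and
subthreshold frequency-sweep ("chirp") sinusoids.  Every protocol carries a
dimensionless scale factor k that multiplies its amplitude parameters — the
device used experimentally to bring cells of different excitability into a
moderate 2–20 Hz firing regime.

The default battery comprises six 2 s steps spanning 100–225×k pA, five 2 s
rising ramps spanning 125–250×k pA, and two 20 s OU processes with a 2 ms
correlation time: type 1 with mean 50×k pA and SD 100×k pA, and type 2
mirroring it (mean 100×k pA, SD 50×k pA).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "StimulusProtocol",
    "make_step",
    "make_ramp",
    "make_ou_noise",
    "make_chirp",
    "default_battery",
]


@dataclass(frozen=True)
class StimulusProtocol:
    """A current waveform with metadata.

    ``duration`` in s, ``dt`` in ms, amplitudes in pA.  ``params`` holds the
    kind-specific parameters; the realized waveform is produced lazily by
    :meth:`current_pA` and is bit-reproducible for equal seeds.
    """

    kind: str  # step | ramp | ou_noise | chirp
    k: float
    duration: float  # s
    dt: float  # ms
    params: dict = field(default_factory=dict)
    name: Optional[str] = None

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.kind not in ("step", "ramp", "ou_noise", "chirp"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * 1e3 / self.dt)) + 1

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def current_pA(self) -> np.ndarray:
        """Realize the waveform (pA), one sample per dt including t=0."""
        t = self.times_ms * 1e-3  # s
        p = self.params
        if self.kind == "step":
            amp = self.k * p["amplitude_pA"]
            onset, dur = p["onset_s"], p["step_duration_s"]
            i = np.where((t >= onset) & (t < onset + dur), amp, 0.0)
        elif self.kind == "ramp":
            peak = self.k * p["peak_pA"]
            rise = p["rise_s"]
            onset = p.get("onset_s", 0.0)
            tt = t - onset
            i = np.where((tt >= 0) & (tt <= rise), peak * np.clip(tt / rise, 0.0, 1.0), 0.0)
        elif self.kind == "ou_noise":
            i = _ou_path(
                mean=self.k * p["mean_pA"],
                sd=self.k * p["sd_pA"],
                tau_ms=p["tau_ms"],
                n=self.n_samples,
                dt_ms=self.dt,
                seed=p["seed"],
            )
        else:  # chirp
            amp = self.k * p["amplitude_pA"]
            f0, f1 = p["f_start_Hz"], p["f_end_Hz"]
            T = self.duration
            # linear sweep: phase(t) = 2*pi*(f0*t + (f1-f0)*t^2/(2T))
            phase = 2.0 * np.pi * (f0 * t + (f1 - f0) * t**2 / (2.0 * T))
            i = amp * np.sin(phase)
        return i

    def with_k(self, k: float) -> "StimulusProtocol":
        return replace(self, k=k)

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "k": self.k, "duration": self.duration,
            "dt": self.dt, "params": dict(self.params), "name": self.name,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(kind=d["kind"], k=d["k"], duration=d["duration"],
                   dt=d["dt"], params=dict(d.get("params", {})), name=d.get("name"))


def _ou_path(mean, sd, tau_ms, n, dt_ms, seed) -> np.ndarray:
    """Exact discretization of a stationary OU process.

    x_{t+dt} = mu + (x_t - mu) e^{-dt/tau} + sd*sqrt(1 - e^{-2dt/tau}) * xi,
    with x_0 drawn from the stationary law N(mu, sd^2); hence the sampled
    path is exactly stationary with mean ``mean`` and SD ``sd`` at every
    sample, for any dt.
    """
    rng = np.random.default_rng(seed)
    a = np.exp(-dt_ms / tau_ms)
    b = sd * np.sqrt(1.0 - a * a)
    noise = rng.standard_normal(n)
    # x_j - mu = sum_{i<=j} a^{j-i} c_i  with c_0 drawn from the stationary
    # law; a first-order IIR filter computes the recursion exactly.
    c = b * noise
    c[0] = sd * noise[0]
    return mean + lfilter([1.0], [1.0, -a], c)


def make_step(amplitude_pA: float, onset_s: float = 0.25, duration_s: float = 2.0,
              k: float = 1.0, *, tail_s: float = 0.25, dt_ms: float = 0.025,
              name: str | None = None) -> StimulusProtocol:
    """Depolarizing step: k·amplitude inside [onset, onset+duration), else 0."""
    if duration_s <= 0:
        raise ValueError("step duration must be positive")
    if onset_s < 0 or tail_s < 0:
        raise ValueError("onset and tail must be non-negative")
    return StimulusProtocol(
        kind="step", k=k, duration=onset_s + duration_s + tail_s, dt=dt_ms,
        params={"amplitude_pA": amplitude_pA, "onset_s": onset_s,
                "step_duration_s": duration_s},
        name=name or f"step_{amplitude_pA:g}pA",
    )


def make_ramp(peak_pA: float, rise_s: float = 2.0, k: float = 1.0, *,
              onset_s: float = 0.25, dt_ms: float = 0.025,
              name: str | None = None) -> StimulusProtocol:
    """Rising ramp from 0 to k·peak over ``rise_s`` (rising phase only)."""
    if rise_s <= 0:
        raise ValueError("rise time must be positive")
    if peak_pA < 0:
        raise ValueError("peak must be non-negative")
    return StimulusProtocol(
        kind="ramp", k=k, duration=onset_s + rise_s, dt=dt_ms,
        params={"peak_pA": peak_pA, "rise_s": rise_s, "onset_s": onset_s},
        name=name or f"ramp_{peak_pA:g}pA",
    )


def make_ou_noise(mean_pA: float, sd_pA: float, tau_ms: float = 2.0,
                  duration_s: float = 20.0, dt_ms: float = 0.025,
                  seed: int = 0, k: float = 1.0,
                  name: str | None = None) -> StimulusProtocol:
    """Ornstein–Uhlenbeck colored-noise current (exact discretization)."""
    if tau_ms <= 0:
        raise ValueError("correlation time must be positive")
    if sd_pA < 0:
        raise ValueError("sd must be non-negative")
    return StimulusProtocol(
        kind="ou_noise", k=k, duration=duration_s, dt=dt_ms,
        params={"mean_pA": mean_pA, "sd_pA": sd_pA, "tau_ms": tau_ms,
                "seed": int(seed)},
        name=name or f"ou_{mean_pA:g}_{sd_pA:g}",
    )


def make_chirp(amplitude_pA: float, f_start_Hz: float = 1.0,
               f_end_Hz: float = 20.0, duration_s: float = 10.0,
               k: float = 1.0, dt_ms: float = 0.025,
               name: str | None = None) -> StimulusProtocol:
    """Phase-continuous sinusoid with linearly swept instantaneous frequency."""
    if f_start_Hz <= 0 or f_end_Hz <= 0:
        raise ValueError("chirp frequencies must be positive")
    return StimulusProtocol(
        kind="chirp", k=k, duration=duration_s, dt=dt_ms,
        params={"amplitude_pA": amplitude_pA, "f_start_Hz": f_start_Hz,
                "f_end_Hz": f_end_Hz},
        name=name or "chirp",
    )


def default_battery(k: float = 1.0, dt_ms: float = 0.025,
                    noise_seed: int = 1234,
                    step_duration_s: float = 2.0,
                    noise_duration_s: float = 20.0) -> dict[str, StimulusProtocol]:
    """The experimental protocol library.

    Six steps 100–225×k pA (2 s each), five ramps 125–250×k pA (2 s rising
    phase), and the two 20 s OU noise types (tau = 2 ms): type 1 mean
    50×k pA / SD 100×k pA, type 2 mean 100×k pA / SD 50×k pA.
    """
    lib: dict[str, StimulusProtocol] = {}
    for i, amp in enumerate(np.linspace(100.0, 225.0, 6)):
        lib[f"step{i + 1}"] = make_step(amp, duration_s=step_duration_s, k=k,
                                        dt_ms=dt_ms, name=f"step{i + 1}")
    for i, peak in enumerate(np.linspace(125.0, 250.0, 5)):
        lib[f"ramp{i + 1}"] = make_ramp(peak, rise_s=step_duration_s, k=k,
                                        dt_ms=dt_ms, name=f"ramp{i + 1}")
    lib["noise1"] = make_ou_noise(50.0, 100.0, 2.0, noise_duration_s, dt_ms,
                                  seed=noise_seed, k=k, name="noise1")
    lib["noise2"] = make_ou_noise(100.0, 50.0, 2.0, noise_duration_s, dt_ms,
                                  seed=noise_seed + 1, k=k, name="noise2")
    return lib
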