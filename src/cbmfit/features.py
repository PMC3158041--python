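"""Spike detection and electrophysiology feature extraction.

Step responses are summarized by six features: spike count during the
pulse, latency to the first spike, accommodation index, mean AP half-width,
mean AP peak height, and mean after-hyperpolarization (AHP) depth.  Ramp
responses additionally carry the slopes of linear fits to AP height and AHP
depth against spike index, capturing the progressive amplitude decline as
sodium channels inactivate during the slow depolarization.

Features that need spikes the response does not contain are flagged
undefined (NaN) rather than silently zeroed; downstream scoring converts
undefined model features into a fixed penalty.

Targets for fitting are per-feature means and standard deviations over
repeated presentations of the same stimulus (:func:`summarize_repetitions`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrain",
    "FeatureVector",
    "FeatureStatistics",
    "detect_spikes",
    "extract_step_features",
    "extract_ramp_features",
    "summarize_repetitions",
    "accommodation_index",
    "STEP_FEATURES",
    "RAMP_FEATURES",
]

STEP_FEATURES = (
    "n_ap",
    "latency_first_ap",
    "accommodation_index",
    "ap_halfwidth",
    "ap_height_mean",
    "ahp_depth_mean",
)
RAMP_FEATURES = STEP_FEATURES + ("ap_height_slope", "ahp_depth_slope")

#: absolute SD floors per feature, in the feature's own units
SD_FLOORS = {
    "n_ap": 0.5,
    "latency_first_ap": 1.0,  # ms
    "accommodation_index": 0.01,
    "ap_halfwidth": 0.05,  # ms
    "ap_height_mean": 0.5,  # mV
    "ahp_depth_mean": 0.5,  # mV
    "ap_height_slope": 0.1,  # mV / spike
    "ahp_depth_slope": 0.1,
}
#: relative SD floor as a fraction of |mean|
SD_FLOOR_REL = 0.005


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times in ms (threshold crossings), strictly increasing."""

    times: np.ndarray
    threshold: float = -20.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size

    def restrict(self, t0: float, t1: float) -> "SpikeTrain":
        m = (self.times >= t0) & (self.times < t1)
        return SpikeTrain(self.times[m], self.threshold)


def detect_spikes(trace, threshold: float = -20.0,
                  refractory_ms: float = 1.0) -> SpikeTrain:
    """Upward threshold crossings with linear sub-sample interpolation.

    Crossings closer than ``refractory_ms`` to the previous accepted spike
    are discarded.  An empty train is a valid result.
    """
    v = trace.voltage
    dt = trace.dt
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    if idx.size == 0:
        return SpikeTrain(np.empty(0), threshold)
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    times = (idx + frac) * dt
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= refractory_ms:
            kept.append(t)
    return SpikeTrain(np.asarray(kept), threshold)


def accommodation_index(isis: np.ndarray, n_skip: int | None = None) -> float:
    """Normalized ISI accommodation.

    A = (1/(N-k-1)) * sum_{i=k+1}^{N-1} (ISI_i - ISI_{i-1})/(ISI_i + ISI_{i-1})
    over the N-1 inter-spike intervals of an N-spike train, skipping the
    first k = min(4, floor(N/5)) intervals to discount the initial burst.
    NaN when fewer than two usable intervals remain.
    """
    isis = np.asarray(isis, dtype=float)
    n_isi = isis.size
    n_spikes = n_isi + 1
    k = min(4, n_spikes // 5) if n_skip is None else n_skip
    usable = isis[k:]
    if usable.size < 2:
        return math.nan
    d = np.diff(usable) / (usable[1:] + usable[:-1])
    return float(np.sum(d) / (n_spikes - k - 1))


def _parabolic_extremum(seg: np.ndarray, i: int) -> float:
    """Sub-sample extremum value via a quadratic through 3 points.

    APs are far narrower than typical sampling steps resolve exactly;
    interpolating the vertex removes the peak-quantization error.
    """
    if i <= 0 or i >= seg.size - 1:
        return float(seg[i])
    a, b, c = seg[i - 1], seg[i], seg[i + 1]
    denom = a - 2.0 * b + c
    if denom == 0:
        return float(b)
    return float(b - 0.125 * (a - c) ** 2 / denom)


def _ap_shape(v: np.ndarray, dt: float, spikes: SpikeTrain, t0: float, t1: float):
    """Per-spike peak height, AHP depth and half-width within [t0, t1).

    Peak and AHP values are parabolic-interpolated around the extremal
    sample.  The AP base is the voltage at the detection-threshold
    crossing; the half-width is measured at base + (peak - base)/2 with
    linear interpolation on both flanks.  AHP depth is the minimum voltage
    between consecutive spikes (defined for trains of >= 2 spikes).
    """
    st = spikes.restrict(t0, t1)
    n = len(st)
    heights = np.full(n, np.nan)
    widths = np.full(n, np.nan)
    ahps = np.full(max(n - 1, 0), np.nan)
    edges = np.concatenate([st.times, [t1]])
    for j in range(n):
        i0 = int(st.times[j] / dt)
        i1 = min(int(edges[j + 1] / dt) + 1, v.size)
        seg = v[i0:i1]
        if seg.size == 0:
            continue
        pk = int(np.argmax(seg))
        heights[j] = _parabolic_extremum(seg, pk)
        if j < n - 1 and seg[pk:].size:
            tr_i = pk + int(np.argmin(seg[pk:]))
            ahps[j] = _parabolic_extremum(seg, tr_i)
        base = spikes.threshold
        half = base + 0.5 * (heights[j] - base)
        # rising flank
        r = np.nonzero(seg[: pk + 1] >= half)[0]
        f = np.nonzero(seg[pk:] <= half)[0]
        if r.size and f.size and r[0] > 0:
            a = r[0]
            tr = a - 1 + (half - seg[a - 1]) / (seg[a] - seg[a - 1])
            b = pk + f[0]
            tf = b - 1 + (half - seg[b - 1]) / (seg[b] - seg[b - 1]) if b > 0 else b
            widths[j] = (tf - tr) * dt
    return heights, ahps, widths


@dataclass(frozen=True)
class FeatureVector:
    """Named feature values; undefined entries are NaN, never silent zeros."""

    values: dict[str, float]
    kind: str  # "step" | "ramp"

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def defined(self, name: str) -> bool:
        return not math.isnan(self.values[name])

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.values)


def _window(stimulus) -> tuple[float, float]:
    p = stimulus.params
    if stimulus.kind == "step":
        t0 = p["onset_s"] * 1e3
        return t0, t0 + p["step_duration_s"] * 1e3
    if stimulus.kind == "ramp":
        t0 = p.get("onset_s", 0.0) * 1e3
        return t0, t0 + p["rise_s"] * 1e3
    return 0.0, stimulus.duration * 1e3


def _base_features(trace, spikes: SpikeTrain, stimulus) -> dict[str, float]:
    t0, t1 = _window(stimulus)
    if t1 > trace.duration + trace.dt:
        raise ValueError(
            f"trace ({trace.duration:g} ms) shorter than stimulus window "
            f"[{t0:g}, {t1:g}) ms"
        )
    st = spikes.restrict(t0, t1)
    n = len(st)
    out = {name: math.nan for name in STEP_FEATURES}
    out["n_ap"] = float(n)
    if n >= 1:
        out["latency_first_ap"] = float(st.times[0] - t0)
    if n >= 2:
        out["accommodation_index"] = accommodation_index(np.diff(st.times))
    heights, ahps, widths = _ap_shape(trace.voltage, trace.dt, spikes, t0, t1)
    if n >= 1 and np.any(np.isfinite(heights)):
        out["ap_height_mean"] = float(np.nanmean(heights))
    if n >= 1 and np.any(np.isfinite(widths)):
        out["ap_halfwidth"] = float(np.nanmean(widths))
    if n >= 2 and np.any(np.isfinite(ahps)):
        out["ahp_depth_mean"] = float(np.nanmean(ahps))
    return out


def extract_step_features(trace, spikes: SpikeTrain, stimulus) -> FeatureVector:
    """The six step-response features (NaN where undefined)."""
    if stimulus.kind != "step":
        raise ValueError(f"expected a step stimulus, got {stimulus.kind!r}")
    return FeatureVector(_base_features(trace, spikes, stimulus), kind="step")


def extract_ramp_features(trace, spikes: SpikeTrain, stimulus) -> FeatureVector:
    """Step features plus AP-height and AHP-depth slopes versus spike index."""
    if stimulus.kind != "ramp":
        raise ValueError(f"expected a ramp stimulus, got {stimulus.kind!r}")
    vals = _base_features(trace, spikes, stimulus)
    t0, t1 = _window(stimulus)
    heights, ahps, _ = _ap_shape(trace.voltage, trace.dt, spikes, t0, t1)
    vals["ap_height_slope"] = _index_slope(heights)
    vals["ahp_depth_slope"] = _index_slope(ahps)
    return FeatureVector(vals, kind="ramp")


def _index_slope(y: np.ndarray) -> float:
    y = np.asarray(y, dtype=float)
    m = np.isfinite(y)
    if m.sum() < 2:
        return math.nan
    x = np.nonzero(m)[0].astype(float)
    return float(np.polyfit(x, y[m], 1)[0])


@dataclass(frozen=True)
class FeatureStatistics:
    """Per-feature mean and SD over repetitions, with the SD floor applied.

    The floor — max(per-feature absolute floor, 0.5 % of |mean|) — prevents
    division blow-ups when repetitions are (nearly) identical, e.g. for
    noiseless surrogate data.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    n: dict[str, int]
    kind: str = "step"

    def features(self) -> tuple[str, ...]:
        return tuple(self.mean)

    def usable(self, name: str) -> bool:
        return self.n.get(name, 0) >= 2


def sd_floor(name: str, mean: float) -> float:
    return max(SD_FLOORS.get(name, 0.5), SD_FLOOR_REL * abs(mean))


def summarize_repetitions(vectors: list[FeatureVector]) -> FeatureStatistics:
    """Sample mean and SD (n-1 denominator) per feature across repetitions.

    Repetitions where a feature is undefined are excluded for that feature,
    with the usable count recorded; a feature with fewer than two defined
    values keeps its count so callers can flag the SD as unusable.
    """
    if len(vectors) < 2:
        raise ValueError("need at least 2 repetitions")
    kind = vectors[0].kind
    names = vectors[0].names
    mean, sd, cnt = {}, {}, {}
    for name in names:
        vals = np.array([fv[name] for fv in vectors], dtype=float)
        vals = vals[np.isfinite(vals)]
        cnt[name] = int(vals.size)
        if vals.size == 0:
            mean[name], sd[name] = math.nan, math.nan
            continue
        mu = float(np.mean(vals))
        s = float(np.std(vals, ddof=1)) if vals.size >= 2 else 0.0
        mean[name] = mu
        sd[name] = max(s, sd_floor(name, mu))
    return FeatureStatistics(mean=mean, sd=sd, n=cnt, kind=kind)
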