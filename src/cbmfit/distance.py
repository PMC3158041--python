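"""Scoring model responses against experimental targets.

Two scoring regimes are used, matching the two kinds of stimuli:

* step/ramp responses — per-feature errors measured as the distance of the
  model feature value from the experimental mean in units of the
  experimental standard deviation across repetitions, so every objective is
  dimensionless and ">= 2 SD" has the same meaning for every feature;

* noise responses — spike-timing precision via the gamma coincidence
  factor (GCF): the chance-corrected fraction of model spikes falling
  within ±delta of experimental spikes, normalized by the intrinsic
  reliability of the reference repetitions.  0 means no better than a
  rate-matched Poisson train, 1 means as precise as repeated recordings of
  the neuron itself.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .features import FeatureStatistics, SpikeTrain

__all__ = [
    "ObjectiveVector",
    "GCFResult",
    "feature_error",
    "gamma_raw",
    "gcf",
    "count_coincidences",
    "DEFAULT_PENALTY",
    "DEFAULT_DELTA_MS",
]

DEFAULT_PENALTY = 250.0  # SD units assigned to undefined model features
DEFAULT_DELTA_MS = 2.0  # coincidence window


@dataclass(frozen=True)
class ObjectiveVector:
    """Error values, one per (stimulus, feature) pair or per noise stimulus.

    ``kinds`` distinguishes feature-based entries ("feature", SD units)
    from noise entries ("gcf", stored as 1 - GCF so that lower is better
    uniformly).
    """

    values: np.ndarray
    labels: tuple[tuple[str, str], ...]  # (stimulus name, feature name)
    kinds: tuple[str, ...]

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not (len(v) == len(self.labels) == len(self.kinds)):
            raise ValueError("values, labels and kinds must align")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise ValueError("objective entries must be finite and >= 0")

    def __len__(self) -> int:
        return self.values.size


def feature_error(model_value: float, stats: FeatureStatistics, feature: str,
                  penalty: float = DEFAULT_PENALTY) -> float:
    """|model - mean| / SD for one feature; the penalty if undefined.

    The penalty applies when the model value is undefined (NaN — e.g. a
    non-spiking model on a spiking target) or when the target itself has no
    usable statistics for this feature.
    """
    if feature not in stats.mean:
        raise ValueError(f"unknown feature {feature!r}")
    mu, sd = stats.mean[feature], stats.sd[feature]
    if model_value is None or math.isnan(model_value):
        return penalty
    if math.isnan(mu) or math.isnan(sd) or sd <= 0:
        return penalty
    return abs(model_value - mu) / sd


def count_coincidences(model: np.ndarray, data: np.ndarray, delta: float) -> int:
    """Greedy-in-time pairing of spikes within ±delta; no double counting."""
    i = j = n = 0
    while i < model.size and j < data.size:
        d = model[i] - data[j]
        if abs(d) <= delta:
            n += 1
            i += 1
            j += 1
        elif d > delta:
            j += 1
        else:
            i += 1
    return n


def gamma_raw(model: SpikeTrain, reference: SpikeTrain, delta: float = DEFAULT_DELTA_MS,
              duration_ms: float | None = None) -> float:
    """Raw coincidence factor between one model and one reference train.

    Gamma = (N_coinc - <N_coinc>) / ((N_model + N_data)/2) * 1/norm, with
    <N_coinc> = 2 * nu_model * delta * N_data the Poisson chance level at
    the model's rate and norm = 1 - 2 * nu_model * delta.  Identical trains
    give exactly 1; an empty model train gives 0.
    """
    n_model, n_data = len(model), len(reference)
    if n_model == 0 and n_data == 0:
        warnings.warn("gamma of two empty spike trains defined as 0", stacklevel=2)
        return 0.0
    if duration_ms is None:
        tmax = max(
            model.times[-1] if n_model else 0.0,
            reference.times[-1] if n_data else 0.0,
        )
        duration_ms = tmax if tmax > 0 else 1.0
    nu = n_model / duration_ms  # spikes per ms
    norm = 1.0 - 2.0 * nu * delta
    if norm <= 0:
        raise ValueError(
            f"model rate {nu * 1e3:.1f} Hz too high for window {delta} ms "
            "(normalizer <= 0)"
        )
    n_coinc = count_coincidences(model.times, reference.times, delta)
    chance = 2.0 * nu * delta * n_data
    return (n_coinc - chance) / (0.5 * (n_model + n_data)) / norm


@dataclass(frozen=True)
class GCFResult:
    """Reliability-normalized gamma coincidence factor and its ingredients."""

    gamma: float
    mean_model_gamma: float  # mean of gamma(model, rep_i)
    intrinsic_gamma: float  # mean of gamma(rep_i, rep_j), i < j
    delta: float
    n_model: int
    n_data_mean: float


def gcf(model: SpikeTrain, repetitions: list[SpikeTrain],
        delta: float = DEFAULT_DELTA_MS, duration_ms: float | None = None) -> GCFResult:
    """GCF of a model train against a set of experimental repetitions.

    gamma = mean_i Gamma(model, rep_i) / mean_{i<j} Gamma(rep_i, rep_j).
    The denominator is the intrinsic reliability of the reference set; a
    degenerate set (non-positive intrinsic gamma) raises.
    """
    if len(repetitions) < 2:
        raise ValueError("need at least 2 experimental repetitions")
    model_g = np.mean([
        gamma_raw(model, rep, delta, duration_ms) for rep in repetitions
    ])
    intrinsic = np.mean([
        gamma_raw(a, b, delta, duration_ms)
        for a, b in combinations(repetitions, 2)
    ])
    if intrinsic <= 0:
        raise ValueError(
            f"degenerate reference set: intrinsic gamma {intrinsic:g} <= 0"
        )
    return GCFResult(
        gamma=float(model_g / intrinsic),
        mean_model_gamma=float(model_g),
        intrinsic_gamma=float(intrinsic),
        delta=delta,
        n_model=len(model),
        n_data_mean=float(np.mean([len(r) for r in repetitions])),
    )
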