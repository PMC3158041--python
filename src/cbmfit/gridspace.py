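"""Solution-space analysis on parameter grids.

Optimization returns point clouds whose members are correlated within a
run; a regular grid removes that artifact and lets the same points be
scored against every stimulus set.  Each grid point is simulated once per
stimulus and marked *consistent* with a stimulus set when all its feature
errors pass the acceptance criterion.  Comparing consistency masks across
stimulus sets quantifies how stimuli carve out zones in parameter space:
intersections measure cross-stimulus generalization, and the shrinkage of
the consistent zone with added stimuli measures how strongly a stimulus
set constrains the model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .channels import ChannelSet, default_channelset
from .distance import DEFAULT_PENALTY, feature_error
from .features import (
    RAMP_FEATURES,
    STEP_FEATURES,
    FeatureStatistics,
    detect_spikes,
    extract_ramp_features,
    extract_step_features,
)
from .model import ParameterVector, SimulationConfig, simulate
from .morphology import Morphology
from .optimizer import AcceptanceCriterion

__all__ = [
    "ParameterGrid",
    "ConsistencyMask",
    "evaluate_grid",
    "intersection_stats",
    "area_ratio",
    "axis_ranges",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParameterGrid:
    """A regular grid over a subset of the free parameters.

    ``axes`` maps parameter names to 1-D point arrays (>= 2 points, within
    bounds); all other parameters are fixed at ``base``'s values.
    """

    base: ParameterVector
    axes: dict[str, np.ndarray]

    def __post_init__(self):
        axes = {k: np.asarray(v, dtype=float) for k, v in self.axes.items()}
        object.__setattr__(self, "axes", axes)
        for name, pts in axes.items():
            if pts.size < 2:
                raise ValueError(f"axis {name!r} needs >= 2 points")
            lo, hi = self.base.bounds[name]
            if pts.min() < lo or pts.max() > hi:
                raise ValueError(f"axis {name!r} exceeds bounds [{lo:g}, {hi:g}]")

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(v.size for v in self.axes.values())

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.axes)

    def points(self):
        """Yield (index tuple, ParameterVector) over the full grid."""
        names = self.names
        for idx in itertools.product(*(range(s) for s in self.shape)):
            vals = {n: float(self.axes[n][i]) for n, i in zip(names, idx)}
            yield idx, self.base.with_values(**vals)

    @classmethod
    def around(cls, base: ParameterVector, names: tuple[str, ...],
               n_points: int = 9) -> "ParameterGrid":
        """Uniform n-point axes spanning each parameter's full bounds."""
        axes = {
            n: np.linspace(*base.bounds[n], n_points) for n in names
        }
        return cls(base=base, axes=axes)


@dataclass(frozen=True)
class ConsistencyMask:
    """Per-grid-point flag: consistent with one stimulus set."""

    grid: ParameterGrid
    mask: np.ndarray  # bool, shape = grid.shape

    def __post_init__(self):
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape must equal grid shape")

    @property
    def area(self) -> int:
        """Number of consistent cells (uniform cell measure)."""
        return int(self.mask.sum())


def evaluate_grid(
    grid: ParameterGrid,
    stimulus_sets: dict[str, dict],
    targets: dict[str, FeatureStatistics],
    criterion: AcceptanceCriterion | None = None,
    morphology: Morphology | None = None,
    config: SimulationConfig | None = None,
    channelset: ChannelSet | None = None,
    spike_threshold: float = -20.0,
) -> dict[str, ConsistencyMask]:
    """Consistency mask of every grid point for every stimulus set.

    ``stimulus_sets`` maps set names to {stimulus name: protocol}; each
    distinct stimulus is simulated once per grid point and shared across
    sets.  A point is consistent with a set when every feature error of
    every member stimulus passes the criterion; integration failures mark
    the point inconsistent.
    """
    criterion = criterion or AcceptanceCriterion()
    morphology = morphology or Morphology()
    config = config or SimulationConfig()
    chans = channelset or default_channelset()

    all_stims: dict[str, object] = {}
    for stims in stimulus_sets.values():
        all_stims.update(stims)
    missing = [n for n in all_stims if n not in targets]
    if missing:
        raise ValueError(f"no targets for stimuli: {missing}")

    ok_per_stim = {n: np.zeros(grid.shape, dtype=bool) for n in all_stims}
    for idx, pv in grid.points():
        for name, stim in all_stims.items():
            try:
                trace = simulate(pv, morphology, stim, config, chans)
            except Exception as e:  # noqa: BLE001
                log.warning("grid point %s failed on %s: %s", idx, name, e)
                continue
            spikes = detect_spikes(trace, spike_threshold)
            extract = (extract_step_features if stim.kind == "step"
                       else extract_ramp_features)
            fv = extract(trace, spikes, stim)
            feats = STEP_FEATURES if stim.kind == "step" else RAMP_FEATURES
            errs = [feature_error(fv[f], targets[name], f, DEFAULT_PENALTY)
                    for f in feats]
            ok_per_stim[name][idx] = max(errs) <= criterion.max_feature_error
    out = {}
    for set_name, stims in stimulus_sets.items():
        m = np.ones(grid.shape, dtype=bool)
        for n in stims:
            m &= ok_per_stim[n]
        out[set_name] = ConsistencyMask(grid=grid, mask=m)
    return out


def intersection_stats(a: ConsistencyMask, b: ConsistencyMask) -> dict:
    """Zone sizes and conditional overlap fractions of two masks.

    ``frac_a`` = |A∩B|/|A| is the probability that a model consistent
    with stimulus set A is also consistent with B — the generalization
    asymmetry quantity; likewise ``frac_b``.
    """
    if a.mask.shape != b.mask.shape:
        raise ValueError("masks must share a grid shape")
    n_a, n_b = a.area, b.area
    n_ab = int((a.mask & b.mask).sum())
    return {
        "n_a": n_a,
        "n_b": n_b,
        "n_intersection": n_ab,
        "frac_a": n_ab / n_a if n_a else 0.0,
        "frac_b": n_ab / n_b if n_b else 0.0,
    }


def area_ratio(mask_many: ConsistencyMask, mask_one: ConsistencyMask) -> float:
    """|consistent with the larger stimulus set| / |consistent with one|.

    With nested sets the ratio is <= 1: adding stimuli can only shrink the
    consistent zone.  Raises when the denominator zone is empty.
    """
    if mask_many.mask.shape != mask_one.mask.shape:
        raise ValueError("masks must share a grid shape")
    if mask_one.area == 0:
        raise ZeroDivisionError("reference mask has no consistent points")
    return mask_many.area / mask_one.area


def plot_masks(masks: dict[str, ConsistencyMask], path, axes_names=None) -> None:
    """2-D projection plot of consistency zones, written to an image file.

    Zones are drawn lightest-first so intersections appear darker; only
    the first two grid axes are shown.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    first = next(iter(masks.values()))
    names = axes_names or first.grid.names[:2]
    x, y = (first.grid.axes[n] for n in names)
    fig, ax = plt.subplots(figsize=(5, 4))
    for i, (label, m) in enumerate(masks.items()):
        proj = m.mask
        while proj.ndim > 2:
            proj = proj.any(axis=-1)
        ax.contourf(x, y, proj.T.astype(float), levels=[0.5, 1.5],
                    colors=[plt.cm.Blues(0.3 + 0.5 * i / max(len(masks) - 1, 1))],
                    alpha=0.6)
        ax.plot([], [], "s", color=plt.cm.Blues(0.3 + 0.5 * i / max(len(masks) - 1, 1)),
                label=label)
    ax.set_xlabel(names[0])
    ax.set_ylabel(names[1])
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def axis_ranges(mask: ConsistencyMask) -> dict[str, tuple[float, float]]:
    """Per-axis [min, max] of the consistent region's projections.

    Empty masks yield (nan, nan) ranges.
    """
    out = {}
    names = mask.grid.names
    if not mask.mask.any():
        return {n: (float("nan"), float("nan")) for n in names}
    idx = np.nonzero(mask.mask)
    for d, n in enumerate(names):
        pts = mask.grid.axes[n][idx[d]]
        out[n] = (float(pts.min()), float(pts.max()))
    return out
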