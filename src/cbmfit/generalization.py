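"""Train/generalize harness.

A model is constrained on a *training set* of stimuli (via their feature
statistics, or spike trains for noise stimuli) and judged on *test sets* of
stimuli it never saw — the operational definition of model quality used
throughout this framework.  Training and test sets are disjoint by
construction; any overlap raises before computation starts.

The canonical design compares five training sets (four 2 s steps; four 2 s
ramps; two steps + two ramps; 8 s of noise type 1; 8 s of noise type 2),
each totalling 8 s of stimulus, against four test conditions (held-out
steps, held-out ramps, noise type 1, noise type 2), yielding a 5 x 4
matrix of generalization scores: mean ± SD feature error in experimental-SD
units for step/ramp tests, mean ± SD gamma coincidence factor for noise
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .channels import ChannelSet, default_channelset
from .distance import DEFAULT_DELTA_MS, DEFAULT_PENALTY, feature_error, gcf
from .features import (
    RAMP_FEATURES,
    STEP_FEATURES,
    FeatureStatistics,
    SpikeTrain,
    detect_spikes,
    extract_ramp_features,
    extract_step_features,
)
from .model import ParameterVector, SimulationConfig, simulate
from .morphology import Morphology
from .optimizer import AcceptanceCriterion, EvolutionResult, GAConfig, evolve, select_acceptable
from .stimuli import StimulusProtocol

__all__ = [
    "TrainTestPlan",
    "GeneralizationReport",
    "ObjectiveEvaluator",
    "FitResult",
    "build_training_sets",
    "train",
    "evaluate",
    "generalization_vs_training_size",
]


@dataclass(frozen=True)
class TrainTestPlan:
    """Named training stimuli and test sets; disjoint by construction."""

    name: str
    train: tuple[str, ...]
    test_sets: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.train:
            raise ValueError("plan has no training stimuli")
        for tname, stims in self.test_sets.items():
            overlap = set(self.train) & set(stims)
            if overlap:
                raise ValueError(
                    f"test set {tname!r} overlaps training set: {sorted(overlap)}; "
                    "stimuli used during parameter constraining are excluded "
                    "from the generalization test"
                )


def build_training_sets(library: dict[str, StimulusProtocol]) -> dict[str, TrainTestPlan]:
    """The five canonical plans from a protocol library.

    Requires >= 5 step and >= 5 ramp intensities plus both noise types in
    ``library`` (named ``step1..``, ``ramp1..``, ``noise1``, ``noise2``).
    Training subsets take the lowest suprathreshold intensities; held-out
    intensities form the within-kind test sets.
    """
    steps = sorted(k for k in library if k.startswith("step"))
    ramps = sorted(k for k in library if k.startswith("ramp"))
    missing = []
    if len(steps) < 5:
        missing.append(f">=5 steps (found {len(steps)})")
    if len(ramps) < 5:
        missing.append(f">=5 ramps (found {len(ramps)})")
    for nz in ("noise1", "noise2"):
        if nz not in library:
            missing.append(nz)
    if missing:
        raise ValueError("protocol library incomplete: " + ", ".join(missing))

    def plan(name, train):
        test = {
            "steps": tuple(s for s in steps if s not in train),
            "ramps": tuple(r for r in ramps if r not in train),
            "noise1": ("noise1",) if "noise1" not in train else (),
            "noise2": ("noise2",) if "noise2" not in train else (),
        }
        test = {k: v for k, v in test.items() if v}
        return TrainTestPlan(name=name, train=tuple(train), test_sets=test)

    return {
        "step": plan("step", steps[:4]),
        "ramp": plan("ramp", ramps[:4]),
        "step+ramp": plan("step+ramp", steps[:2] + ramps[:2]),
        "noise1": plan("noise1", ["noise1"]),
        "noise2": plan("noise2", ["noise2"]),
    }


class ObjectiveEvaluator:
    """Maps free-parameter values to the plan's objective vector.

    Feature targets contribute one SD-unit error per (stimulus, feature);
    noise targets contribute 1 - GCF (optimization minimizes, so
    maximizing GCF means minimizing this entry).  Non-finite simulation or
    scoring failures surface as exceptions that the optimizer converts to
    penalty objectives.

    ``aggregate="feature"`` collapses the layout to one objective per
    feature name, averaging the error across stimuli.  Selection pressure
    in Pareto ranking degrades as the objective count grows, so the
    aggregated layout is preferable for small populations with several
    training stimuli; the acceptance criterion then applies to the
    per-feature averages.
    """

    def __init__(
        self,
        stimuli: dict[str, StimulusProtocol],
        targets: dict[str, FeatureStatistics | list[SpikeTrain]],
        base_params: ParameterVector,
        free: tuple[str, ...],
        morphology: Morphology,
        config: SimulationConfig,
        channelset: ChannelSet | None = None,
        penalty: float = DEFAULT_PENALTY,
        delta: float = DEFAULT_DELTA_MS,
        spike_threshold: float = -20.0,
        aggregate: str = "none",
    ):
        if aggregate not in ("none", "feature"):
            raise ValueError(f"unknown aggregation mode {aggregate!r}")
        missing = [n for n in stimuli if n not in targets]
        if missing:
            raise ValueError(f"no targets for training stimuli: {missing}")
        self.stimuli = dict(stimuli)
        self.targets = targets
        self.base = base_params
        self.free = tuple(free)
        self.morph = morphology
        self.config = config
        self.chans = channelset or default_channelset()
        self.penalty = penalty
        self.delta = delta
        self.threshold = spike_threshold

        self.aggregate = aggregate
        labels, kinds = [], []
        for name, stim in self.stimuli.items():
            tgt = targets[name]
            if isinstance(tgt, FeatureStatistics):
                feats = STEP_FEATURES if stim.kind == "step" else RAMP_FEATURES
                for f in feats:
                    labels.append((name, f))
                    kinds.append("feature")
            else:
                labels.append((name, "gcf"))
                kinds.append("gcf")
        if aggregate == "feature":
            grouped = []
            for stim_name, feat in labels:
                key = ("*", feat)
                if key not in grouped:
                    grouped.append(key)
            self._groups = [
                [i for i, (_, f) in enumerate(labels) if f == feat]
                for (_, feat) in grouped
            ]
            self.labels = tuple(grouped)
            self.kinds = tuple(
                "gcf" if feat == "gcf" else "feature" for _, feat in grouped)
        else:
            self._groups = None
            self.labels = tuple(labels)
            self.kinds = tuple(kinds)

    @property
    def bounds(self) -> np.ndarray:
        return np.array([self.base.bounds[n] for n in self.free])

    def params_from_free(self, x: np.ndarray) -> ParameterVector:
        return self.base.with_values(**dict(zip(self.free, np.asarray(x, float))))

    def __call__(self, x: np.ndarray) -> np.ndarray:
        pv = self.params_from_free(x)
        out = []
        for name, stim in self.stimuli.items():
            tgt = self.targets[name]
            trace = simulate(pv, self.morph, stim, self.config, self.chans)
            spikes = detect_spikes(trace, self.threshold)
            if isinstance(tgt, FeatureStatistics):
                extract = (extract_step_features if stim.kind == "step"
                           else extract_ramp_features)
                fv = extract(trace, spikes, stim)
                for f in (STEP_FEATURES if stim.kind == "step" else RAMP_FEATURES):
                    out.append(feature_error(fv[f], tgt, f, self.penalty))
            else:
                if len(spikes) == 0:
                    out.append(1.0)
                else:
                    g = gcf(spikes, tgt, self.delta,
                            duration_ms=stim.duration * 1e3).gamma
                    out.append(max(0.0, 1.0 - g))
        raw = np.asarray(out)
        if self._groups is not None:
            return np.array([raw[g].mean() for g in self._groups])
        return raw


@dataclass
class FitResult:
    """Evolved pool plus acceptance bookkeeping for one training plan."""

    plan: TrainTestPlan
    evolution: EvolutionResult
    evaluator: ObjectiveEvaluator
    accepted: np.ndarray  # row indices into the pooled population
    criterion: AcceptanceCriterion

    @property
    def accepted_params(self) -> np.ndarray:
        return self.evolution.params[self.accepted]

    def nearest_miss(self) -> tuple[np.ndarray, float]:
        """Best pooled model by worst-objective, for empty-acceptance diagnostics."""
        worst = self.evolution.objectives.max(axis=1)
        i = int(np.argmin(worst))
        return self.evolution.params[i], float(worst[i])


def train(
    plan: TrainTestPlan,
    stimuli: dict[str, StimulusProtocol],
    targets: dict,
    base_params: ParameterVector,
    free: tuple[str, ...],
    morphology: Morphology,
    config: SimulationConfig,
    ga: GAConfig,
    criterion: AcceptanceCriterion | None = None,
    channelset: ChannelSet | None = None,
    aggregate: str = "none",
    constrain_to_criterion: bool = True,
) -> FitResult:
    """Fit the plan's training objectives and select acceptable models.

    By default the search uses constraint-domination anchored on the
    acceptance criterion, so the evolved populations concentrate in the
    model-selection region rather than spreading along the Pareto
    extremes.  Returns a :class:`FitResult`; an empty accepted set is
    reported (with nearest-miss diagnostics available), not raised.
    """
    criterion = criterion or AcceptanceCriterion()
    train_stimuli = {n: stimuli[n] for n in plan.train}
    ev = ObjectiveEvaluator(
        train_stimuli, targets, base_params, free, morphology, config, channelset,
        aggregate=aggregate,
    )
    thresholds = None
    if constrain_to_criterion:
        thresholds = np.array([
            (1.0 - criterion.min_gcf) if k == "gcf" else criterion.max_feature_error
            for k in ev.kinds])
    result = evolve(ev, ev.bounds, ga, feasibility_thresholds=thresholds)
    accepted = select_acceptable(result, criterion, ev.kinds)
    return FitResult(plan=plan, evolution=result, evaluator=ev,
                     accepted=accepted, criterion=criterion)


@dataclass
class GeneralizationReport:
    """mean ± SD scores per (train plan, test set), with model counts.

    Feature test sets report pooled model x feature errors (SD units,
    lower better); noise test sets report GCF per model (0–1, higher
    better).
    """

    rows: dict[tuple[str, str], dict]

    def to_frame(self):
        import pandas as pd

        recs = [
            {"train": k[0], "test": k[1], **v} for k, v in self.rows.items()
        ]
        return pd.DataFrame(recs)


def evaluate(
    fit: FitResult,
    stimuli: dict[str, StimulusProtocol],
    targets: dict,
    test_sets: dict[str, tuple[str, ...]] | None = None,
    max_models: int | None = None,
) -> GeneralizationReport:
    """Score accepted models on held-out test sets.

    Feature tests pool |model - mean|/SD over models x stimuli x features;
    noise tests collect one GCF per model.  Simulation failures score the
    penalty and are counted.  ``max_models`` caps the evaluated subset
    (first rows) for desk-scale runs.
    """
    if fit.accepted.size == 0:
        raise ValueError("no accepted models to evaluate; see nearest_miss()")
    test_sets = test_sets if test_sets is not None else fit.plan.test_sets
    models = fit.accepted_params
    if max_models is not None:
        models = models[:max_models]
    ev = fit.evaluator
    rows = {}
    for tname, stim_names in test_sets.items():
        overlap = set(stim_names) & set(fit.plan.train)
        if overlap:
            raise ValueError(f"test set {tname!r} overlaps training: {overlap}")
        errs, gammas, failures = [], [], 0
        for x in models:
            pv = ev.params_from_free(x) if len(x) == len(ev.free) else None
            assert pv is not None
            for sname in stim_names:
                stim = stimuli[sname]
                tgt = targets[sname]
                try:
                    trace = simulate(pv, ev.morph, stim, ev.config, ev.chans)
                except Exception:  # noqa: BLE001
                    failures += 1
                    if isinstance(tgt, FeatureStatistics):
                        errs.extend([ev.penalty] * len(
                            STEP_FEATURES if stim.kind == "step" else RAMP_FEATURES))
                    else:
                        gammas.append(0.0)
                    continue
                spikes = detect_spikes(trace, ev.threshold)
                if isinstance(tgt, FeatureStatistics):
                    extract = (extract_step_features if stim.kind == "step"
                               else extract_ramp_features)
                    fv = extract(trace, spikes, stim)
                    feats = STEP_FEATURES if stim.kind == "step" else RAMP_FEATURES
                    errs.extend(feature_error(fv[f], tgt, f, ev.penalty)
                                for f in feats)
                else:
                    if len(spikes) == 0:
                        gammas.append(0.0)
                    else:
                        gammas.append(gcf(spikes, tgt, ev.delta,
                                          duration_ms=stim.duration * 1e3).gamma)
        vals = np.asarray(errs if errs else gammas, dtype=float)
        rows[(fit.plan.name, tname)] = {
            "metric": "feature_error" if errs else "gcf",
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
            "n_models": int(models.shape[0]),
            "n_values": int(vals.size),
            "failures": failures,
        }
    return GeneralizationReport(rows=rows)


def generalization_vs_training_size(
    sizes: list[int],
    train_pool: tuple[str, ...],
    test_names: tuple[str, ...],
    stimuli: dict[str, StimulusProtocol],
    targets: dict,
    base_params: ParameterVector,
    free: tuple[str, ...],
    morphology: Morphology,
    config: SimulationConfig,
    ga: GAConfig,
    criterion: AcceptanceCriterion | None = None,
    max_models: int | None = 20,
    aggregate: str = "feature",
) -> dict[int, dict]:
    """Training and generalization error versus number of training stimuli.

    For each n in ``sizes``, trains on the first n stimuli of
    ``train_pool`` and evaluates on ``test_names``; returns per-size
    training error (mean over accepted models' objectives), generalization
    error, and the accepted count.  The device behind learning-curve
    analyses of stimulus utility.
    """
    out = {}
    for n in sizes:
        plan = TrainTestPlan(
            name=f"n={n}", train=tuple(train_pool[:n]),
            test_sets={"test": tuple(t for t in test_names
                                     if t not in train_pool[:n])},
        )
        fit = train(plan, stimuli, targets, base_params, free, morphology,
                    config, ga, criterion, aggregate=aggregate)
        rec = {"n_accepted": int(fit.accepted.size)}
        if fit.accepted.size:
            rec["training_error"] = float(
                fit.evolution.objectives[fit.accepted].mean())
            rep = evaluate(fit, stimuli, targets, max_models=max_models)
            row = rep.rows[(plan.name, "test")]
            rec["generalization_error"] = row["mean"]
            rec["generalization_sd"] = row["sd"]
        else:
            rec["training_error"] = math.nan
            rec["generalization_error"] = math.nan
            rec["generalization_sd"] = math.nan
        out[n] = rec
    return out
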