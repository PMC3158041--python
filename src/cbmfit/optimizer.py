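"""Elitist multi-objective genetic optimization (NSGA-II).

The fitting problem is posed with one objective per (stimulus, feature)
pair, kept unreduced — no weight vector.  NSGA-II maintains a population of
parameter vectors ranked by Pareto non-domination with a parameter-less
crowding-distance diversity mechanism; parents and offspring are pooled
each generation and truncated elitistically by (rank, crowding).  Variation
uses the canonical real-coded operators: simulated binary crossover (SBX)
and bounded polynomial mutation.

The production-scale configuration evaluates 300 parameter sets for 1500
generations and repeats each optimization ten times, pooling the ten final
populations into 3000 candidate models; desk-scale defaults for tests are
much smaller.  Models are then filtered by the acceptance criterion — every
feature error within two experimental SDs (or, for spike-timing objectives,
GCF at or above a floor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAConfig",
    "AcceptanceCriterion",
    "Individual",
    "EvolutionResult",
    "dominates",
    "non_dominated_sort",
    "crowding_distance",
    "evolve",
    "select_acceptable",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAConfig:
    population: int = 300
    generations: int = 1500
    repeats: int = 10
    crossover_rate: float = 0.9
    mutation_rate: float | None = None  # default 1/n_params
    eta_crossover: float = 15.0
    eta_mutation: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.population < 4 or self.population % 2:
            raise ValueError("population must be even and >= 4")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @classmethod
    def desk_scale(cls, seed: int = 0, **kw) -> "GAConfig":
        """Small configuration for tests and examples."""
        kw.setdefault("population", 40)
        kw.setdefault("generations", 100)
        kw.setdefault("repeats", 3)
        return cls(seed=seed, **kw)


@dataclass(frozen=True)
class AcceptanceCriterion:
    """Model selection rule applied to the pooled population.

    ``max_feature_error`` in experimental-SD units (the two-SD rule);
    ``min_gcf`` applies to spike-timing objectives, which are stored as
    1 - GCF in the objective vector.
    """

    max_feature_error: float = 2.0
    min_gcf: float = 0.8

    def __post_init__(self):
        if self.max_feature_error <= 0:
            raise ValueError("threshold must be positive")

    def passes(self, objectives: np.ndarray, kinds) -> bool:
        for val, kind in zip(objectives, kinds):
            if kind == "gcf":
                if 1.0 - val < self.min_gcf:
                    return False
            elif val > self.max_feature_error:
                return False
        return True


@dataclass
class Individual:
    params: np.ndarray
    objectives: np.ndarray
    rank: int = -1
    crowding: float = 0.0


@dataclass
class EvolutionResult:
    """Pooled final populations across repeats, plus convergence logs."""

    params: np.ndarray  # (repeats * population, n_params)
    objectives: np.ndarray  # (repeats * population, n_obj)
    ranks: np.ndarray
    convergence: list[np.ndarray]  # per repeat: (generations+1, 2) best/mean
    config: GAConfig


def dominates(a: np.ndarray, b: np.ndarray) -> bool:
    """Pareto domination: a <= b elementwise and strictly better somewhere."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("objective vectors must have equal length")
    return bool(np.all(a <= b) and np.any(a < b))


def non_dominated_sort(objectives: np.ndarray,
                       violations: np.ndarray | None = None) -> list[np.ndarray]:
    """Partition row indices into non-domination fronts (front 0 first).

    Deb's fast non-dominated sort: front 0 holds all non-dominated rows,
    front k the rows non-dominated once fronts < k are removed.

    With ``violations`` (constraint-domination): any zero-violation row
    dominates every positive-violation row; among positive-violation rows
    the smaller violation dominates; zero-violation rows compare by the
    usual Pareto rule.
    """
    F = np.asarray(objectives, dtype=float)
    n = F.shape[0]
    if n == 0:
        raise ValueError("population must be non-empty")
    # domination matrix via broadcasting: d[i, j] = i dominates j
    le = np.all(F[:, None, :] <= F[None, :, :], axis=2)
    lt = np.any(F[:, None, :] < F[None, :, :], axis=2)
    dom = le & lt
    if violations is not None:
        v = np.asarray(violations, dtype=float)
        feas = v <= 0
        pareto = dom
        dom = np.zeros_like(pareto)
        dom |= feas[:, None] & ~feas[None, :]
        both_inf = ~feas[:, None] & ~feas[None, :]
        dom |= both_inf & (v[:, None] < v[None, :])
        both_feas = feas[:, None] & feas[None, :]
        dom |= both_feas & pareto
    n_dominators = dom.sum(axis=0)
    fronts = []
    remaining = np.ones(n, dtype=bool)
    while remaining.any():
        current = remaining & (n_dominators == 0)
        if not current.any():  # numerical safety; cannot happen with a partial order
            current = remaining.copy()
        fronts.append(np.nonzero(current)[0])
        remaining &= ~current
        n_dominators = n_dominators - dom[current].sum(axis=0)
    return fronts


def crowding_distance(objectives: np.ndarray) -> np.ndarray:
    """Crowding distance within one front; boundary points get +inf.

    Per objective the front is sorted and interior points accumulate the
    normalized gap between their neighbours; fronts of one or two points
    are all-infinite.
    """
    F = np.asarray(objectives, dtype=float)
    n, m = F.shape
    if n == 0:
        raise ValueError("front must be non-empty")
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for j in range(m):
        order = np.argsort(F[:, j], kind="stable")
        fj = F[order, j]
        span = fj[-1] - fj[0]
        d[order[0]] = d[order[-1]] = np.inf
        if span > 0:
            d[order[1:-1]] += (fj[2:] - fj[:-2]) / span
    return d


def _rank_and_crowd(objectives: np.ndarray, violations=None):
    fronts = non_dominated_sort(objectives, violations)
    rank = np.empty(objectives.shape[0], dtype=np.int64)
    crowd = np.empty(objectives.shape[0])
    for k, fr in enumerate(fronts):
        rank[fr] = k
        crowd[fr] = crowding_distance(objectives[fr])
    return rank, crowd, fronts


def _tournament(rank, crowd, rng, n_pick):
    n = rank.size
    a = rng.integers(0, n, n_pick)
    b = rng.integers(0, n, n_pick)
    better_a = (rank[a] < rank[b]) | ((rank[a] == rank[b]) & (crowd[a] > crowd[b]))
    return np.where(better_a, a, b)


def _sbx(parents_a, parents_b, lo, hi, eta, p_cross, rng):
    """Simulated binary crossover, per-variable, bounds-clipped."""
    n, d = parents_a.shape
    c1 = parents_a.copy()
    c2 = parents_b.copy()
    do = rng.random(n) < p_cross
    u = rng.random((n, d))
    beta = np.where(u <= 0.5,
                    (2.0 * u) ** (1.0 / (eta + 1.0)),
                    (1.0 / (2.0 * (1.0 - u))) ** (1.0 / (eta + 1.0)))
    mix = rng.random((n, d)) < 0.5  # exchange half the variables on average
    b1 = 0.5 * ((1 + beta) * parents_a + (1 - beta) * parents_b)
    b2 = 0.5 * ((1 - beta) * parents_a + (1 + beta) * parents_b)
    mask = do[:, None] & mix
    c1 = np.where(mask, b1, c1)
    c2 = np.where(mask, b2, c2)
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _poly_mutate(x, lo, hi, eta, p_mut, rng):
    n, d = x.shape
    y = x.copy()
    span = hi - lo
    do = rng.random((n, d)) < p_mut
    u = rng.random((n, d))
    delta = np.where(
        u < 0.5,
        (2.0 * u) ** (1.0 / (eta + 1.0)) - 1.0,
        1.0 - (2.0 * (1.0 - u)) ** (1.0 / (eta + 1.0)),
    )
    y = np.where(do, y + delta * span, y)
    return np.clip(y, lo, hi)


def _evaluate_population(evaluator, X, penalty_dim, penalty=1e6):
    out = []
    for row in X:
        try:
            out.append(np.asarray(evaluator(row), dtype=float))
        except Exception as e:  # noqa: BLE001 - evaluator failures become penalties
            log.warning("evaluator failed (%s); assigning penalty objectives", e)
            out.append(np.full(penalty_dim, penalty))
    F = np.vstack(out)
    F[~np.isfinite(F)] = penalty
    return F


def evolve(evaluator, bounds: np.ndarray, config: GAConfig,
           feasibility_thresholds: np.ndarray | None = None) -> EvolutionResult:
    """Run the elitist NSGA-II loop ``config.repeats`` times and pool.

    ``evaluator`` maps a parameter row to an objective vector (lower is
    better); ``bounds`` is (n_params, 2).  The pooled output has
    population x repeats rows regardless of the generation count.
    Deterministic for a fixed ``config.seed``.

    ``feasibility_thresholds`` (one per objective) switches ranking to
    constraint-domination with violation sum(max(0, f - threshold)):
    solutions meeting every threshold outrank all others, which keeps the
    population anchored to the model-selection region instead of
    dispersing along degenerate Pareto extremes — important at small
    population sizes when the targets are mutually consistent.
    """
    bounds = np.asarray(bounds, dtype=float)
    lo, hi = bounds[:, 0], bounds[:, 1]
    n_par = bounds.shape[0]
    p_mut = config.mutation_rate if config.mutation_rate is not None else 1.0 / n_par
    pop = config.population

    seeds = np.random.SeedSequence(config.seed).spawn(config.repeats)
    all_params, all_objs, all_ranks, logs = [], [], [], []

    # probe the objective dimension once
    probe = np.asarray(evaluator(0.5 * (lo + hi)), dtype=float)
    n_obj = probe.size
    thr = None
    if feasibility_thresholds is not None:
        thr = np.asarray(feasibility_thresholds, dtype=float)
        if thr.shape != (n_obj,):
            raise ValueError("need one feasibility threshold per objective")

    def _violations(F):
        if thr is None:
            return None
        return np.maximum(F - thr, 0.0).sum(axis=1)

    for rep in range(config.repeats):
        rng = np.random.default_rng(seeds[rep])
        X = lo + rng.random((pop, n_par)) * (hi - lo)
        F = _evaluate_population(evaluator, X, n_obj)
        rank, crowd, _ = _rank_and_crowd(F, _violations(F))
        curve = np.empty((config.generations + 1, 2))
        total = F.sum(axis=1)
        curve[0] = total.min(), total.mean()

        for gen in range(config.generations):
            idx = _tournament(rank, crowd, rng, pop)
            pa, pb = X[idx[0::2]], X[idx[1::2]]
            c1, c2 = _sbx(pa, pb, lo, hi, config.eta_crossover,
                          config.crossover_rate, rng)
            children = np.vstack([c1, c2])
            children = _poly_mutate(children, lo, hi, config.eta_mutation,
                                    p_mut, rng)
            Fc = _evaluate_population(evaluator, children, n_obj)
            Xall = np.vstack([X, children])
            Fall = np.vstack([F, Fc])
            rk, cw, fronts = _rank_and_crowd(Fall, _violations(Fall))
            keep = []
            for fr in fronts:
                if len(keep) + fr.size <= pop:
                    keep.extend(fr.tolist())
                else:
                    need = pop - len(keep)
                    order = np.argsort(-cw[fr], kind="stable")
                    keep.extend(fr[order[:need]].tolist())
                    break
            keep = np.asarray(keep)
            X, F = Xall[keep], Fall[keep]
            rank, crowd, _ = _rank_and_crowd(F, _violations(F))
            total = F.sum(axis=1)
            curve[gen + 1] = total.min(), total.mean()
            if (gen + 1) % 25 == 0:
                log.info("repeat %d gen %d: best %.3g mean %.3g",
                         rep, gen + 1, curve[gen + 1, 0], curve[gen + 1, 1])

        all_params.append(X)
        all_objs.append(F)
        all_ranks.append(rank)
        logs.append(curve)

    return EvolutionResult(
        params=np.vstack(all_params),
        objectives=np.vstack(all_objs),
        ranks=np.concatenate(all_ranks),
        convergence=logs,
        config=config,
    )


def select_acceptable(result: EvolutionResult, criterion: AcceptanceCriterion,
                      kinds=None) -> np.ndarray:
    """Row indices of pooled models passing the acceptance criterion.

    ``kinds`` labels each objective ("feature" or "gcf"); all-"feature" by
    default.  An empty result is returned, never raised.
    """
    n_obj = result.objectives.shape[1]
    kinds = tuple(kinds) if kinds is not None else ("feature",) * n_obj
    ok = [i for i, row in enumerate(result.objectives)
          if criterion.passes(row, kinds)]
    return np.asarray(ok, dtype=np.int64)
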