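"""Elephant-herding optimization and Cartesian-distance feature selection.

The elephant-herding algorithm (EHA) is a population metaheuristic: the
herd is split into clans; each member moves toward its clan's matriarch
(the clan-best position) by a random fraction; the matriarch herself moves
to a scaled clan centroid; and once per generation the worst member of each
clan is replaced by a uniform random position (the departing male).  A
global elitist record keeps the best position ever evaluated.

For feature selection, the 2-D search position is the pair
(score quantile q, redundancy cutoff rho): candidate features are those
whose per-feature Cartesian-distance score reaches the q-quantile, and a
greedy pass drops any candidate correlated above rho with a higher-scoring
kept feature.  The objective rewards between-class centroid separation in
the selected standardized subspace, mildly penalized by subset size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EHAParams",
    "EHAResult",
    "SelectionResult",
    "clan_update",
    "matriarch_update",
    "replace_worst",
    "eha_optimize",
    "cartesian_distance_scores",
    "select_at",
    "select_features",
]


@dataclass(frozen=True)
class EHAParams:
    """Control parameters of the elephant-herding search.

    Defaults mirror the published configuration: 30 members, 5 generations
    (separation events), a 2-D search space and 1500 iterations.  ``beta``
    scales the matriarch's move toward the clan centroid; it is not given
    in the source configuration and defaults to a small drift of 0.1.
    """

    n_members: int = 30
    n_clans: int = 5
    n_generations: int = 5
    search_dim: int = 2
    beta: float = 0.1
    max_iter: int = 1500
    bounds: tuple[float, float] | tuple[np.ndarray, np.ndarray] = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_members % self.n_clans != 0:
            raise ValueError("n_members must be divisible by n_clans")
        if not (0.0 < self.beta <= 1.0):
            raise ValueError("beta must be in (0, 1]")
        lo, hi = self.lower, self.upper
        if not np.all(lo < hi):
            raise ValueError("bounds must satisfy X_min < X_max elementwise")

    @property
    def lower(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.bounds[0], dtype=float), (self.search_dim,)).copy()

    @property
    def upper(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.bounds[1], dtype=float), (self.search_dim,)).copy()


@dataclass
class EHAResult:
    best_position: np.ndarray
    best_value: float
    trace: np.ndarray  # best-so-far value per iteration (monotone non-decreasing)
    n_evaluations: int


def _clip(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return np.minimum(np.maximum(x, lo), hi)


def clan_update(position: np.ndarray, clan_best: np.ndarray,
                rng: np.random.Generator,
                lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Move a member toward the matriarch: X + a*(X_best - X)*r, clamped.

    ``a`` and ``r`` are independent uniform(0,1) draws per dimension.
    """
    a = rng.uniform(size=position.shape)
    r = rng.uniform(size=position.shape)
    return _clip(position + a * (clan_best - position) * r, lower, upper)


def matriarch_update(clan_positions: np.ndarray, beta: float,
                     lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """New matriarch position: beta * clan centroid, clamped to bounds."""
    clan_positions = np.atleast_2d(np.asarray(clan_positions, dtype=float))
    if clan_positions.shape[0] == 0:
        raise ValueError("empty clan")
    return _clip(beta * clan_positions.mean(axis=0), lower, upper)


def replace_worst(lower: np.ndarray, upper: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Departing-male replacement: X_min + (X_max - X_min + 1)*rand, clamped.

    The +1 in the published update can overshoot X_max; the literal formula
    is kept and the sample is clamped back into the bounds.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    raw = lower + (upper - lower + 1.0) * rng.uniform(size=lower.shape)
    return _clip(raw, lower, upper)


def eha_optimize(objective, params: EHAParams | None = None) -> EHAResult:
    """Maximize ``objective`` over the bounded search space with the EHA.

    The loop applies the member update toward the clan best, the matriarch
    update for the clan-best member, and — spaced so that the configured
    number of generations fits into ``max_iter`` — the worst-member
    replacement per clan.  A global elitist best is retained and reported.
    """
    params = params or EHAParams()
    rng = np.random.default_rng(params.seed)
    lo, hi = params.lower, params.upper
    m = params.n_members // params.n_clans
    d = params.search_dim

    positions = rng.uniform(lo, hi, size=(params.n_clans, m, d))
    fitness = np.empty((params.n_clans, m))
    n_eval = 0

    def _eval(x: np.ndarray) -> float:
        nonlocal n_eval
        v = float(objective(x))
        if not np.isfinite(v):
            raise ValueError(f"objective returned non-finite value {v} at {x}")
        n_eval += 1
        return v

    for c in range(params.n_clans):
        for j in range(m):
            fitness[c, j] = _eval(positions[c, j])

    flat = int(np.argmax(fitness))
    best_pos = positions.reshape(-1, d)[flat].copy()
    best_val = float(fitness.ravel()[flat])

    sep_every = max(1, params.max_iter // max(params.n_generations, 1))
    trace = np.empty(params.max_iter)

    for it in range(params.max_iter):
        for c in range(params.n_clans):
            best_j = int(np.argmax(fitness[c]))
            clan_best = positions[c, best_j].copy()
            centroid_src = positions[c].copy()
            for j in range(m):
                if j == best_j:
                    new = matriarch_update(centroid_src, params.beta, lo, hi)
                else:
                    new = clan_update(positions[c, j], clan_best, rng, lo, hi)
                positions[c, j] = new
                fitness[c, j] = _eval(new)
                if fitness[c, j] > best_val:
                    best_val = float(fitness[c, j])
                    best_pos = new.copy()
        if (it + 1) % sep_every == 0:
            for c in range(params.n_clans):
                worst_j = int(np.argmin(fitness[c]))
                positions[c, worst_j] = replace_worst(lo, hi, rng)
                fitness[c, worst_j] = _eval(positions[c, worst_j])
                if fitness[c, worst_j] > best_val:
                    best_val = float(fitness[c, worst_j])
                    best_pos = positions[c, worst_j].copy()
        trace[it] = best_val

    return EHAResult(best_pos, best_val, trace, n_eval)


def cartesian_distance_scores(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-feature class-separation score.

    Each column is z-scored over all samples (population sd); the score is
    the absolute difference of class means of the standardized column, i.e.
    the per-axis Cartesian distance between the class centroids.
    Zero-variance columns score 0.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("need >= 2 samples per class")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - mu[ok]) / sd[ok]
    d = Z[y == classes[1]].mean(axis=0) - Z[y == classes[0]].mean(axis=0)
    d[~ok] = 0.0
    return np.abs(d)


@dataclass
class SelectionResult:
    """Outcome of EHA-driven feature selection."""

    selected_indices: np.ndarray
    cd_scores: np.ndarray
    threshold_quantile: float
    redundancy_cutoff: float
    fitness: float

    def __post_init__(self) -> None:
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        if self.selected_indices.size == 0:
            raise ValueError("selection must be non-empty")


def _greedy_prune(order: np.ndarray, candidate: np.ndarray,
                  abs_corr: np.ndarray, rho: float) -> np.ndarray:
    """Keep candidates in descending-score order, dropping any feature with
    |corr| > rho to an already-kept higher-scoring feature."""
    kept: list[int] = []
    for i in order:
        if not candidate[i]:
            continue
        if kept and np.max(abs_corr[i, kept]) > rho:
            continue
        kept.append(int(i))
    return np.array(kept, dtype=int)


def _prepare_selection(X: np.ndarray, y: np.ndarray):
    scores = cartesian_distance_scores(X, y)
    classes = np.unique(y)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    delta = Z[y == classes[1]].mean(axis=0) - Z[y == classes[0]].mean(axis=0)
    with np.errstate(invalid="ignore"):
        abs_corr = np.abs(np.corrcoef(Z.T))
    abs_corr = np.nan_to_num(abs_corr, nan=0.0)
    order = np.argsort(-scores, kind="stable")
    return scores, delta, abs_corr, order


def select_at(features: np.ndarray, labels: np.ndarray,
              q: float, rho: float) -> np.ndarray:
    """The feature subset the selection rule yields at a fixed (q, rho).

    Candidates are features whose CD score reaches the q-quantile; greedy
    pruning drops candidates with |corr| > rho to a kept higher-scoring
    feature.  Falls back to the single argmax-CD feature when empty.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    scores, _, abs_corr, order = _prepare_selection(X, y)
    candidate = scores >= np.quantile(scores, q)
    kept = _greedy_prune(order, candidate, abs_corr, rho)
    if kept.size == 0:
        kept = np.array([int(np.argmax(scores))])
    return np.sort(np.unique(kept))


def select_features(features: np.ndarray, labels: np.ndarray,
                    params: EHAParams | None = None,
                    seed: int | None = None) -> SelectionResult:
    """EHA search over (quantile, redundancy cutoff) in the unit square.

    The candidate set at position (q, rho) contains features whose CD score
    reaches the q-quantile of all scores; greedy pruning then removes
    redundant candidates.  Fitness is the Euclidean distance between class
    centroids in the selected standardized subspace divided by k**(1/4)
    (k = subset size): the mild size penalty rejects pure-noise features
    without collapsing the selection onto the single best-scoring feature.
    Always returns at least one feature (argmax CD fallback).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if params is None:
        params = EHAParams()
    if seed is not None:
        params = EHAParams(**{**params.__dict__, "seed": seed})
    if params.search_dim != 2:
        raise ValueError("feature selection requires search_dim = 2")

    scores, delta, abs_corr, order = _prepare_selection(X, y)
    delta_sq = delta**2

    cache: dict[tuple[int, float], tuple[float, np.ndarray]] = {}

    def _selection_at(q: float, rho: float) -> tuple[float, np.ndarray]:
        rho = round(float(rho), 2)  # coarse grid keeps the search cacheable
        thr = np.quantile(scores, q)
        candidate = scores >= thr
        key = (int(candidate.sum()), rho)
        if key not in cache:
            kept = _greedy_prune(order, candidate, abs_corr, rho)
            if kept.size == 0:
                kept = np.array([int(np.argmax(scores))])
            fit = float(np.sqrt(delta_sq[kept].sum()) / kept.size**0.25)
            cache[key] = (fit, kept)
        return cache[key]

    def objective(pos: np.ndarray) -> float:
        return _selection_at(pos[0], pos[1])[0]

    result = eha_optimize(objective, params)
    q, rho = float(result.best_position[0]), float(result.best_position[1])
    fit, kept = _selection_at(q, rho)
    return SelectionResult(np.sort(np.unique(kept)), scores, q, round(rho, 2), fit)
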