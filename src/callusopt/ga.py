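"""Discrete single-point-crossover genetic algorithm over the culture grid.

A chromosome is the 4-gene integer tuple (treatment 1-8, explant index 1-4,
MS-level index 1-3, day index 1-2), i.e. one of the 192 culture conditions.
Fitness is the trained surrogate's prediction, memoised over the full grid at
the start of a run (the search space is finite, so every chromosome's fitness
is a table lookup).

Single-objective mode maximises one predicted output with binary tournament
selection, single-point crossover, per-gene uniform resampling mutation,
elitism and a small stream of random immigrants (so the finite grid is
eventually covered even on landscapes with no exploitable structure).  Multi-objective mode is the established non-dominated GA scheme:
fast non-dominated sorting with crowding-distance tie-breaking (NSGA-II
style), an archive of every condition evaluated, and a single reported
compromise solution chosen by maximising the sum of min–max-normalised
objectives over the final front.

The speed objective is maximised as a *desirability* (diameter/time scale);
a surrogate trained on the as-written time/diameter value can be plugged in
with ``speed_sense="min"``, which negates its predictions for the search.

Because the space has only 192 points, :func:`brute_force_optimum` gives the
exact answer and serves as the oracle every GA run is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .design import CultureCondition, EXPLANTS, MS_LEVELS, SAMPLING_DAYS, encode_condition, full_grid

GENE_RANGES = (8, 4, 3, 2)

Chromosome = tuple[int, int, int, int]


def decode_chromosome(c: Sequence[int]) -> CultureCondition:
    t, e, m, d = (int(g) for g in c)
    return CultureCondition(t, EXPLANTS[e - 1], MS_LEVELS[m - 1], SAMPLING_DAYS[d - 1])


def chromosome_of(cond: CultureCondition) -> Chromosome:
    return (
        cond.treatment_id,
        EXPLANTS.index(cond.explant) + 1,
        MS_LEVELS.index(cond.ms_level) + 1,
        SAMPLING_DAYS.index(cond.sampling_day) + 1,
    )


def _grid_index(c: Sequence[int]) -> int:
    t, e, m, d = (int(g) for g in c)
    return (((t - 1) * 4 + (e - 1)) * 3 + (m - 1)) * 2 + (d - 1)


def _all_chromosomes() -> np.ndarray:
    out = np.empty((192, 4), dtype=int)
    i = 0
    for t in range(1, 9):
        for e in range(1, 5):
            for m in range(1, 4):
                for d in range(1, 3):
                    out[i] = (t, e, m, d)
                    i += 1
    return out


@dataclass
class GAConfig:
    population_size: int = 100
    generations: int = 1000
    crossover_prob: float = 0.9
    mutation_prob: float = 0.05
    tournament_size: int = 2
    elitism: int = 1
    immigrants: int = 5             # uniform-random individuals injected per generation
    seed: int = 0
    objectives: str = "percentage"      # percentage | speed | both
    speed_sense: str = "max"            # surrogate predicts desirability (max) or as-written (min)

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.objectives not in ("percentage", "speed", "both"):
            raise ValueError(f"unknown objectives {self.objectives!r}")
        if self.speed_sense not in ("max", "min"):
            raise ValueError(f"unknown speed_sense {self.speed_sense!r}")
        if not 0 <= self.mutation_prob <= 1 or not 0 <= self.crossover_prob <= 1:
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class ParetoResult:
    """GA output: decoded optimum (single mode) or front + compromise (both)."""

    objectives: str
    best_chromosome: Chromosome
    best_condition: CultureCondition
    best_objectives: dict[str, float]
    history: list[float]
    front: list[tuple[Chromosome, float, float]] = field(default_factory=list)
    selected_solution: Chromosome | None = None
    selection_rule: str = ""


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------


def single_point_crossover(
    a: Sequence[int], b: Sequence[int], cut: int, apply: bool = True
) -> tuple[Chromosome, Chromosome]:
    """Swap gene suffixes after position ``cut`` (1-3); conserves alleles."""
    if not 1 <= cut <= 3:
        raise ValueError(f"cut must be in 1..3, got {cut}")
    a = tuple(int(g) for g in a)
    b = tuple(int(g) for g in b)
    if not apply:
        return a, b
    return a[:cut] + b[cut:], b[:cut] + a[cut:]


def mutate(c: Sequence[int], p: float, rng: np.random.Generator) -> Chromosome:
    """Resample each gene uniformly from its range with probability ``p``."""
    if not 0 <= p <= 1:
        raise ValueError(f"mutation probability must be in [0, 1], got {p}")
    genes = list(int(g) for g in c)
    for i, r in enumerate(GENE_RANGES):
        if rng.random() < p:
            genes[i] = int(rng.integers(1, r + 1))
    return tuple(genes)


def non_dominated_sort(points: np.ndarray) -> np.ndarray:
    """Pareto ranks (0 = non-dominated) for objective pairs, maximising both.

    Equal points share a rank; rank k is the non-dominated set once ranks
    < k are removed.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    ranks = np.full(n, -1, dtype=int)
    remaining = np.arange(n)
    rank = 0
    while remaining.size:
        sub = pts[remaining]
        nondom = np.ones(remaining.size, dtype=bool)
        for i in range(remaining.size):
            if not nondom[i]:
                continue
            dominated = (sub >= sub[i]).all(axis=1) & (sub > sub[i]).any(axis=1)
            if dominated.any():
                nondom[i] = False
        ranks[remaining[nondom]] = rank
        remaining = remaining[~nondom]
        rank += 1
    return ranks


def crowding_distance(points: np.ndarray) -> np.ndarray:
    """NSGA-II crowding distance within one front (boundary points infinite)."""
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if n <= 2:
        return np.full(n, np.inf)
    dist = np.zeros(n)
    for j in range(pts.shape[1]):
        order = np.argsort(pts[:, j], kind="stable")
        span = pts[order[-1], j] - pts[order[0], j]
        dist[order[0]] = dist[order[-1]] = np.inf
        if span > 0:
            dist[order[1:-1]] += (pts[order[2:], j] - pts[order[:-2], j]) / span
    return dist


# ---------------------------------------------------------------------------
# Fitness memoisation over the grid
# ---------------------------------------------------------------------------


def grid_objectives(model_pct=None, model_speed=None, speed_sense: str = "max") -> dict:
    """Predict both objectives for all 192 conditions (row i = grid index i)."""
    chroms = _all_chromosomes()
    X = np.stack([encode_condition(decode_chromosome(c)) for c in chroms])
    out = {"chromosomes": chroms}
    if model_pct is not None:
        out["percentage"] = np.asarray(model_pct.predict(X), dtype=float)
    if model_speed is not None:
        s = np.asarray(model_speed.predict(X), dtype=float)
        out["speed"] = s if speed_sense == "max" else -s
    return out


def _objective_matrix(grid: dict, objectives: str) -> np.ndarray:
    cols = []
    if objectives in ("percentage", "both"):
        cols.append(grid["percentage"])
    if objectives in ("speed", "both"):
        cols.append(grid["speed"])
    return np.column_stack(cols)


def _compromise(front_pts: np.ndarray) -> int:
    """Index of the compromise point: max sum of min-max-normalised objectives."""
    lo = front_pts.min(axis=0)
    span = np.where(front_pts.max(axis=0) - lo > 0, front_pts.max(axis=0) - lo, 1.0)
    score = ((front_pts - lo) / span).sum(axis=1)
    return int(np.argmax(score))


# ---------------------------------------------------------------------------
# Optimisation
# ---------------------------------------------------------------------------


def brute_force_optimum(model_pct=None, model_speed=None, objectives: str = "percentage",
                        speed_sense: str = "max") -> ParetoResult:
    """Exact optimum / Pareto front by evaluating all 192 conditions.

    Ties in fitness are broken toward the lexicographically smallest
    chromosome tuple.
    """
    grid = grid_objectives(model_pct, model_speed, speed_sense)
    chroms = grid["chromosomes"]
    F = _objective_matrix(grid, objectives)
    if objectives == "both":
        ranks = non_dominated_sort(F)
        front_idx = np.flatnonzero(ranks == 0)
        order = np.lexsort(tuple(chroms[front_idx][:, k] for k in (3, 2, 1, 0)))
        front_idx = front_idx[order]
        front = [
            (tuple(int(g) for g in chroms[i]), float(F[i, 0]), float(F[i, 1]))
            for i in front_idx
        ]
        sel = front_idx[_compromise(F[front_idx])]
        best = tuple(int(g) for g in chroms[sel])
        return ParetoResult(
            objectives,
            best,
            decode_chromosome(best),
            {"percentage": float(F[sel, 0]), "speed": float(F[sel, 1])},
            [],
            front,
            best,
            "max-normalized-objective-sum",
        )
    f = F[:, 0]
    best_i = min(
        range(len(f)), key=lambda i: (-f[i], tuple(int(g) for g in chroms[i]))
    )
    best = tuple(int(g) for g in chroms[best_i])
    return ParetoResult(
        objectives, best, decode_chromosome(best), {objectives: float(f[best_i])}, []
    )


def optimize(model_pct=None, model_speed=None, cfg: GAConfig | None = None) -> ParetoResult:
    """Run the GA; deterministic for a fixed config seed."""
    cfg = cfg or GAConfig()
    if cfg.objectives in ("percentage", "both") and model_pct is None:
        raise ValueError("percentage objective requires a trained percentage surrogate")
    if cfg.objectives in ("speed", "both") and model_speed is None:
        raise ValueError("speed objective requires a trained speed surrogate")
    grid = grid_objectives(model_pct, model_speed, cfg.speed_sense)
    F = _objective_matrix(grid, cfg.objectives)
    rng = np.random.default_rng(cfg.seed)
    pop = np.column_stack(
        [rng.integers(1, r + 1, cfg.population_size) for r in GENE_RANGES]
    )
    if cfg.objectives == "both":
        return _run_multi(pop, F, grid, cfg, rng)
    return _run_single(pop, F[:, 0], grid, cfg, rng)


def _pop_indices(pop: np.ndarray) -> np.ndarray:
    return (((pop[:, 0] - 1) * 4 + (pop[:, 1] - 1)) * 3 + (pop[:, 2] - 1)) * 2 + (
        pop[:, 3] - 1
    )


def _offspring(pop: np.ndarray, parent_idx: np.ndarray, cfg: GAConfig,
               rng: np.random.Generator) -> np.ndarray:
    """Pair selected parents, apply single-point crossover and mutation."""
    children = []
    for i in range(0, len(parent_idx) - 1, 2):
        a = tuple(pop[parent_idx[i]])
        b = tuple(pop[parent_idx[i + 1]])
        cut = int(rng.integers(1, 4))
        c1, c2 = single_point_crossover(a, b, cut, apply=rng.random() < cfg.crossover_prob)
        children.append(mutate(c1, cfg.mutation_prob, rng))
        children.append(mutate(c2, cfg.mutation_prob, rng))
    if len(parent_idx) % 2:
        children.append(mutate(tuple(pop[parent_idx[-1]]), cfg.mutation_prob, rng))
    children = np.array(children, dtype=int)
    # random immigrants keep the search globally ergodic on the finite grid
    n_imm = min(cfg.immigrants, len(children))
    if n_imm:
        imm = np.column_stack([rng.integers(1, r + 1, n_imm) for r in GENE_RANGES])
        children[len(children) - n_imm :] = imm
    return children


def _run_single(pop, fitness_table, grid, cfg, rng) -> ParetoResult:
    chroms = grid["chromosomes"]
    history: list[float] = []
    # best-so-far with deterministic tie-break (lexicographically smallest genes)
    best_key = None
    for _ in range(cfg.generations):
        fit = fitness_table[_pop_indices(pop)]
        for i in range(len(pop)):
            key = (-fit[i], tuple(int(g) for g in pop[i]))
            if best_key is None or key < best_key:
                best_key = key
        history.append(-best_key[0])
        order = np.argsort(-fit, kind="stable")
        elite = pop[order[: cfg.elitism]]
        n_children = cfg.population_size - cfg.elitism
        cand = rng.integers(0, len(pop), (n_children, cfg.tournament_size))
        winners = cand[np.arange(n_children), np.argmax(fit[cand], axis=1)]
        children = _offspring(pop, winners, cfg, rng)
        pop = np.vstack([elite, children[:n_children]])
    best = best_key[1]
    return ParetoResult(
        cfg.objectives,
        best,
        decode_chromosome(best),
        {cfg.objectives: float(-best_key[0])},
        history,
    )


def _run_multi(pop, F, grid, cfg, rng) -> ParetoResult:
    chroms = grid["chromosomes"]
    archive: set[int] = set(_pop_indices(pop).tolist())
    history: list[float] = []
    for _ in range(cfg.generations):
        idx = _pop_indices(pop)
        objs = F[idx]
        ranks = non_dominated_sort(objs)
        crowd = np.empty(len(pop))
        for r in np.unique(ranks):
            members = np.flatnonzero(ranks == r)
            crowd[members] = crowding_distance(objs[members])
        # scalarised front summary: best normalised-objective sum on rank 0
        front_members = np.flatnonzero(ranks == 0)
        fp = objs[front_members]
        lo, hi = fp.min(axis=0), fp.max(axis=0)
        span = np.where(hi - lo > 0, hi - lo, 1.0)
        history.append(float(((fp - lo) / span).sum(axis=1).max()))
        # binary tournament on (rank, -crowding)
        n_children = cfg.population_size
        cand = rng.integers(0, len(pop), (n_children, cfg.tournament_size))
        keys = ranks[cand] - 1e-12 * np.minimum(crowd[cand], 1e6)
        winners = cand[np.arange(n_children), np.argmin(keys, axis=1)]
        children = _offspring(pop, winners, cfg, rng)
        archive.update(_pop_indices(children).tolist())
        # environmental selection from parents + children
        union = np.vstack([pop, children])
        u_idx = _pop_indices(union)
        u_objs = F[u_idx]
        u_ranks = non_dominated_sort(u_objs)
        u_crowd = np.empty(len(union))
        for r in np.unique(u_ranks):
            members = np.flatnonzero(u_ranks == r)
            u_crowd[members] = crowding_distance(u_objs[members])
        order = np.lexsort((-u_crowd, u_ranks))
        pop = union[order[: cfg.population_size]]
    arch = np.array(sorted(archive), dtype=int)
    ranks = non_dominated_sort(F[arch])
    front_idx = arch[np.flatnonzero(ranks == 0)]
    order = np.lexsort(tuple(chroms[front_idx][:, k] for k in (3, 2, 1, 0)))
    front_idx = front_idx[order]
    front = [
        (tuple(int(g) for g in chroms[i]), float(F[i, 0]), float(F[i, 1]))
        for i in front_idx
    ]
    sel = front_idx[_compromise(F[front_idx])]
    best = tuple(int(g) for g in chroms[sel])
    return ParetoResult(
        "both",
        best,
        decode_chromosome(best),
        {"percentage": float(F[sel, 0]), "speed": float(F[sel, 1])},
        history,
        front,
        best,
        "max-normalized-objective-sum",
    )
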