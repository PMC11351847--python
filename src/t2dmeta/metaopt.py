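"""Bald Eagle Search and Red Deer optimization, and the feature-selection wrapper.

Both algorithms are bounded continuous minimizers over [LB, UB]^d with
elitist best tracking and greedy (improvement-only) acceptance of every
proposed move, so the best-fitness trace is non-increasing by construction.

Bald Eagle Search (BESO) iterates three stages modeled on a hunting eagle:

* select  -- P_new = P_best + a * r * (P_mean - P_i), r ~ U(0,1) per agent;
* search  -- a spiral scan: with theta_i = a_polar * pi * rand and
  r_i = theta_i + R + rand, polar coordinates (r_i sin theta_i,
  r_i cos theta_i) are normalized by the population maxima and drive
  P_new = P_i + y_i (P_i - P_{i+1}) + x_i (P_i - P_mean);
* swoop   -- hyperbolic form with r_i = theta_i and sinh/cosh coordinates:
  P_new = rand * P_best + x1_i (P_i - C1 P_mean) + y1_i (P_i - C2 P_best),
  C1, C2 ~ U(1, 2).

Red Deer optimization (RDO) evolves a herd of ``pop_size`` deer whose best
``n_males`` are males and the rest hinds.  Each generation: a fraction of
males roar (a random step; improvers become commanders), commanders fight
random stags (midpoint +/- random step; the best contender leads), harems
form in proportion to commander fitness, and offspring arise from commander
x own-harem (fraction alpha), commander x other-harem (fraction beta) and
stag x nearest-hind matings.  The next generation keeps the elite males and
fills up by roulette-wheel selection on inverse cost.

For feature selection a d-dimensional position in [0,1]^d is decoded as the
top-k coordinates (ties to the lowest index), scored by a wrapper fitness:
stratified cross-validated nearest-centroid error plus a small sparsity
term.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._util import as_rng, round_half_up


class OptimizationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# containers


@dataclass(frozen=True)
class Bounds:
    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "lb", np.asarray(self.lb, dtype=float))
        object.__setattr__(self, "ub", np.asarray(self.ub, dtype=float))
        if self.lb.shape != self.ub.shape or np.any(self.lb >= self.ub):
            raise ValueError("bounds require LB < UB elementwise")

    @classmethod
    def cube(cls, d: int, lo: float = 0.0, hi: float = 1.0) -> "Bounds":
        return cls(np.full(d, lo), np.full(d, hi))

    def clamp(self, positions: np.ndarray) -> np.ndarray:
        return np.clip(positions, self.lb, self.ub)

    @property
    def dim(self) -> int:
        return self.lb.size


@dataclass(frozen=True)
class BesoParams:
    """Eagle-search settings; the stage coefficients live in their stated ranges."""

    pop_size: int = 30
    iters: int = 50
    a_select: float = 2.0  # in [1.5, 2]
    a_polar: float = 7.5  # in (5, 10)
    R: float = 1.5  # in [0.5, 2]
    c_low: float = 1.0  # C1, C2 ~ U(c_low, c_high)
    c_high: float = 2.0
    seed: int | None = None

    def validate(self) -> None:
        if not 1.5 <= self.a_select <= 2.0:
            raise ValueError("a_select must lie in [1.5, 2]")
        if not 5.0 < self.a_polar < 10.0:
            raise ValueError("a_polar must lie in (5, 10)")
        if not 0.5 <= self.R <= 2.0:
            raise ValueError("R must lie in [0.5, 2]")
        if not 1.0 <= self.c_low <= self.c_high <= 2.0:
            raise ValueError("C draws must lie in [1, 2]")


@dataclass(frozen=True)
class RdoParams:
    """Red-deer settings; defaults follow the published parameter table."""

    pop_size: int = 100  # initial population I
    n_males: int = 15  # M; hinds H = I - M
    iters: int = 30
    time_limit_s: float | None = None  # 10 s in the study; None disables
    alpha: float = 0.85  # own-harem mating fraction
    beta: float = 0.4  # other-harem mating fraction
    gamma: float = 0.7  # listed in the source table; unused by default
    roar: float = 0.25  # fraction of males roaring per generation
    fight: float = 0.4  # fraction of stags each commander fights
    mating: float = 0.77  # offspring-pool cap relative to pop_size
    seed: int | None = None

    def validate(self) -> None:
        if not 0 < self.n_males < self.pop_size:
            raise ValueError("need 0 < n_males < pop_size")
        for name in ("alpha", "beta", "gamma", "roar", "fight", "mating"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class Population:
    positions: np.ndarray  # (agents, d)
    fitness: np.ndarray  # (agents,), lower is better
    best_position: np.ndarray
    best_fitness: float
    trace: list = field(default_factory=list)


@dataclass
class SelectionResult:
    indices: np.ndarray  # sorted, distinct
    mask: np.ndarray  # boolean length-d
    best_fitness: float
    trace: list
    method: str


def _evaluate(fitness_fn, positions: np.ndarray) -> np.ndarray:
    vals = np.array([fitness_fn(p) for p in positions], dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = positions[int(np.flatnonzero(~np.isfinite(vals))[0])]
        raise OptimizationError(f"non-finite fitness at position {bad}")
    return vals


def _greedy_accept(positions, fitness, proposals, fitness_fn):
    new_fit = _evaluate(fitness_fn, proposals)
    improved = new_fit < fitness
    positions = np.where(improved[:, None], proposals, positions)
    fitness = np.where(improved, new_fit, fitness)
    return positions, fitness, improved


# ---------------------------------------------------------------------------
# BESO stages


def beso_select_stage(pop: Population, params: BesoParams, rng, fitness_fn) -> Population:
    """Exploration: move toward the best, scaled by the mean-offset."""
    n = pop.positions.shape[0]
    r = as_rng(rng).random(n)
    p_mean = pop.positions.mean(axis=0)
    proposals = pop.best_position[None, :] + (
        params.a_select * r[:, None] * (p_mean[None, :] - pop.positions)
    )
    return _accept_stage(pop, proposals, fitness_fn)


def _spiral_coords(n: int, params: BesoParams, rng, hyperbolic: bool):
    """Per-agent spiral coordinates normalized by the population maxima.

    Draw order (documented for stub-based tests): one uniform vector for
    theta, then -- in the planar form only -- one for the radius increment.
    """
    rng = as_rng(rng)
    theta = params.a_polar * np.pi * rng.random(n)
    if hyperbolic:
        r = theta.copy()
        xr = r * np.sinh(theta)
        yr = r * np.cosh(theta)
    else:
        r = theta + params.R + rng.random(n)
        xr = r * np.sin(theta)
        yr = r * np.cos(theta)
    x_den = np.max(np.abs(xr)) or 1.0
    y_den = np.max(np.abs(yr)) or 1.0
    return xr / x_den, yr / y_den


def beso_search_stage(pop: Population, params: BesoParams, rng, fitness_fn) -> Population:
    """Spiral scan of the selected area (planar sin/cos coordinates)."""
    n = pop.positions.shape[0]
    x, y = _spiral_coords(n, params, rng, hyperbolic=False)
    p_mean = pop.positions.mean(axis=0)
    neighbor = np.roll(pop.positions, -1, axis=0)  # P_{i+1}; last pairs with first
    proposals = (
        pop.positions
        + y[:, None] * (pop.positions - neighbor)
        + x[:, None] * (pop.positions - p_mean[None, :])
    )
    return _accept_stage(pop, proposals, fitness_fn)


def beso_swoop_stage(pop: Population, params: BesoParams, rng, fitness_fn) -> Population:
    """Convergence dive (hyperbolic sinh/cosh coordinates, r_i = theta_i).

    Draw order: theta vector, then the rand vector multiplying P_best,
    then C1 and C2 vectors in U(c_low, c_high).
    """
    rng = as_rng(rng)
    n = pop.positions.shape[0]
    x1, y1 = _spiral_coords(n, params, rng, hyperbolic=True)
    move_rand = rng.random(n)
    c1 = rng.uniform(params.c_low, params.c_high, n)
    c2 = rng.uniform(params.c_low, params.c_high, n)
    p_mean = pop.positions.mean(axis=0)
    proposals = (
        move_rand[:, None] * pop.best_position[None, :]
        + x1[:, None] * (pop.positions - c1[:, None] * p_mean[None, :])
        + y1[:, None] * (pop.positions - c2[:, None] * pop.best_position[None, :])
    )
    return _accept_stage(pop, proposals, fitness_fn)


def _accept_stage(pop: Population, proposals, fitness_fn) -> Population:
    proposals = np.clip(proposals, pop._bounds.lb, pop._bounds.ub)
    positions, fitness, _ = _greedy_accept(pop.positions, pop.fitness, proposals, fitness_fn)
    pop.positions, pop.fitness = positions, fitness
    i = int(np.argmin(fitness))
    if fitness[i] < pop.best_fitness:
        pop.best_fitness = float(fitness[i])
        pop.best_position = positions[i].copy()
    return pop


def population_from_positions(positions, fitness_fn, bounds: Bounds) -> Population:
    """Build a Population around explicit positions (for tests and warm starts)."""
    positions = bounds.clamp(np.atleast_2d(np.asarray(positions, dtype=float)))
    fitness = _evaluate(fitness_fn, positions)
    i = int(np.argmin(fitness))
    pop = Population(
        positions=positions,
        fitness=fitness,
        best_position=positions[i].copy(),
        best_fitness=float(fitness[i]),
    )
    pop._bounds = bounds
    return pop


def _init_population(fitness_fn, bounds: Bounds, pop_size: int, rng) -> Population:
    positions = bounds.lb + as_rng(rng).random((pop_size, bounds.dim)) * (bounds.ub - bounds.lb)
    fitness = _evaluate(fitness_fn, positions)
    i = int(np.argmin(fitness))
    pop = Population(
        positions=positions,
        fitness=fitness,
        best_position=positions[i].copy(),
        best_fitness=float(fitness[i]),
    )
    pop._bounds = bounds
    return pop


def beso_optimize(fitness_fn, bounds: Bounds, params: BesoParams = BesoParams()):
    """Iterate select -> search -> swoop; returns (best_position, best_fitness, trace)."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    pop = _init_population(fitness_fn, bounds, params.pop_size, rng)
    for _ in range(params.iters):
        beso_select_stage(pop, params, rng, fitness_fn)
        beso_search_stage(pop, params, rng, fitness_fn)
        beso_swoop_stage(pop, params, rng, fitness_fn)
        pop.trace.append(pop.best_fitness)
    return pop.best_position, pop.best_fitness, pop.trace


# ---------------------------------------------------------------------------
# RDO phases


def rdo_roar(male_old: np.ndarray, bounds: Bounds, rng) -> np.ndarray:
    """Roar proposal: male +/- a1 * (((UB - LB) * a2) + LB), branch on a3 >= 0.5."""
    rng = as_rng(rng)
    a1, a2, a3 = rng.random(3)
    step = a1 * ((bounds.ub - bounds.lb) * a2 + bounds.lb)
    new = male_old + step if a3 >= 0.5 else male_old - step
    return bounds.clamp(new)


def rdo_roar_phase(position, cost, bounds, rng, fitness_fn):
    """Greedy roar of one male; returns (position, cost, became_commander)."""
    proposal = rdo_roar(position, bounds, rng)
    new_cost = float(fitness_fn(proposal))
    if not np.isfinite(new_cost):
        raise OptimizationError(f"non-finite fitness at position {proposal}")
    if new_cost < cost:
        return proposal, new_cost, True
    return position, cost, False


def rdo_fight(com: np.ndarray, stag: np.ndarray, bounds: Bounds, rng):
    """Fight proposals: midpoint +/- b1 * (((UB - LB) * b2) + LB)."""
    rng = as_rng(rng)
    b1, b2 = rng.random(2)
    mid = (com + stag) / 2.0
    step = b1 * ((bounds.ub - bounds.lb) * b2 + bounds.lb)
    return bounds.clamp(mid + step), bounds.clamp(mid - step)


def rdo_form_harems(commander_costs: np.ndarray, n_hind: int) -> np.ndarray:
    """Harem sizes proportional to normalized commander power.

    Power is the max-cost-shifted inverse cost (lower cost -> higher power);
    sizes are rounded half-up and the rounding residual is absorbed by the
    best commander so that sizes always sum to ``n_hind``.
    """
    costs = np.asarray(commander_costs, dtype=float)
    shifted = costs.max() - costs
    total = shifted.sum()
    p = np.full(len(costs), 1.0 / len(costs)) if total == 0 else shifted / total
    sizes = round_half_up(p * n_hind)
    top = int(np.argmin(costs))
    sizes[top] += n_hind - sizes.sum()
    while sizes.min() < 0:  # extreme rounding: repair from the largest harem
        j = int(np.argmin(sizes))
        k = int(np.argmax(sizes))
        sizes[k] += sizes[j]
        sizes[j] = 0
    return sizes


def roulette_pick(costs: np.ndarray, rng) -> int:
    """One roulette-wheel draw on inverse cost (lower cost -> higher weight)."""
    costs = np.asarray(costs, dtype=float)
    w = costs.max() - costs
    if w.sum() == 0:
        w = np.ones_like(w)
    w = w / w.sum()
    return int(as_rng(rng).choice(len(costs), p=w))


def _mate_pair(p1: np.ndarray, p2: np.ndarray, bounds: Bounds, rng) -> np.ndarray:
    """Offspring by midpoint-plus-noise recombination (the fight-equation form)."""
    rng = as_rng(rng)
    b1, b2 = rng.random(2)
    child = (p1 + p2) / 2.0 + b1 * ((bounds.ub - bounds.lb) * b2 + bounds.lb)
    return bounds.clamp(child)


def rdo_mate(commanders, harems, stags, hinds, bounds, params: RdoParams, rng):
    """All three mating modes; returns the offspring positions (possibly capped).

    ``harems`` maps commander index -> array of hind row indices.  Each
    commander mates with round-half-up(alpha * harem) of its own hinds and
    with round-half-up(beta * |other|) hinds of one random other harem; each
    stag mates with its nearest hind (Euclidean).  The pool is capped at
    round-half-up(mating * pop_size) by a seeded random subset.
    """
    rng = as_rng(rng)
    offspring = []
    n_harems = len(harems)
    for ci, com in enumerate(commanders):
        own = harems[ci]
        n_own = int(round_half_up(params.alpha * len(own)))
        if n_own > 0:
            for hi in rng.choice(own, size=n_own, replace=False):
                offspring.append(_mate_pair(com, hinds[int(hi)], bounds, rng))
        others = [j for j in range(n_harems) if j != ci and len(harems[j])]
        if others:
            oj = others[int(rng.integers(len(others)))]
            n_other = int(round_half_up(params.beta * len(harems[oj])))
            if n_other > 0:
                for hi in rng.choice(harems[oj], size=n_other, replace=False):
                    offspring.append(_mate_pair(com, hinds[int(hi)], bounds, rng))
    if len(hinds):
        for stag in stags:
            d2 = ((hinds - stag[None, :]) ** 2).sum(axis=1)
            offspring.append(_mate_pair(stag, hinds[int(np.argmin(d2))], bounds, rng))
    if not offspring:
        return np.empty((0, bounds.dim))
    offspring = np.stack(offspring)
    cap = int(round_half_up(params.mating * params.pop_size))
    if len(offspring) > cap:
        keep = rng.choice(len(offspring), size=cap, replace=False)
        offspring = offspring[np.sort(keep)]
    return offspring


def rdo_next_gen(parent_pos, parent_cost, pool_pos, pool_cost, params: RdoParams, rng):
    """Elitist carryover of the best n_males plus roulette fill from the pool."""
    rng = as_rng(rng)
    all_pos = np.concatenate([parent_pos, pool_pos]) if len(pool_pos) else parent_pos
    all_cost = np.concatenate([parent_cost, pool_cost]) if len(pool_cost) else parent_cost
    elite_order = np.argsort(all_cost, kind="stable")[: params.n_males]
    elite_pos, elite_cost = all_pos[elite_order], all_cost[elite_order]

    need = params.pop_size - params.n_males
    if len(pool_pos) == 0:
        warnings.warn("empty selection pool: re-sampling parents with replacement")
        pool_pos, pool_cost = parent_pos, parent_cost
    if len(pool_pos) >= need:
        idx = roulette_pick_without(pool_cost, rng, need)
    else:
        warnings.warn("selection pool smaller than needed: sampling with replacement")
        idx = np.array([roulette_pick(pool_cost, rng) for _ in range(need)], dtype=int)
    rest_pos, rest_cost = pool_pos[idx], pool_cost[idx]
    return np.concatenate([elite_pos, rest_pos]), np.concatenate([elite_cost, rest_cost])


def roulette_pick_without(costs: np.ndarray, rng, k: int) -> np.ndarray:
    """k distinct roulette-wheel draws (sequential, weights renormalized)."""
    rng = as_rng(rng)
    costs = np.asarray(costs, dtype=float)
    w = costs.max() - costs
    if w.sum() == 0:
        w = np.ones_like(w)
    w = w.astype(float).copy()
    picked = []
    avail = np.arange(len(costs))
    for _ in range(k):
        p = w[avail]
        p = np.ones_like(p) / len(p) if p.sum() == 0 else p / p.sum()
        j = int(rng.choice(len(avail), p=p))
        picked.append(int(avail[j]))
        avail = np.delete(avail, j)
    return np.array(picked, dtype=int)


def rdo_optimize(fitness_fn, bounds: Bounds, params: RdoParams = RdoParams()):
    """Roar -> fight -> harems -> mating -> next generation, elitist best.

    Stops at ``iters`` generations or ``time_limit_s`` wall-clock seconds
    (whichever first; the time stop is off by default so that seeded runs
    are exactly reproducible).  Returns (best_position, best_fitness, trace).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    positions = bounds.lb + rng.random((params.pop_size, bounds.dim)) * (bounds.ub - bounds.lb)
    costs = _evaluate(fitness_fn, positions)
    best_i = int(np.argmin(costs))
    best_pos, best_cost = positions[best_i].copy(), float(costs[best_i])
    trace = []
    t0 = time.monotonic()

    for _ in range(params.iters):
        order = np.argsort(costs, kind="stable")
        positions, costs = positions[order], costs[order]
        male_pos = positions[: params.n_males].copy()
        male_cost = costs[: params.n_males].copy()
        hind_pos = positions[params.n_males :].copy()
        hind_cost = costs[params.n_males :].copy()

        # roar: a fraction of males explore; improvers become commanders
        n_roar = max(1, int(round_half_up(params.roar * params.n_males)))
        roarers = rng.choice(params.n_males, size=min(n_roar, params.n_males), replace=False)
        commander_idx = []
        for mi in np.sort(roarers):
            male_pos[mi], male_cost[mi], promoted = rdo_roar_phase(
                male_pos[mi], male_cost[mi], bounds, rng, fitness_fn
            )
            if promoted:
                commander_idx.append(int(mi))
        if not commander_idx:  # guarantee a leader
            commander_idx = [int(np.argmin(male_cost))]
        commander_idx = sorted(set(commander_idx))
        stag_idx = [i for i in range(params.n_males) if i not in commander_idx]

        # fight: each commander against a random subset of stags
        if stag_idx:
            n_fight = max(1, int(round_half_up(params.fight * len(stag_idx))))
            for ci in commander_idx:
                opponents = rng.choice(stag_idx, size=min(n_fight, len(stag_idx)), replace=False)
                for si in np.sort(opponents):
                    new1, new2 = rdo_fight(male_pos[ci], male_pos[si], bounds, rng)
                    cand_pos = [male_pos[ci], male_pos[si], new1, new2]
                    cand_cost = [
                        male_cost[ci],
                        male_cost[si],
                        float(fitness_fn(new1)),
                        float(fitness_fn(new2)),
                    ]
                    rank = np.argsort(cand_cost, kind="stable")
                    male_pos[ci], male_cost[ci] = cand_pos[rank[0]], cand_cost[rank[0]]
                    male_pos[si], male_cost[si] = cand_pos[rank[1]], cand_cost[rank[1]]

        # harems proportional to commander power
        com_cost = male_cost[commander_idx]
        sizes = rdo_form_harems(com_cost, len(hind_pos))
        perm = rng.permutation(len(hind_pos))
        harems, at = [], 0
        for s in sizes:
            harems.append(perm[at : at + int(s)])
            at += int(s)

        offspring = rdo_mate(
            [male_pos[ci] for ci in commander_idx],
            harems,
            [male_pos[si] for si in stag_idx],
            hind_pos,
            bounds,
            params,
            rng,
        )
        off_cost = _evaluate(fitness_fn, offspring) if len(offspring) else np.empty(0)

        pool_pos = np.concatenate([hind_pos, offspring]) if len(offspring) else hind_pos
        pool_cost = np.concatenate([hind_cost, off_cost]) if len(offspring) else hind_cost
        positions, costs = rdo_next_gen(
            male_pos, male_cost, pool_pos, pool_cost, params, rng
        )

        i = int(np.argmin(costs))
        if costs[i] < best_cost:
            best_cost, best_pos = float(costs[i]), positions[i].copy()
        trace.append(best_cost)
        if params.time_limit_s is not None and time.monotonic() - t0 > params.time_limit_s:
            break
    return best_pos, best_cost, trace


def random_search(fitness_fn, bounds: Bounds, n_evals: int, seed=None):
    """Budget-matched uniform random-search baseline."""
    rng = np.random.default_rng(seed)
    best_pos, best_cost, trace = None, np.inf, []
    for _ in range(int(n_evals)):
        p = bounds.lb + rng.random(bounds.dim) * (bounds.ub - bounds.lb)
        c = float(fitness_fn(p))
        if c < best_cost:
            best_cost, best_pos = c, p
        trace.append(best_cost)
    return best_pos, best_cost, trace


def beso_eval_budget(params: BesoParams) -> int:
    """Fitness evaluations one BESO run spends (init + three stages per iter)."""
    return params.pop_size * (1 + 3 * params.iters)


# ---------------------------------------------------------------------------
# feature-selection wrapper


def subset_from_position(position: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest coordinates; ties broken toward lower index."""
    position = np.asarray(position, dtype=float).ravel()
    if k > position.size:
        raise ValueError("k must not exceed the position dimension")
    order = np.argsort(-position, kind="stable")
    return np.sort(order[:k])


@dataclass(frozen=True)
class FitnessConfig:
    """Wrapper-fitness settings: CV folds, sparsity weight, margin tie-break
    weight and fold seed."""

    n_folds: int = 5
    sparsity_weight: float = 0.01
    margin_weight: float = 1e-3
    seed: int = 0


def _nearest_centroid_fold(train_x, train_y, test_x, test_y):
    """(hard error, soft margin loss) of nearest-centroid on one fold.

    The soft loss is the mean of (1 + margin)/2 with the relative margin
    (d2_true - d2_other) / (d2_true + d2_other) in [-1, 1]; it decreases
    smoothly as test points sit deeper inside their own class.
    """
    classes = np.unique(train_y)
    centroids = np.stack([train_x[train_y == c].mean(axis=0) for c in classes])
    d2 = ((test_x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    pred = classes[np.argmin(d2, axis=1)]
    col = {c: j for j, c in enumerate(classes)}
    idx = np.array([col[t] for t in test_y])
    rows = np.arange(len(test_y))
    d2_true = d2[rows, idx]
    other = np.where(d2.shape[1] == 2, 1 - idx, idx)  # binary problem in practice
    d2_other = d2[rows, other] if d2.shape[1] == 2 else d2_true
    margin = (d2_true - d2_other) / (d2_true + d2_other + 1e-12)
    return float(np.mean(pred != test_y)), float(np.mean((1.0 + margin) / 2.0))


def _cv_folds(labels, cfg: FitnessConfig):
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def fs_fitness(
    indices,
    features: np.ndarray,
    labels,
    cfg: FitnessConfig = FitnessConfig(),
    folds=None,
) -> float:
    """Cost of a feature subset.

    Mean stratified k-fold nearest-centroid misclassification error plus
    ``sparsity_weight * k / d``, plus a small continuous margin term
    (``margin_weight`` x soft margin loss).  The margin term is bounded by
    ``margin_weight`` -- far below the cost of one misclassification -- and
    exists to keep selection pressure alive on the zero-error plateau,
    where the hard error alone cannot distinguish candidate subsets.
    ``features`` is the d x n_patients matrix; folds are seeded from the
    config so the objective is deterministic within one selection run.
    """
    indices = np.asarray(indices, dtype=int)
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    x = features[indices].T  # (patients, k)
    if folds is None:
        folds = _cv_folds(labels, cfg)
    errors, softs = [], []
    for train_idx, test_idx in folds:
        if len(np.unique(labels[train_idx])) < 2:
            warnings.warn("degenerate class in a fold: fold skipped")
            continue
        err, soft = _nearest_centroid_fold(
            x[train_idx], labels[train_idx], x[test_idx], labels[test_idx]
        )
        errors.append(err)
        softs.append(soft)
    err = float(np.mean(errors)) if errors else 0.5
    soft = float(np.mean(softs)) if softs else 1.0
    return (
        err
        + cfg.sparsity_weight * len(indices) / features.shape[0]
        + cfg.margin_weight * soft
    )


def select_features(
    features: np.ndarray,
    labels,
    method: str = "RDO",
    k: int = 287,
    params=None,
    fitness_cfg: FitnessConfig = FitnessConfig(),
    restarts: int = 1,
) -> SelectionResult:
    """Wrapper feature selection: optimize [0,1]^d positions decoded as top-k.

    ``features`` is the d x n_patients matrix (a FeatureMatrix ``.values``).
    ``restarts`` > 1 runs independent seeded starts (seed, seed + 1000, ...)
    and keeps the lowest-cost run -- the standard multi-start remedy for the
    flat, multimodal subset landscape.  Returns the best subset of exactly
    ``k`` features and the winning run's fitness trace.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    d = features.shape[0]
    if k > d:
        raise ValueError("k must not exceed the number of features")
    bounds = Bounds.cube(d)
    folds = _cv_folds(labels, fitness_cfg)

    def fitness(position):
        return fs_fitness(
            subset_from_position(position, k), features, labels, fitness_cfg, folds=folds
        )

    method = method.upper()
    if method not in ("BESO", "RDO"):
        raise ValueError(f"unknown feature-selection method {method!r}")
    if params is None:
        params = BesoParams() if method == "BESO" else RdoParams()

    best_pos, best_fit, trace = None, np.inf, []
    base_seed = params.seed if params.seed is not None else 0
    for r in range(max(1, restarts)):
        run_params = type(params)(**{**params.__dict__, "seed": base_seed + 1000 * r})
        if method == "BESO":
            pos, fit, tr = beso_optimize(fitness, bounds, run_params)
        else:
            pos, fit, tr = rdo_optimize(fitness, bounds, run_params)
        if fit < best_fit:
            best_pos, best_fit, trace = pos, fit, tr

    indices = subset_from_position(best_pos, k)
    mask = np.zeros(d, dtype=bool)
    mask[indices] = True
    return SelectionResult(
        indices=indices, mask=mask, best_fitness=best_fit, trace=trace, method=method
    )
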