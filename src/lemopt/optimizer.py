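"""Artificial Lemming Algorithm (ALA) and its hill-climbing hybrid (AHALA).

ALA is a population metaheuristic for bound-constrained minimisation whose
agents imitate four lemming behaviours:

* long-distance **migration** and burrow **digging** (exploration),
* spiral **foraging** and predator **evasion** (exploitation).

An energy factor ``E = 4 (1 - t/Tmax) ln(1/rand)`` decays over the run and
switches each agent between the exploratory (``E > 1``) and exploitative
(``E <= 1``) pairs of moves.  AHALA augments ALA with an adaptive
hill-climbing refinement of the incumbent best solution every ``k``
iterations: ``M`` uniform perturbations scaled per dimension by the bound
range, accepted only on strict improvement, with the step size decayed
geometrically (``alpha <- beta * alpha``) after every rejection.

Everything here follows the minimisation convention; wrap a maximisation
objective with a negation.  A single seeded NumPy generator drives each run,
so identical configurations reproduce identical traces, and the hybrid with
``k > Tmax`` is bit-identical to plain ALA under a shared seed (the
hill-climbing branch never consumes random draws when it does not fire).
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "SearchSpace",
    "Population",
    "MoveSample",
    "AHALAConfig",
    "OptimizationTrace",
    "init_population",
    "energy_factor",
    "draw_energy",
    "levy_step",
    "migration_update",
    "dig_update",
    "forage_update",
    "evade_update",
    "clip_to_bounds",
    "hill_climb",
    "run_ala",
    "run_ahala",
    "run_hill_climbing",
]

LEVY_BETA = 1.5  # Lévy exponent of the Mantegna step sampler


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SearchSpace:
    """Bound-constrained search domain.

    Parameters
    ----------
    lb, ub
        Per-dimension lower/upper bounds.  ``lb[j] <= ub[j]`` must hold and
        both must be finite.
    integer_mask
        Marks dimensions that downstream consumers decode as integers
        (nearest-integer rounding).  The optimizer itself always works in
        the continuous relaxation.
    """

    lb: np.ndarray
    ub: np.ndarray
    integer_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        if self.lb.ndim != 1 or self.lb.shape != self.ub.shape:
            raise ValueError("lb and ub must be 1-D arrays of equal length")
        if not (np.isfinite(self.lb).all() and np.isfinite(self.ub).all()):
            raise ValueError("search-space bounds must be finite")
        if np.any(self.lb > self.ub):
            raise ValueError("every lower bound must be <= its upper bound")
        if self.integer_mask is None:
            self.integer_mask = np.zeros(self.lb.size, dtype=bool)
        else:
            self.integer_mask = np.asarray(self.integer_mask, dtype=bool)
            if self.integer_mask.shape != self.lb.shape:
                raise ValueError("integer_mask length must equal dim")

    @property
    def dim(self) -> int:
        return self.lb.size

    @property
    def span(self) -> np.ndarray:
        return self.ub - self.lb


@dataclass
class Population:
    """Agent matrix ``Z`` (N x dim) with fitness and best-so-far state."""

    Z: np.ndarray
    fitness: np.ndarray
    z_best: np.ndarray
    f_best: float

    @property
    def N(self) -> int:
        return self.Z.shape[0]


@dataclass
class MoveSample:
    """Random quantities consumed by a single behavioural move.

    Only the fields a particular move needs are populated; the rest stay
    ``None``.  ``F`` flips the search direction (+1/-1, equiprobable), ``BM``
    is a standard-normal Brownian step vector and ``R`` is uniform on
    [-1, 1] per dimension.
    """

    F: float
    BM: Optional[np.ndarray] = None
    R: Optional[np.ndarray] = None
    L: Optional[float] = None
    spiral: Optional[float] = None
    radius: Optional[float] = None
    G: Optional[float] = None
    levy: Optional[np.ndarray] = None

    @staticmethod
    def draw_migration(dim: int, rng: np.random.Generator) -> "MoveSample":
        F = 1.0 if rng.random() < 0.5 else -1.0
        BM = rng.standard_normal(dim)
        R = 2.0 * rng.random(dim) - 1.0
        return MoveSample(F=F, BM=BM, R=R)


@dataclass
class AHALAConfig:
    """All tunable knobs of ALA/AHALA runs.

    ``k`` is the hill-climbing period (every ``k`` iterations), ``M`` the
    number of perturbation trials per invocation, ``alpha0`` the initial
    relative step size (fraction of each dimension's bound range) and
    ``beta_decay`` the geometric step-decay factor.  ``n_elite`` selects how
    many top agents are refined per invocation (1 = incumbent global best).
    """

    N: int = 30
    Tmax: int = 100
    k: int = 10
    M: int = 10
    alpha0: float = 0.01
    beta_decay: float = 0.9
    seed: int = 42
    n_elite: int = 1
    greedy_agent_update: bool = False
    levy_uniform_uv: bool = False

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("population size N must be >= 1")
        if self.Tmax < 1:
            raise ValueError("Tmax must be >= 1")
        if self.k < 1:
            raise ValueError("hill-climb period k must be >= 1")
        if self.M < 1:
            raise ValueError("hill-climb budget M must be >= 1")
        if not self.alpha0 > 0:
            raise ValueError("alpha0 must be > 0")
        if not 0.0 < self.beta_decay < 1.0:
            raise ValueError("beta_decay must lie in (0, 1)")
        if self.n_elite < 1:
            raise ValueError("n_elite must be >= 1")


@dataclass
class OptimizationTrace:
    """Per-iteration diagnostics of a run.

    ``best_per_iter`` is the best-so-far fitness after each iteration
    (non-increasing), ``diversity_per_iter`` the mean agent distance to the
    population centroid, ``eval_count`` the exact number of objective
    evaluations spent.
    """

    best_per_iter: np.ndarray
    diversity_per_iter: np.ndarray
    eval_count: int
    elapsed: float = 0.0


class _CountingObjective:
    """Wraps an objective: counts calls, maps non-finite values to +inf."""

    def __init__(self, f: Callable[[np.ndarray], float]):
        self._f = f
        self.count = 0

    def __call__(self, x: np.ndarray) -> float:
        self.count += 1
        val = float(self._f(np.asarray(x, dtype=float)))
        return val if math.isfinite(val) else math.inf


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def init_population(
    space: SearchSpace,
    N: int,
    rng: np.random.Generator,
    f: Optional[Callable[[np.ndarray], float]] = None,
) -> Population:
    """Uniform random initialisation ``z = lb + rand * (ub - lb)``.

    When an objective ``f`` is given, all agents are evaluated and the
    best-so-far state is set; otherwise fitness is +inf placeholders.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    Z = space.lb + rng.random((N, space.dim)) * space.span
    if f is not None:
        fitness = np.array([f(z) for z in Z], dtype=float)
    else:
        fitness = np.full(N, np.inf)
    best = int(np.argmin(fitness))
    return Population(Z=Z, fitness=fitness, z_best=Z[best].copy(), f_best=float(fitness[best]))


def energy_factor(t: int, Tmax: int, rand: float) -> float:
    """Decaying energy ``E = 4 (1 - t/Tmax) ln(1/rand)``, ``rand in (0, 1]``."""
    if not 0 <= t <= Tmax:
        raise ValueError("iteration t must lie in [0, Tmax]")
    if not 0.0 < rand <= 1.0:
        raise ValueError("rand must lie in (0, 1]")
    return 4.0 * (1.0 - t / Tmax) * math.log(1.0 / rand)


def draw_energy(t: int, Tmax: int, rng: np.random.Generator) -> float:
    """Sample the energy factor, resampling the degenerate ``rand = 0`` draw."""
    u = rng.random()
    while u == 0.0:  # ln(1/0) diverges
        u = rng.random()
    return energy_factor(t, Tmax, u)


def _levy_sigma(beta: float = LEVY_BETA) -> float:
    num = math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
    den = math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0)
    return (num / den) ** (1.0 / beta)


def levy_step(
    dim: int,
    rng: np.random.Generator,
    uniform_uv: bool = False,
) -> np.ndarray:
    """Heavy-tailed Lévy step, Mantegna scheme with exponent beta = 1.5.

    Per component: ``0.01 * u * sigma / |v|**(1/beta)`` with ``u, v``
    standard normal.  ``uniform_uv=True`` draws ``u, v`` uniform on [0, 1]
    instead (an alternative reading of the sampler; heavier right tail, no
    sign changes).  Near-zero ``v`` draws are resampled.
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    sigma = _levy_sigma()
    draw = rng.random if uniform_uv else rng.standard_normal
    u = draw(dim)
    v = draw(dim)
    tiny = np.finfo(float).tiny
    while np.any(np.abs(v) < tiny):
        bad = np.abs(v) < tiny
        v[bad] = draw(int(bad.sum()))
    return 0.01 * u * sigma / np.abs(v) ** (1.0 / LEVY_BETA)


def migration_update(
    z_i: np.ndarray,
    z_a: np.ndarray,
    z_best: np.ndarray,
    sample: MoveSample,
) -> np.ndarray:
    """Long-distance migration (exploration).

    ``z_best + F * BM ⊙ [R ⊙ (z_best - z_i) + (1 - R) ⊙ (z_i - z_a)]`` with
    all products elementwise; ``z_a`` is a uniformly chosen agent.
    """
    return z_best + sample.F * sample.BM * (
        sample.R * (z_best - z_i) + (1.0 - sample.R) * (z_i - z_a)
    )


def dig_update(
    z_i: np.ndarray,
    z_b: np.ndarray,
    z_best: np.ndarray,
    F: float,
    t: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Burrow digging (exploration): ``z_i + F * L * (z_best - z_b)``.

    ``L = rand * (1 + sin(t/2))`` ties the dig length to the iteration
    count; it always lies in [0, 2].
    """
    L = rng.random() * (1.0 + math.sin(t / 2.0))
    return z_i + F * L * (z_best - z_b)


def forage_update(
    z_i: np.ndarray,
    z_best: np.ndarray,
    F: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Spiral foraging (exploitation) around the best position.

    ``z_best + F * spiral * rand * z_i`` where
    ``spiral = radius * (sin(2*pi*rand) + cos(2*pi*rand))`` and ``radius``
    is the Euclidean distance between ``z_i`` and ``z_best``.
    """
    radius = float(np.linalg.norm(z_best - z_i))
    theta = rng.random()
    spiral = radius * (math.sin(2.0 * math.pi * theta) + math.cos(2.0 * math.pi * theta))
    return z_best + F * spiral * rng.random() * z_i


def evade_update(
    z_i: np.ndarray,
    z_b: np.ndarray,
    z_best: np.ndarray,
    F: float,
    t: int,
    Tmax: int,
    rng: np.random.Generator,
    uniform_uv: bool = False,
) -> np.ndarray:
    """Predator evasion (exploitation) with Lévy deception.

    ``z_best + F * G * Levy ⊙ (z_best - z_b)`` with escape coefficient
    ``G = 2 (1 - t/Tmax)`` decaying linearly to zero.
    """
    G = 2.0 * (1.0 - t / Tmax)
    step = levy_step(z_i.size, rng, uniform_uv=uniform_uv)
    return z_best + F * G * step * (z_best - z_b)


def clip_to_bounds(z: np.ndarray, space: SearchSpace) -> np.ndarray:
    """Clamp a position into ``[lb, ub]`` componentwise."""
    return np.clip(z, space.lb, space.ub)


def hill_climb(
    x_best: np.ndarray,
    f_best: float,
    f: Callable[[np.ndarray], float],
    space: SearchSpace,
    M: int,
    alpha0: float,
    beta_decay: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, float, float]:
    """Adaptive hill climbing from an already-evaluated point.

    Repeats ``M`` times: perturb by ``alpha * delta ⊙ (ub - lb)`` with
    ``delta ~ U(-1, 1)`` per dimension, accept only on strict improvement,
    otherwise decay ``alpha <- beta_decay * alpha``.  The step size resets
    to ``alpha0`` at every invocation.  Spends exactly ``M`` objective
    evaluations; the returned fitness never exceeds the input fitness.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    x = np.asarray(x_best, dtype=float).copy()
    fx = float(f_best)
    alpha = float(alpha0)
    span = space.span
    for _ in range(M):
        delta = 2.0 * rng.random(space.dim) - 1.0
        x_new = clip_to_bounds(x + alpha * delta * span, space)
        f_new = float(f(x_new))
        if f_new < fx:
            x, fx = x_new, f_new
        else:
            alpha *= beta_decay
    return x, fx, alpha


# ---------------------------------------------------------------------------
# Run loops
# ---------------------------------------------------------------------------

def _population_diversity(Z: np.ndarray) -> float:
    centroid = Z.mean(axis=0)
    return float(np.linalg.norm(Z - centroid, axis=1).mean())


def _run(
    f: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: AHALAConfig,
    hill_climbing: bool,
) -> tuple[np.ndarray, float, OptimizationTrace]:
    rng = np.random.default_rng(config.seed)
    obj = _CountingObjective(f)
    t0 = time.perf_counter()
    pop = init_population(space, config.N, rng, f=obj)
    Tmax = config.Tmax
    best_per_iter = np.empty(Tmax)
    diversity = np.empty(Tmax)

    for t in range(1, Tmax + 1):
        for i in range(pop.N):
            E = draw_energy(t, Tmax, rng)
            r = rng.random()
            z_i = pop.Z[i]
            if E > 1.0:
                if r < 0.3:
                    a = int(rng.integers(pop.N))
                    sample = MoveSample.draw_migration(space.dim, rng)
                    z_new = migration_update(z_i, pop.Z[a], pop.z_best, sample)
                else:
                    b = int(rng.integers(pop.N))
                    F = 1.0 if rng.random() < 0.5 else -1.0
                    z_new = dig_update(z_i, pop.Z[b], pop.z_best, F, t, rng)
            else:
                if r < 0.5:
                    F = 1.0 if rng.random() < 0.5 else -1.0
                    z_new = forage_update(z_i, pop.z_best, F, rng)
                else:
                    b = int(rng.integers(pop.N))
                    F = 1.0 if rng.random() < 0.5 else -1.0
                    z_new = evade_update(
                        z_i, pop.Z[b], pop.z_best, F, t, Tmax, rng,
                        uniform_uv=config.levy_uniform_uv,
                    )
            z_new = clip_to_bounds(z_new, space)
            f_new = obj(z_new)
            # agents adopt the move unconditionally unless greedy updates
            # are requested; the global best is always tracked greedily
            if not config.greedy_agent_update or f_new < pop.fitness[i]:
                pop.Z[i] = z_new
                pop.fitness[i] = f_new
            if f_new < pop.f_best:
                pop.z_best = z_new.copy()
                pop.f_best = f_new

        if hill_climbing and t % config.k == 0:
            if config.n_elite == 1:
                x, fx, _ = hill_climb(
                    pop.z_best, pop.f_best, obj, space,
                    config.M, config.alpha0, config.beta_decay, rng,
                )
                if fx < pop.f_best:
                    pop.z_best, pop.f_best = x, fx
            else:
                order = np.argsort(pop.fitness, kind="stable")[: config.n_elite]
                for i in order:
                    x, fx, _ = hill_climb(
                        pop.Z[i], pop.fitness[i], obj, space,
                        config.M, config.alpha0, config.beta_decay, rng,
                    )
                    pop.Z[i] = x
                    pop.fitness[i] = fx
                    if fx < pop.f_best:
                        pop.z_best, pop.f_best = x.copy(), fx

        best_per_iter[t - 1] = pop.f_best
        diversity[t - 1] = _population_diversity(pop.Z)

    trace = OptimizationTrace(
        best_per_iter=best_per_iter,
        diversity_per_iter=diversity,
        eval_count=obj.count,
        elapsed=time.perf_counter() - t0,
    )
    return pop.z_best.copy(), pop.f_best, trace


def run_ala(
    f: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: AHALAConfig,
) -> tuple[np.ndarray, float, OptimizationTrace]:
    """Plain ALA run (the hill-climbing period ``k`` is ignored).

    Spends exactly ``N * (Tmax + 1)`` objective evaluations.
    """
    return _run(f, space, config, hill_climbing=False)


def run_ahala(
    f: Callable[[np.ndarray], float],
    space: SearchSpace,
    config: AHALAConfig,
) -> tuple[np.ndarray, float, OptimizationTrace]:
    """AHALA run: ALA plus periodic adaptive hill climbing.

    Every ``k``-th iteration the incumbent best (or the ``n_elite`` top
    agents) is refined for ``M`` trials, adding exactly
    ``floor(Tmax / k) * M * n_elite`` objective evaluations over the plain
    ALA budget.
    """
    return _run(f, space, config, hill_climbing=True)


def run_hill_climbing(
    f: Callable[[np.ndarray], float],
    space: SearchSpace,
    iterations: int,
    alpha0: float = 0.01,
    beta_decay: float = 0.9,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, float, OptimizationTrace]:
    """Standalone adaptive hill climbing from a uniform random start.

    The component-comparison baseline: one perturbation trial per
    iteration, strict-improvement acceptance, geometric step decay on
    rejection.  Spends ``iterations + 1`` objective evaluations.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    obj = _CountingObjective(f)
    t0 = time.perf_counter()
    x = space.lb + rng.random(space.dim) * space.span
    fx = obj(x)
    alpha = float(alpha0)
    best_per_iter = np.empty(iterations)
    span = space.span
    for t in range(iterations):
        delta = 2.0 * rng.random(space.dim) - 1.0
        x_new = clip_to_bounds(x + alpha * delta * span, space)
        f_new = obj(x_new)
        if f_new < fx:
            x, fx = x_new, f_new
        else:
            alpha *= beta_decay
        best_per_iter[t] = fx
    trace = OptimizationTrace(
        best_per_iter=best_per_iter,
        diversity_per_iter=np.zeros(iterations),
        eval_count=obj.count,
        elapsed=time.perf_counter() - t0,
    )
    return x, fx, trace
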