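"""Gorilla Troops Optimization (GTO) as a box-constrained maximizer.

GTO is a population metaheuristic modelled on gorilla social behaviour.
Each of N agents is a candidate solution; the best agent is the
"silverback".  Every iteration runs two phases:

* **exploration** (migration): per agent one of three moves — a jump to a
  uniformly random point (probability ``p``), a move towards a random
  troop member, or a repulsion move relative to a random candidate;
* **exploitation**: if the adaptive coefficient ``C = (cos(2 r4) + 1)
  (1 - t/T)`` is at least the switch ``W`` the agent follows the
  silverback, otherwise it competes around it with a force term
  ``A = beta * E`` where ``E`` is standard-normal noise (per-dimension
  vector or broadcast scalar depending on a coin flip).

After each phase candidates are clamped into the box, evaluated, and
accepted only on strict improvement (greedy replacement), so the
best-so-far fitness is monotone non-decreasing.  One run costs
Theta(T N D) time and Theta(N D) memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class NonFiniteObjectiveError(RuntimeError):
    """The objective returned NaN or +inf at some evaluated point."""


@dataclass
class Bounds:
    """Box constraints, elementwise ``lower < upper``."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=np.float64))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=np.float64))
        if self.lower.shape != self.upper.shape or np.any(self.lower >= self.upper):
            raise ValueError("bounds require lower < upper elementwise")

    @property
    def dim(self) -> int:
        return self.lower.size

    def clamp(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


@dataclass
class GTOParams:
    """Troop-size / schedule parameters.

    Defaults follow the published setup for the segmentation task:
    30 agents, 100 iterations, migration probability p = 0.03,
    force multiplier beta = 3 and exploitation switch W = 0.8.
    """

    n_agents: int = 30
    max_iters: int = 100
    p: float = 0.03
    beta: float = 3.0
    W: float = 0.8

    def __post_init__(self) -> None:
        if self.n_agents < 2:
            raise ValueError("need at least 2 agents")
        if self.max_iters < 1:
            raise ValueError("need at least 1 iteration")
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must be in (0, 1)")


@dataclass
class OptimizerResult:
    best_position: np.ndarray
    best_fitness: float
    trace: list[tuple[int, float]] = field(default_factory=list)

    def trace_array(self) -> np.ndarray:
        """Trace as an (n, 2) array of (cumulative evaluations, best fitness)."""
        return np.asarray(self.trace, dtype=np.float64)


def adaptive_coefficients(t_norm: float, r4: float, l: float) -> tuple[float, float, float]:
    """Leadership coefficients: F = cos(2 r4) + 1, C = F (1 - t_norm), L = C l."""
    f = np.cos(2.0 * r4) + 1.0
    c = f * (1.0 - t_norm)
    return c, f, c * l


class _Evaluator:
    """Wraps the objective with an evaluation counter and finiteness check."""

    def __init__(self, objective):
        self.objective = objective
        self.n_evals = 0

    def __call__(self, X: np.ndarray) -> np.ndarray:
        vals = np.array([self.objective(x) for x in X], dtype=np.float64)
        self.n_evals += len(vals)
        if np.any(np.isnan(vals)) or np.any(vals == np.inf):
            raise NonFiniteObjectiveError(
                "objective returned NaN or +inf; cannot maximize")
        return vals


def exploration_move(x: np.ndarray, X: np.ndarray, cand: np.ndarray,
                     t_norm: float, params: GTOParams, bounds: Bounds,
                     rng: np.random.Generator) -> np.ndarray:
    """One exploration (migration) proposal for the agent at position `x`.

    `X` is the current population, `cand` the candidate array the phase is
    filling (used by the third move as the pool of candidate companions).
    """
    n, d = X.shape
    r4 = rng.random()
    l = rng.uniform(-1.0, 1.0)
    c, _, L = adaptive_coefficients(t_norm, r4, l)
    rand = rng.random()
    if rand < params.p:
        # migration to an unknown place: uniform point in the box
        new = bounds.lower + (bounds.upper - bounds.lower) * rng.random(d)
    elif rand >= 0.5:
        # move towards a random troop member
        r2 = rng.random()
        x_r = X[rng.integers(n)]
        z = rng.uniform(-c, c, size=d) if c > 0 else np.zeros(d)
        new = (r2 - c) * x_r + L * (z * x)
    else:
        # repulsion relative to a random candidate companion
        r3 = rng.random()
        x_gr = cand[rng.integers(n)]
        diff = x - x_gr
        new = x - L * (L * diff + r3 * diff)
    return bounds.clamp(new)


def follow_silverback_move(x: np.ndarray, mean_abs: np.ndarray, silverback: np.ndarray,
                           L: float, bounds: Bounds) -> np.ndarray:
    """Exploitation move used when C >= W: drift along the troop mean.

    `mean_abs` is the per-dimension population mean; the published update
    raises its magnitude to ``m = 2**L`` and takes the m-th root, which
    algebraically collapses to the absolute mean — both forms coincide.
    """
    m = 2.0 ** L
    mvec = np.abs(mean_abs) ** m
    mvec = mvec ** (1.0 / m)
    return bounds.clamp(L * mvec * (x - silverback) + x)


def competition_move(x: np.ndarray, silverback: np.ndarray, params: GTOParams,
                     bounds: Bounds, rng: np.random.Generator) -> np.ndarray:
    """Exploitation move used when C < W: competition around the silverback."""
    d = x.size
    r5 = rng.random()
    q = 2.0 * r5 - 1.0
    rand = rng.random()
    if rand >= 0.5:
        e = rng.standard_normal(d)
    else:
        e = np.full(d, rng.standard_normal())
    a = params.beta * e
    return bounds.clamp(silverback - (silverback * q - x * q) * a)


def _greedy_merge(X: np.ndarray, fit: np.ndarray, cand: np.ndarray,
                  cand_fit: np.ndarray) -> None:
    """Keep each candidate iff it strictly improves; ties keep the incumbent."""
    better = cand_fit > fit
    X[better] = cand[better]
    fit[better] = cand_fit[better]


def gto_iteration(X: np.ndarray, fit: np.ndarray, t_norm: float,
                  params: GTOParams, bounds: Bounds, evaluator: _Evaluator,
                  rng: np.random.Generator) -> None:
    """One full GTO generation (exploration + exploitation), in place."""
    n, d = X.shape
    # exploration phase; candidate slots not yet proposed default to the
    # current positions so the repulsion move draws from a defined pool
    cand = X.copy()
    for i in range(n):
        cand[i] = exploration_move(X[i], X, cand, t_norm, params, bounds, rng)
    _greedy_merge(X, fit, cand, evaluator(cand))
    silverback = X[int(np.argmax(fit))].copy()
    # exploitation phase
    mean_vec = X.mean(axis=0)
    cand = np.empty_like(X)
    for i in range(n):
        r4 = rng.random()
        l = rng.uniform(-1.0, 1.0)
        c, _, L = adaptive_coefficients(t_norm, r4, l)
        if c >= params.W:
            cand[i] = follow_silverback_move(X[i], mean_vec, silverback, L, bounds)
        else:
            cand[i] = competition_move(X[i], silverback, params, bounds, rng)
    _greedy_merge(X, fit, cand, evaluator(cand))


def _init_population(bounds: Bounds, n: int, rng: np.random.Generator) -> np.ndarray:
    span = bounds.upper - bounds.lower
    return bounds.lower + span * rng.random((n, bounds.dim))


def gto_optimize(objective, bounds: Bounds, params: GTOParams | None = None,
                 rng: np.random.Generator | int | None = None) -> OptimizerResult:
    """Maximize `objective` over the box with GTO.

    Parameters
    ----------
    objective : callable
        Maps a length-D vector inside the box to a finite real (or -inf
        for invalid encodings).  Maximized.
    bounds : Bounds
    params : GTOParams, optional
    rng : numpy Generator or seed, optional
        Single RNG stream for the whole run; identical seeds replay the
        identical trajectory.

    Returns
    -------
    OptimizerResult
        Best-ever position/fitness and a trace of (cumulative objective
        evaluations, best-so-far fitness), monotone in fitness.
    """
    params = params or GTOParams()
    rng = np.random.default_rng(rng)
    evaluator = _Evaluator(objective)

    X = _init_population(bounds, params.n_agents, rng)
    fit = evaluator(X)
    best_i = int(np.argmax(fit))
    best_x, best_f = X[best_i].copy(), float(fit[best_i])
    trace = [(evaluator.n_evals, best_f)]

    for t in range(1, params.max_iters + 1):
        t_norm = t / params.max_iters
        gto_iteration(X, fit, t_norm, params, bounds, evaluator, rng)
        it_best = int(np.argmax(fit))
        if fit[it_best] > best_f:
            best_f = float(fit[it_best])
            best_x = X[it_best].copy()
        trace.append((evaluator.n_evals, best_f))

    return OptimizerResult(best_x, best_f, trace)
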