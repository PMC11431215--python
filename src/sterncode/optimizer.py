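"""Sooty Tern Optimization Algorithm (STOA) and its Levy-flight variant.

The STOA is a population metaheuristic that mimics the migration and attack
behaviour of sooty terns.  Each search agent carries a real-valued position
inside a box.  An iteration has two phases:

*migration* (global search) — the agent's position is damped by a linearly
decreasing factor ``SA`` (collision avoidance) and pulled toward the current
global best by a random factor ``CB`` drawn once per agent per iteration:

    C = SA * P,    M = CB * (P_best - P),    D = C + M,
    SA = Cf - z * Cf / max_iterations,       CB = 0.5 * Rand.

*attack* (local search) — the agent spirals onto the best position.  With a
spiral angle ``i`` drawn uniformly in [0, 2*pi] and a *contracting* spiral
radius ``R = u * e^{SPIRAL_K_SIGN * i * v}`` (``u = v = 1`` by default; see
below), the offsets ``x' = R sin i``, ``y' = R cos i``, ``z' = R i`` combine
into a scalar gain and the new position is the elementwise product
``(D * (x' + y' + z')) * P_best``.

The exponent constant ``k`` of the spiral law ``r = u e^{k v}`` is a
convention choice; this implementation fixes ``k = -i`` (module constant
:data:`SPIRAL_K_SIGN`), i.e. the attack spiral tightens as the angle
advances.  A growing radius (``k = +i``) makes the attack gain reach
``e^{2 pi} * 2 pi ~ 3.5e3``, so nearly every attack overshoots the box and
convergence then rests on rare lucky contractions; the decaying radius
keeps the gain in ``[~0.01, ~1.3]`` and the spiral reliably contracts onto
the best position.

The Levy variant (LSTOA) replaces the attack update in the later iterations
with a heavy-tailed perturbation: step lengths follow a power-law tail
``P(l) ~ l^{-(1+beta)}``, ``0 < beta <= 2``, generated with the Mantegna
algorithm.  Occasional long jumps let the swarm escape the local optima the
pure spiral update converges to.

All randomness flows through a single seeded :class:`numpy.random.Generator`,
so runs are bit-reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

#: Sign convention for the undefined exponent of the spiral law r = u*e^{kv}:
#: k = SPIRAL_K_SIGN * i, with i the spiral angle.  -1 gives a contracting
#: attack spiral (see module docstring).
SPIRAL_K_SIGN = -1.0

__all__ = [
    "SPIRAL_K_SIGN",
    "OptimizerConfig",
    "OptimizationResult",
    "sa_schedule",
    "migrate",
    "spiral_attack",
    "levy_step",
    "lstoa_optimize",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """Hyperparameters of one (L)STOA run.

    Parameters
    ----------
    bounds : sequence of (low, high)
        Per-dimension box; the problem dimension is ``len(bounds)``.
    population : int
        Number of search agents (>= 2).
    max_iterations : int
        Iteration budget.
    cf : float
        Initial value of the linearly decreasing control factor ``SA``.
    u, v : float
        Spiral shape constants of the attack phase.
    levy_beta : float
        Tail exponent of the Levy step distribution, in (0, 2].
    levy_start_fraction : float
        Fraction of the iteration budget after which the Levy perturbation
        becomes active.  ``1.0`` disables it entirely and recovers the plain
        STOA; ``0.0`` activates it from the first iteration.
    levy_prob : float
        Per-agent probability, in the active phase, that the agent's attack
        update is perturbed by a Levy step.  Occasional long jumps let the
        swarm escape local optima while unperturbed agents keep exploiting.
    levy_scale : float
        Levy step size as a fraction of the box width per dimension.
    penalty_weight : float
        Static penalty added per unit of constraint violation.
    seed : int
        Seed of the run's random generator.
    """

    bounds: tuple[tuple[float, float], ...]
    population: int = 30
    max_iterations: int = 1000
    cf: float = 2.0
    u: float = 1.0
    v: float = 1.0
    levy_beta: float = 1.5
    levy_start_fraction: float = 0.5
    levy_prob: float = 0.25
    levy_scale: float = 0.05
    penalty_weight: float = 1e6
    seed: int = 0

    def __post_init__(self) -> None:
        bounds = tuple((float(lo), float(hi)) for lo, hi in self.bounds)
        object.__setattr__(self, "bounds", bounds)
        if not bounds:
            raise ValueError("bounds must define at least one dimension")
        if any(hi < lo for lo, hi in bounds):
            raise ValueError("each bound must satisfy low <= high")
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.cf <= 0:
            raise ValueError("cf must be positive")
        if not 0.0 < self.levy_beta <= 2.0:
            raise ValueError(f"levy_beta must be in (0, 2], got {self.levy_beta}")
        if not 0.0 <= self.levy_start_fraction <= 1.0:
            raise ValueError("levy_start_fraction must be in [0, 1]")
        if not 0.0 <= self.levy_prob <= 1.0:
            raise ValueError("levy_prob must be in [0, 1]")

    @property
    def dimension(self) -> int:
        return len(self.bounds)

    def with_seed(self, seed: int) -> "OptimizerConfig":
        return replace(self, seed=seed)

    def to_dict(self) -> dict:
        return {
            "bounds": [list(b) for b in self.bounds],
            "population": self.population,
            "max_iterations": self.max_iterations,
            "cf": self.cf,
            "u": self.u,
            "v": self.v,
            "levy_beta": self.levy_beta,
            "levy_start_fraction": self.levy_start_fraction,
            "levy_prob": self.levy_prob,
            "levy_scale": self.levy_scale,
            "penalty_weight": self.penalty_weight,
            "seed": self.seed,
        }


@dataclass
class OptimizationResult:
    """Outcome of one optimizer run."""

    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray  # best-so-far fitness, one entry per iteration (plus init)
    evaluations: int
    seed: int
    config: OptimizerConfig = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "best_position": [float(x) for x in self.best_position],
            "best_fitness": float(self.best_fitness),
            "history": [float(h) for h in self.history],
            "evaluations": self.evaluations,
            "seed": self.seed,
            "config": self.config.to_dict() if self.config is not None else None,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def history_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("iteration,best_fitness\n")
            for i, h in enumerate(self.history):
                fh.write(f"{i},{h!r}\n")


def sa_schedule(z: int, config: OptimizerConfig) -> float:
    """Linearly decreasing control factor: ``Cf`` at z=0, 0 at the last iteration."""
    if not 0 <= z <= config.max_iterations:
        raise ValueError(
            f"iteration index {z} outside [0, {config.max_iterations}]"
        )
    return config.cf - z * (config.cf / config.max_iterations)


def migrate(
    position: np.ndarray,
    best: np.ndarray,
    z: int,
    config: OptimizerConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Migration phase: collision avoidance, convergence, and their sum.

    Returns ``(C, M, D)`` where ``C = SA * P`` damps the old position,
    ``M = CB * (P_best - P)`` pulls toward the global best with a single
    scalar draw ``CB = 0.5 * Rand`` per call, and ``D = C + M``.
    """
    sa = sa_schedule(z, config)
    cb = 0.5 * rng.uniform(0.0, 1.0)
    c = sa * position
    m = cb * (best - position)
    return c, m, c + m


def spiral_attack(
    d_vec: np.ndarray,
    best: np.ndarray,
    rng: np.random.Generator,
    config: OptimizerConfig,
) -> np.ndarray:
    """Attack phase: spiral descent onto the global best.

    Draws one spiral angle ``i`` uniformly in [0, 2*pi], forms the
    contracting radius ``R = u * e^{-i v}`` (:data:`SPIRAL_K_SIGN`
    convention) and the scalar gain ``x' + y' + z'`` with ``x' = R sin i``,
    ``y' = R cos i``, ``z' = R i``, and returns the elementwise product
    ``(D * gain) * best``.
    """
    angle = rng.uniform(0.0, 2.0 * math.pi)
    radius = config.u * math.exp(SPIRAL_K_SIGN * angle * config.v)
    gain = radius * math.sin(angle) + radius * math.cos(angle) + radius * angle
    return (d_vec * gain) * best


_LEVY_SIGMA_CACHE: dict[float, float] = {}


def _mantegna_sigma(beta: float) -> float:
    sigma = _LEVY_SIGMA_CACHE.get(beta)
    if sigma is None:
        sigma = (
            math.gamma(1.0 + beta)
            * math.sin(math.pi * beta / 2.0)
            / (math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0))
        ) ** (1.0 / beta)
        _LEVY_SIGMA_CACHE[beta] = sigma
    return sigma


def levy_step(dimension: int, beta: float, rng: np.random.Generator) -> np.ndarray:
    """Heavy-tailed step vector via the Mantegna algorithm.

    Each component is ``u / |v|^{1/beta}`` with ``u ~ N(0, sigma_u^2)`` and
    ``v ~ N(0, 1)``; the resulting step magnitudes have a power-law tail with
    index ``beta`` and the distribution is symmetric around zero.
    """
    if not 0.0 < beta <= 2.0:
        raise ValueError(f"beta must be in (0, 2], got {beta}")
    sigma = _mantegna_sigma(beta)
    u = rng.normal(0.0, sigma, size=dimension)
    v = rng.normal(0.0, 1.0, size=dimension)
    return u / np.abs(v) ** (1.0 / beta)


def lstoa_optimize(
    objective: Callable[[np.ndarray], float],
    config: OptimizerConfig,
    constraints: Sequence[Callable[[np.ndarray], float]] = (),
    vectorized: bool = False,
) -> OptimizationResult:
    """Minimize ``objective`` over the box with the Levy sooty tern algorithm.

    Parameters
    ----------
    objective : callable
        Maps a position vector to a real value.  Must be finite at every
        feasible point; a non-finite value there aborts the run.  With
        ``vectorized=True`` it instead maps a (population, dimension) array
        to a length-population array, which avoids per-agent Python overhead
        for cheap objectives.
    config : OptimizerConfig
        Run hyperparameters, including the seed.
    constraints : sequence of callables, optional
        Each maps a position vector to a violation amount (<= 0 when
        satisfied).  Violations are folded in by a static additive penalty
        of ``config.penalty_weight`` per violated unit.

    Returns
    -------
    OptimizationResult
        Best position/fitness, per-iteration best-so-far history (index 0 is
        the post-initialization best), and the evaluation count.

    Notes
    -----
    With a scalar objective the population is updated asynchronously: each
    agent's migration and spiral attack reference the best position known at
    that moment, so an improvement found early in an iteration immediately
    steers the remaining agents.  This within-iteration cascade is what
    drives the spiral update's fast contraction onto a good optimum.  With
    ``vectorized=True`` the whole population is updated against the best
    entering the iteration (synchronous), trading some contraction speed
    for batched evaluation.  Either way ``CB`` and the spiral angle are
    drawn once per agent per iteration.
    """
    rng = np.random.default_rng(config.seed)
    dim = config.dimension
    pop = config.population
    low = np.array([b[0] for b in config.bounds])
    high = np.array([b[1] for b in config.bounds])
    span = high - low

    def evaluate(block: np.ndarray) -> np.ndarray:
        if vectorized:
            raw = np.asarray(objective(block), dtype=float)
        else:
            raw = np.array([float(objective(x)) for x in block])
        if constraints:
            violation = np.zeros(len(block))
            for g in constraints:
                violation += np.array(
                    [max(0.0, float(g(x))) for x in block]
                )
        else:
            violation = None
        bad = ~np.isfinite(raw)
        if bad.any():
            feasible_bad = bad if violation is None else bad & (violation == 0.0)
            if feasible_bad.any():
                where = int(np.argmax(feasible_bad))
                raise RuntimeError(
                    f"objective returned non-finite value {raw[where]} at "
                    f"feasible point {block[where].tolist()}"
                )
            raw = np.where(bad, math.inf, raw)
        if violation is not None:
            raw = raw + config.penalty_weight * violation
        return raw

    positions = rng.uniform(low, high, size=(pop, dim))
    fitness = evaluate(positions)
    evaluations = pop

    best_idx = int(np.argmin(fitness))
    best_pos = positions[best_idx].copy()
    best_fit = float(fitness[best_idx])
    history = [best_fit]

    # Iterations up to this threshold use the plain spiral update; beyond
    # it the Levy perturbation takes over.  fraction=1.0 never fires.
    if config.levy_start_fraction < 1.0:
        levy_from = config.levy_start_fraction * config.max_iterations
    else:
        levy_from = math.inf

    sigma = _mantegna_sigma(config.levy_beta)
    for z in range(1, config.max_iterations + 1):
        levy_phase = z > levy_from
        if vectorized:
            sa = sa_schedule(z, config)
            cb = 0.5 * rng.uniform(0.0, 1.0, size=pop)
            d_vecs = sa * positions + cb[:, None] * (best_pos[None, :] - positions)
            angles = rng.uniform(0.0, 2.0 * math.pi, size=pop)
            radius = config.u * np.exp(SPIRAL_K_SIGN * angles * config.v)
            gain = radius * (np.sin(angles) + np.cos(angles) + angles)
            new_pos = d_vecs * gain[:, None] * best_pos[None, :]
            if levy_phase:
                jump = rng.uniform(size=pop) < config.levy_prob
                u = rng.normal(0.0, sigma, size=(pop, dim))
                v = rng.normal(0.0, 1.0, size=(pop, dim))
                steps = u / np.abs(v) ** (1.0 / config.levy_beta)
                new_pos = new_pos + jump[:, None] * config.levy_scale * span * steps
            np.clip(new_pos, low, high, out=new_pos)
            fitness = evaluate(new_pos)
            positions = new_pos
            evaluations += pop
            idx = int(np.argmin(fitness))
            if float(fitness[idx]) < best_fit:
                best_fit = float(fitness[idx])
                best_pos = positions[idx].copy()
        else:
            for a in range(pop):
                _, _, d_vec = migrate(positions[a], best_pos, z, config, rng)
                new_one = spiral_attack(d_vec, best_pos, rng, config)
                if levy_phase and rng.uniform() < config.levy_prob:
                    new_one = new_one + config.levy_scale * span * levy_step(
                        dim, config.levy_beta, rng
                    )
                np.clip(new_one, low, high, out=new_one)
                new_fit = float(evaluate(new_one[None, :])[0])
                evaluations += 1
                positions[a] = new_one
                fitness[a] = new_fit
                if new_fit < best_fit:
                    best_fit = new_fit
                    best_pos = new_one.copy()
        history.append(best_fit)

    return OptimizationResult(
        best_position=best_pos,
        best_fitness=best_fit,
        history=np.asarray(history),
        evaluations=evaluations,
        seed=config.seed,
        config=config,
    )
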