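"""Classic continuous benchmark functions (F1-F13) and a multi-run harness.

Seven high-dimensional unimodal functions (sphere, Schwefel 2.22, rotated
hyper-ellipsoid / Schwefel 1.2, Schwefel 2.21, Rosenbrock, step, quartic with
noise) and six multimodal ones (Schwefel 2.26, Rastrigin, Ackley, Griewank,
and the two penalized functions) with their conventional boxes at dimension
50.  The harness runs an optimizer repeatedly with derived seeds and reports
the mean and standard deviation of the final best fitness per function.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .optimizer import OptimizerConfig, lstoa_optimize

__all__ = [
    "BenchmarkFunction",
    "SuiteReport",
    "get_benchmark",
    "benchmark_suite",
    "evaluate",
    "run_suite",
    "FUNCTION_NAMES",
]

FUNCTION_NAMES = tuple(f"F{i}" for i in range(1, 14))


@dataclass(frozen=True)
class BenchmarkFunction:
    """One benchmark: expression, box, dimension, and (if known) the minimum."""

    name: str
    expression: Callable[[np.ndarray, Optional[np.random.Generator]], float]
    dimension: int
    box: tuple[float, float]
    known_minimum: Optional[float]
    minimizer: Optional[Callable[[int], np.ndarray]]
    noisy: bool = False

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return tuple([self.box] * self.dimension)


def evaluate(
    f: BenchmarkFunction, x: np.ndarray, rng: Optional[np.random.Generator] = None
) -> float:
    """Evaluate ``f`` at ``x``.

    Pure and deterministic except for the quartic-noise function, whose
    additive uniform noise consumes ``rng``; with ``rng=None`` the noise term
    is zeroed (useful for minimum-recovery checks).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (f.dimension,):
        raise ValueError(
            f"{f.name} has dimension {f.dimension}, got point of shape {x.shape}"
        )
    return float(f.expression(x, rng))


def _f1(x, rng):  # sphere
    return np.sum(x**2)


def _f2(x, rng):  # Schwefel 2.22
    ax = np.abs(x)
    return np.sum(ax) + np.prod(ax)


def _f3(x, rng):  # Schwefel 1.2 (double sum)
    return np.sum(np.cumsum(x) ** 2)


def _f4(x, rng):  # Schwefel 2.21
    return np.max(np.abs(x))


def _f5(x, rng):  # Rosenbrock
    return np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2)


def _f6(x, rng):  # step
    return np.sum(np.floor(x + 0.5) ** 2)


def _f7(x, rng):  # quartic with additive noise
    i = np.arange(1, len(x) + 1)
    noise = rng.uniform(0.0, 1.0) if rng is not None else 0.0
    return np.sum(i * x**4) + noise


def _f8(x, rng):  # Schwefel 2.26 (conventional inner square root)
    return np.sum(-x * np.sin(np.sqrt(np.abs(x))))


def _f8_literal(x, rng):  # printed-literal variant without the radical
    return np.sum(-x * np.sin(np.abs(x)))


def _f9(x, rng):  # Rastrigin
    return np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x) + 10.0)


def _f10(x, rng):  # Ackley
    n = len(x)
    return (
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x**2) / n))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / n)
        + 20.0
        + np.e
    )


def _f11(x, rng):  # Griewank
    i = np.arange(1, len(x) + 1)
    return np.sum(x**2) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0


def _u_penalty(x, a, k, m):
    out = np.zeros_like(x)
    over = x > a
    under = x < -a
    out[over] = k * (x[over] - a) ** m
    out[under] = k * (-x[under] - a) ** m
    return out


def _f12(x, rng):  # penalized function 1
    n = len(x)
    y = 1.0 + (x + 1.0) / 4.0
    core = (
        10.0 * np.sin(np.pi * y[0]) ** 2
        + np.sum((y[:-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(np.pi * y[1:]) ** 2))
        + (y[-1] - 1.0) ** 2
    )
    return np.pi / n * core + np.sum(_u_penalty(x, 10.0, 100.0, 4))


def _f13(x, rng):  # penalized function 2 (as printed: no boundary u-term)
    core = (
        np.sin(3.0 * np.pi * x[0]) ** 2
        + np.sum((x[:-1] - 1.0) ** 2 * (1.0 + np.sin(3.0 * np.pi * x[1:]) ** 2))
        + (x[-1] - 1.0) ** 2 * (1.0 + np.sin(2.0 * np.pi * x[-1]) ** 2)
    )
    return 0.1 * core


def _zeros(n: int) -> np.ndarray:
    return np.zeros(n)


def _ones(n: int) -> np.ndarray:
    return np.ones(n)


def _minus_ones(n: int) -> np.ndarray:
    return -np.ones(n)


_CATALOG: dict[str, tuple] = {
    # name: (expression, box, known_minimum, minimizer, noisy)
    "F1": (_f1, (-100.0, 100.0), 0.0, _zeros, False),
    "F2": (_f2, (-10.0, 10.0), 0.0, _zeros, False),
    "F3": (_f3, (-100.0, 100.0), 0.0, _zeros, False),
    "F4": (_f4, (-100.0, 100.0), 0.0, _zeros, False),
    "F5": (_f5, (-30.0, 30.0), 0.0, _ones, False),
    "F6": (_f6, (-100.0, 100.0), 0.0, _zeros, False),
    "F7": (_f7, (-1.28, 1.28), 0.0, _zeros, True),
    "F8": (_f8, (-500.0, 500.0), None, None, False),
    "F9": (_f9, (-5.12, 5.12), 0.0, _zeros, False),
    "F10": (_f10, (-32.0, 32.0), 0.0, _zeros, False),
    "F11": (_f11, (-600.0, 600.0), 0.0, _zeros, False),
    "F12": (_f12, (-50.0, 50.0), 0.0, _minus_ones, False),
    "F13": (_f13, (-50.0, 50.0), 0.0, _ones, False),
}


def get_benchmark(
    name: str, dimension: int = 50, schwefel_literal: bool = False
) -> BenchmarkFunction:
    """Look up a benchmark by name (``F1`` ... ``F13``).

    ``schwefel_literal=True`` selects the F8 variant without the inner square
    root, ``-x sin(|x|)``; the default keeps the conventional Schwefel-2.26
    form ``-x sin(sqrt(|x|))``.
    """
    key = name.upper()
    if key not in _CATALOG:
        raise KeyError(f"unknown benchmark {name!r}; known: {', '.join(FUNCTION_NAMES)}")
    expr, box, fmin, minimizer, noisy = _CATALOG[key]
    if key == "F8" and schwefel_literal:
        expr = _f8_literal
    return BenchmarkFunction(
        name=key,
        expression=expr,
        dimension=dimension,
        box=box,
        known_minimum=fmin,
        minimizer=minimizer,
        noisy=noisy,
    )


def benchmark_suite(dimension: int = 50) -> list[BenchmarkFunction]:
    """All thirteen functions at the given dimension."""
    return [get_benchmark(name, dimension) for name in FUNCTION_NAMES]


@dataclass
class SuiteReport:
    """Per-function mean/SD of final best fitness over repeated runs."""

    rows: list[dict]  # function, ave, sd, runs, dim, seeds, failures
    runs: int
    dimension: int
    base_seed: int

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(
                fh, fieldnames=["function", "ave", "sd", "runs", "dim"]
            )
            writer.writeheader()
            for row in self.rows:
                writer.writerow(
                    {k: row[k] for k in ("function", "ave", "sd", "runs", "dim")}
                )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "runs": self.runs,
                    "dimension": self.dimension,
                    "base_seed": self.base_seed,
                    "rows": self.rows,
                },
                fh,
                indent=1,
            )


def _derived_seed(base_seed: int, func_name: str, run: int) -> int:
    ss = np.random.SeedSequence((base_seed, int(func_name[1:]), run))
    return int(ss.generate_state(1)[0] % (2**31))


def run_suite(
    optimizer: Callable[..., object] = lstoa_optimize,
    functions: Sequence[BenchmarkFunction] = (),
    runs: int = 30,
    config: OptimizerConfig = None,
) -> SuiteReport:
    """Run ``optimizer`` on each function ``runs`` times and tabulate results.

    Each run gets an independent seed derived from ``config.seed``, the
    function index, and the run index, so the report is reproducible and any
    subset of functions yields the same per-function numbers.  A run that
    raises is recorded as a failed cell (NaN with a note), never silently
    dropped.  With ``runs == 1`` the SD is 0 by convention.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if config is None:
        raise ValueError("an OptimizerConfig template is required")
    rows = []
    for f in functions:
        values = []
        seeds = []
        failures = []
        for r in range(runs):
            seed = _derived_seed(config.seed, f.name, r)
            seeds.append(seed)
            run_cfg = OptimizerConfig(
                **{
                    **config.to_dict(),
                    "bounds": f.bounds,
                    "seed": seed,
                }
            )
            noise_rng = np.random.default_rng(seed + 1) if f.noisy else None
            objective = lambda x, _f=f, _rng=noise_rng: evaluate(_f, x, _rng)
            try:
                result = optimizer(objective, run_cfg)
                values.append(float(result.best_fitness))
            except Exception as exc:  # failed cell, recorded
                failures.append({"run": r, "seed": seed, "error": str(exc)})
                values.append(math.nan)
        clean = [v for v in values if not math.isnan(v)]
        if clean:
            ave = float(np.mean(clean))
            sd = 0.0 if len(clean) == 1 else float(np.std(clean, ddof=1))
        else:
            ave = math.nan
            sd = math.nan
        rows.append(
            {
                "function": f.name,
                "ave": ave,
                "sd": sd,
                "runs": runs,
                "dim": f.dimension,
                "seeds": seeds,
                "failures": failures,
            }
        )
    return SuiteReport(
        rows=rows,
        runs=runs,
        dimension=functions[0].dimension if functions else 0,
        base_seed=config.seed,
    )
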