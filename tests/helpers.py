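"""Independent oracles shared by the test modules.

These deliberately avoid the package's implementation paths: the edit
distance oracle is a naive exponential recursion, and the benchmark oracles
are plain-Python loop re-implementations of the published expressions.
"""

from __future__ import annotations

import functools
import math


@functools.lru_cache(maxsize=None)
def naive_edit_distance(a: str, b: str) -> int:
    """Levenshtein distance by plain recursion over the three edit moves."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    sub = naive_edit_distance(a[1:], b[1:]) + (a[0] != b[0])
    dele = naive_edit_distance(a[1:], b) + 1
    ins = naive_edit_distance(a, b[1:]) + 1
    return min(sub, dele, ins)


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def _u(x: float, a: float, k: float, m: float) -> float:
    if x > a:
        return k * (x - a) ** m
    if x < -a:
        return k * (-x - a) ** m
    return 0.0


def oracle_f1(x):
    return sum(v * v for v in x)


def oracle_f2(x):
    s = sum(abs(v) for v in x)
    p = 1.0
    for v in x:
        p *= abs(v)
    return s + p


def oracle_f3(x):
    total = 0.0
    for i in range(len(x)):
        inner = sum(x[j] for j in range(i + 1))
        total += inner * inner
    return total


def oracle_f4(x):
    return max(abs(v) for v in x)


def oracle_f5(x):
    total = 0.0
    for i in range(len(x) - 1):
        total += 100.0 * (x[i + 1] - x[i] ** 2) ** 2 + (x[i] - 1.0) ** 2
    return total


def oracle_f6(x):
    return sum(math.floor(v + 0.5) ** 2 for v in x)


def oracle_f7(x, noise=0.0):
    return sum((i + 1) * v**4 for i, v in enumerate(x)) + noise


def oracle_f8(x):
    return sum(-v * math.sin(math.sqrt(abs(v))) for v in x)


def oracle_f9(x):
    return sum(v * v - 10.0 * math.cos(2.0 * math.pi * v) + 10.0 for v in x)


def oracle_f10(x):
    n = len(x)
    q = sum(v * v for v in x) / n
    c = sum(math.cos(2.0 * math.pi * v) for v in x) / n
    return -20.0 * math.exp(-0.2 * math.sqrt(q)) - math.exp(c) + 20.0 + math.e


def oracle_f11(x):
    s = sum(v * v for v in x) / 4000.0
    p = 1.0
    for i, v in enumerate(x):
        p *= math.cos(v / math.sqrt(i + 1))
    return s - p + 1.0


def oracle_f12(x):
    n = len(x)
    y = [1.0 + (v + 1.0) / 4.0 for v in x]
    core = 10.0 * math.sin(math.pi * y[0]) ** 2
    for i in range(n - 1):
        core += (y[i] - 1.0) ** 2 * (1.0 + 10.0 * math.sin(math.pi * y[i + 1]) ** 2)
    core += (y[-1] - 1.0) ** 2
    return math.pi / n * core + sum(_u(v, 10.0, 100.0, 4) for v in x)


def oracle_f13(x):
    n = len(x)
    core = math.sin(3.0 * math.pi * x[0]) ** 2
    for i in range(n - 1):
        core += (x[i] - 1.0) ** 2 * (1.0 + math.sin(3.0 * math.pi * x[i + 1]) ** 2)
    core += (x[-1] - 1.0) ** 2 * (1.0 + math.sin(2.0 * math.pi * x[-1]) ** 2)
    return 0.1 * core


BENCHMARK_ORACLES = {
    "F1": oracle_f1,
    "F2": oracle_f2,
    "F3": oracle_f3,
    "F4": oracle_f4,
    "F5": oracle_f5,
    "F6": oracle_f6,
    "F7": oracle_f7,
    "F8": oracle_f8,
    "F9": oracle_f9,
    "F10": oracle_f10,
    "F11": oracle_f11,
    "F12": oracle_f12,
    "F13": oracle_f13,
}
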