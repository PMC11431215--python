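"""JIT-compiled Levenshtein kernels for the set builder's inner loop.

The incremental builder evaluates millions of codeword-vs-set distance sums;
these numba kernels keep that affordable.  They operate on uint8-encoded
codewords (A=0, C=1, G=2, T=3).  The public API in :mod:`sterncode.constraints`
and the set validator use an independent implementation (edlib), so the
builder's fast path never certifies its own output.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_TO_BASE = np.array(list("ACGT"))


def encode(word: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 vector."""
    return np.fromiter((_BASE_TO_CODE[c] for c in word), dtype=np.uint8, count=len(word))


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 vector back to an ACGT string."""
    return "".join(_CODE_TO_BASE[codes])


@njit(cache=True)
def levenshtein(a: np.ndarray, b: np.ndarray) -> int:
    """Unit-cost Levenshtein distance between two encoded words."""
    la, lb = len(a), len(b)
    prev = np.arange(lb + 1, dtype=np.int64)
    cur = np.empty(lb + 1, dtype=np.int64)
    for i in range(1, la + 1):
        cur[0] = i
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ai == b[j - 1] else 1
            best = prev[j - 1] + cost
            if prev[j] + 1 < best:
                best = prev[j] + 1
            if cur[j - 1] + 1 < best:
                best = cur[j - 1] + 1
            cur[j] = best
        prev, cur = cur, prev
    return prev[lb]


@njit(cache=True)
def distance_sum(word: np.ndarray, members: np.ndarray, count: int) -> int:
    """Sum of Levenshtein distances from ``word`` to the first ``count`` rows."""
    total = 0
    for k in range(count):
        total += levenshtein(word, members[k])
    return total


@njit(cache=True)
def batch_eval(
    cand: np.ndarray,
    members: np.ndarray,
    count: int,
    d: int,
    gc_lo: int,
    gc_hi: int,
    nrl: int,
    weight: float,
    sign: float,
):
    """Penalized search score and admissibility for a batch of candidates.

    ``cand`` is a (k, n) uint8 matrix of encoded candidates; ``members`` the
    encoded current set (first ``count`` rows).  The score is
    ``sign * sum_of_distances - weight * violation`` where violation counts
    G+C excess/shortfall against the integer count window [gc_lo, gc_hi],
    adjacent repeats (when ``nrl``), duplicate membership, and the
    minimum-distance shortfall below ``d``.  A candidate is admissible when
    it has no violation.
    """
    k, n = cand.shape
    fitness = np.empty(k, dtype=np.float64)
    admissible = np.zeros(k, dtype=np.uint8)
    for i in range(k):
        row = cand[i]
        violation = 0.0
        gc = 0
        for j in range(n):
            if row[j] == 1 or row[j] == 2:  # C or G
                gc += 1
        if gc < gc_lo:
            violation += gc_lo - gc
        elif gc > gc_hi:
            violation += gc - gc_hi
        if nrl:
            for j in range(n - 1):
                if row[j] == row[j + 1]:
                    violation += 1.0
        dist_sum = 0.0
        if count > 0:
            min_dist = 1 << 30
            for m in range(count):
                dist = levenshtein(row, members[m])
                dist_sum += dist
                if dist < min_dist:
                    min_dist = dist
            if min_dist == 0:
                violation += 1.0
            elif min_dist < d:
                violation += d - min_dist
        fitness[i] = sign * dist_sum - weight * violation
        if violation == 0.0:
            admissible[i] = 1
    return fitness, admissible


@njit(cache=True)
def count_compatible(word: np.ndarray, pool: np.ndarray, d: int) -> int:
    """How many pool rows sit at Levenshtein distance >= d from ``word``."""
    total = 0
    for i in range(pool.shape[0]):
        if levenshtein(word, pool[i]) >= d:
            total += 1
    return total


@njit(cache=True)
def min_distance(word: np.ndarray, members: np.ndarray, count: int) -> int:
    """Minimum Levenshtein distance from ``word`` to the first ``count`` rows.

    Returns a large sentinel (2**30) when ``count`` is zero.
    """
    best = 1 << 30
    for k in range(count):
        dist = levenshtein(word, members[k])
        if dist < best:
            best = dist
            if best == 0:
                return 0
    return best
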