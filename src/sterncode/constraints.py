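"""Validity predicates and distance functions for DNA storage codewords.

A codeword is a fixed-length string over the alphabet {A, C, G, T}.  A coding
set is useful for addressing in a random-access DNA storage pool when every
member individually keeps a balanced GC content and avoids homopolymer runs,
and every pair of members is separated by a minimum Levenshtein (edit)
distance so that synthesis/sequencing errors cannot turn one address into
another.

This module defines the per-codeword predicates (GC window, no-runlength),
the pairwise edit distance, the set-level minimum distance, an optional
prefix/suffix "uncorrelated address" predicate, and an independent validator
for whole coding sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib

DNA_ALPHABET = "ACGT"

#: Sentinel returned by :func:`min_pairwise_edit_distance` for sets with
#: fewer than two members: any minimum-distance requirement holds vacuously.
INF_DISTANCE = math.inf


class CodewordError(ValueError):
    """A string is not a well-formed DNA codeword."""


def canonical_codeword(seq: str) -> str:
    """Uppercase a codeword and verify it is a non-empty string over ACGT.

    Lowercase input is folded to uppercase (FASTA dialect tolerance).
    Raises :class:`CodewordError` naming the first offending position.
    """
    if not seq:
        raise CodewordError("empty codeword (length-zero string)")
    up = seq.upper()
    for i, ch in enumerate(up):
        if ch not in DNA_ALPHABET:
            raise CodewordError(
                f"invalid character {seq[i]!r} at position {i}: "
                f"codewords are strings over {{A,C,G,T}}"
            )
    return up


@dataclass(frozen=True)
class ConstraintProfile:
    """Constraint bundle defining which codewords and sets are admissible.

    Parameters
    ----------
    n : int
        Codeword length.
    d : int
        Minimum pairwise edit distance required within a set, ``1 <= d <= n``.
    gc_low, gc_high : float
        Inclusive GC-content window as fractions; the conventional
        recommendation for stable, uniform-melting sequences is 40-60%.
    no_runlength : bool
        If true, adjacent identical bases are forbidden (homopolymer-free).
    uncorrelated_address : bool
        If true, the set-level prefix/suffix overlap predicate
        (:func:`uncorrelated_address`) is enforced by the validator.  The
        exact predicate is an interpretation; see its docstring.
    """

    n: int
    d: int
    gc_low: float = 0.40
    gc_high: float = 0.60
    no_runlength: bool = True
    uncorrelated_address: bool = False

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"codeword length n must be positive, got {self.n}")
        if not 1 <= self.d <= self.n:
            raise ValueError(f"need 1 <= d <= n, got d={self.d}, n={self.n}")
        if not 0.0 <= self.gc_low <= self.gc_high <= 1.0:
            raise ValueError(
                f"GC window must satisfy 0 <= gc_low <= gc_high <= 1, "
                f"got [{self.gc_low}, {self.gc_high}]"
            )

    @property
    def gc_midpoint(self) -> float:
        """Midpoint of the GC window (0.5 for the default balanced window)."""
        return 0.5 * (self.gc_low + self.gc_high)


def gc_content(x: str) -> float:
    """Fraction of G and C bases in ``x`` (in [0, 1])."""
    x = canonical_codeword(x)
    return (x.count("G") + x.count("C")) / len(x)


def satisfies_gc(x: str, profile: ConstraintProfile) -> bool:
    """True iff ``gc_low <= GC(x) <= gc_high`` (both bounds inclusive)."""
    return profile.gc_low <= gc_content(x) <= profile.gc_high


def no_runlength(x: str) -> bool:
    """True iff no two adjacent bases of ``x`` are equal.

    Homopolymer runs (e.g. the "AAAA" in "TAAAATCG") are misread as runs of
    the wrong length during synthesis and nanopore sequencing, so
    homopolymer-free codewords are preferred for addresses.
    """
    x = canonical_codeword(x)
    return all(a != b for a, b in zip(x, x[1:]))


def edit_distance(m: str, n: str) -> int:
    """Levenshtein distance between two DNA strings (unit-cost global).

    Minimum number of insertions, deletions and substitutions converting one
    string into the other.  Unequal lengths are allowed.  Symmetric, zero iff
    the strings are identical, and satisfies the triangle inequality.
    """
    m = canonical_codeword(m)
    n = canonical_codeword(n)
    return edlib.align(m, n, mode="NW", task="distance")["editDistance"]


def min_pairwise_edit_distance(S: Iterable[str]) -> float:
    """Minimum edit distance over all unordered distinct pairs of ``S``.

    For fewer than two members returns :data:`INF_DISTANCE`, so singleton
    and empty sets vacuously satisfy any minimum-distance requirement.
    """
    words = [canonical_codeword(w) for w in S]
    if len(words) < 2:
        return INF_DISTANCE
    best = INF_DISTANCE
    for i in range(len(words)):
        for j in range(i + 1, len(words)):
            dist = edlib.align(words[i], words[j], mode="NW", task="distance")[
                "editDistance"
            ]
            if dist < best:
                best = dist
                if best == 0:
                    return 0
    return best


def uncorrelated_address(S: Iterable[str]) -> bool:
    """Prefix/suffix non-overlap across all ordered pairs, self-pairs included.

    Default interpretation of the "uncorrelated address" set property: for
    every ordered pair ``(x, y)`` (including ``x == y``) no proper prefix of
    ``x`` of length ``k`` (``1 <= k < n``) equals the length-``k`` suffix of
    ``y``.  This prevents two addresses (or one address with itself) from
    forming spurious overlaps when fragments concatenate in the pool.

    The predicate is a *strategy point*: alternative readings (exclude
    self-pairs, require a minimum overlap length) can be passed to
    :func:`validate_code_set` via ``ua_predicate``.
    """
    words = [canonical_codeword(w) for w in S]
    for x in words:
        for y in words:
            for k in range(1, min(len(x), len(y))):
                if x[:k] == y[-k:]:
                    return False
    return True


def is_valid_codeword(x: str, profile: ConstraintProfile) -> bool:
    """Per-codeword admissibility: GC window and (if enabled) no-runlength.

    Set-level requirements (minimum pairwise distance, uncorrelated-address)
    are deliberately *not* checked here; see :func:`validate_code_set`.
    """
    x = canonical_codeword(x)
    if len(x) != profile.n:
        return False
    if not satisfies_gc(x, profile):
        return False
    if profile.no_runlength and not no_runlength(x):
        return False
    return True


@dataclass
class Violation:
    """One violated constraint, naming the offending codeword(s)."""

    constraint: str
    codewords: tuple[str, ...]
    detail: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"[{self.constraint}] {', '.join(self.codewords)}: {self.detail}"


@dataclass
class ValidationReport:
    """Outcome of validating a coding set against a profile."""

    valid: bool
    profile: ConstraintProfile
    size: int
    min_distance: float
    violations: list[Violation] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "valid": self.valid,
            "n": self.profile.n,
            "d": self.profile.d,
            "gc_window": [self.profile.gc_low, self.profile.gc_high],
            "size": self.size,
            "min_distance": (
                None if math.isinf(self.min_distance) else int(self.min_distance)
            ),
            "violations": [
                {
                    "constraint": v.constraint,
                    "codewords": list(v.codewords),
                    "detail": v.detail,
                }
                for v in self.violations
            ],
        }

    def summary(self) -> str:
        lines = [
            f"coding set: {self.size} codewords, profile n={self.profile.n} "
            f"d={self.profile.d} GC=[{self.profile.gc_low:.2f},{self.profile.gc_high:.2f}] "
            f"NRL={'on' if self.profile.no_runlength else 'off'} "
            f"UA={'on' if self.profile.uncorrelated_address else 'off'}",
            f"verdict: {'VALID' if self.valid else 'INVALID'}",
        ]
        if self.size == 0:
            lines.append("note: empty set is vacuously valid")
        for v in self.violations:
            lines.append(f"  violation {v}")
        return "\n".join(lines)


def validate_code_set(
    S: Sequence[str],
    profile: ConstraintProfile,
    ua_predicate=None,
) -> ValidationReport:
    """Independently validate a whole coding set against ``profile``.

    Checks every codeword with :func:`is_valid_codeword`, the set-level
    minimum pairwise edit distance against ``profile.d``, duplicates, and
    (when enabled) the uncorrelated-address predicate.  This validator is a
    deliberate second opinion: it shares no code with the incremental checks
    used while a set is being grown.

    Malformed input raises :class:`CodewordError` naming the position.
    """
    words = [canonical_codeword(w) for w in S]
    violations: list[Violation] = []

    for w in words:
        if len(w) != profile.n:
            violations.append(
                Violation("length", (w,), f"length {len(w)} != n={profile.n}")
            )
            continue
        if not satisfies_gc(w, profile):
            violations.append(
                Violation(
                    "gc_content",
                    (w,),
                    f"GC={gc_content(w):.3f} outside "
                    f"[{profile.gc_low}, {profile.gc_high}]",
                )
            )
        if profile.no_runlength and not no_runlength(w):
            violations.append(
                Violation("no_runlength", (w,), "adjacent identical bases")
            )

    seen: dict[str, int] = {}
    for w in words:
        seen[w] = seen.get(w, 0) + 1
    for w, cnt in seen.items():
        if cnt > 1:
            violations.append(Violation("duplicate", (w,), f"appears {cnt} times"))

    min_dist = min_pairwise_edit_distance(words)
    if min_dist < profile.d:
        offenders = _closest_pair(words)
        violations.append(
            Violation(
                "min_edit_distance",
                offenders,
                f"minimum pairwise distance {int(min_dist)} < d={profile.d}",
            )
        )

    if profile.uncorrelated_address:
        pred = ua_predicate if ua_predicate is not None else uncorrelated_address
        if not pred(words):
            violations.append(
                Violation(
                    "uncorrelated_address",
                    tuple(words),
                    "prefix/suffix overlap between members",
                )
            )

    return ValidationReport(
        valid=not violations,
        profile=profile,
        size=len(words),
        min_distance=min_dist,
        violations=violations,
    )


def _closest_pair(words: Sequence[str]) -> tuple[str, ...]:
    best: tuple[str, ...] = ()
    best_d = INF_DISTANCE
    for i in range(len(words)):
        for j in range(i + 1, len(words)):
            dist = edlib.align(words[i], words[j], mode="NW", task="distance")[
                "editDistance"
            ]
            if dist < best_d:
                best_d = dist
                best = (words[i], words[j])
    return best
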