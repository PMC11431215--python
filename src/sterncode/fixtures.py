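"""Random constraint-satisfying codewords for seeding tests and examples."""

from __future__ import annotations

import numpy as np

from .codeset import enumerate_valid_codewords, profile_is_feasible
from .constraints import ConstraintProfile, is_valid_codeword

_ENUMERATE_BELOW_N = 9  # 4^8 = 65536 strings is still cheap to enumerate


def generate_fixture(
    profile: ConstraintProfile, count: int, seed: int
) -> list[str]:
    """Return ``count`` distinct random codewords valid under ``profile``.

    Pairwise distance is deliberately *not* enforced — these are unit-test
    seeds, not coding sets.  For small ``n`` the valid words are enumerated
    and sampled without replacement (so an over-large ``count`` is detected
    exactly); for larger ``n`` rejection sampling is used.

    Raises ``ValueError`` when the profile is infeasible or cannot supply
    ``count`` distinct words.
    """
    if count < 1:
        raise ValueError("count must be >= 1")
    if not profile_is_feasible(profile):
        raise ValueError(
            f"infeasible profile: GC window [{profile.gc_low}, {profile.gc_high}] "
            f"admits no integer G+C count for n={profile.n}"
        )
    rng = np.random.default_rng(seed)

    if profile.n < _ENUMERATE_BELOW_N:
        pool = enumerate_valid_codewords(profile)
        if len(pool) < count:
            raise ValueError(
                f"profile admits only {len(pool)} valid codewords, "
                f"cannot supply {count} distinct ones"
            )
        picks = rng.choice(len(pool), size=count, replace=False)
        return [pool[i] for i in sorted(picks)]

    words: set[str] = set()
    attempts = 0
    max_attempts = 10_000 * count
    while len(words) < count:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not sample {count} distinct valid codewords in "
                f"{max_attempts} attempts (profile too restrictive)"
            )
        idx = rng.integers(0, 4, size=profile.n)
        word = "".join("ACGT"[i] for i in idx)
        attempts += 1
        if is_valid_codeword(word, profile):
            words.add(word)
    return sorted(words)
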