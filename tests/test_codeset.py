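"""Position decoding, the set objective, the builder, and the exact oracle."""

import itertools
import math

import numpy as np
import pytest

from sterncode import (
    BuilderConfig,
    ConstraintProfile,
    InfeasibleProfileError,
    build_code_set,
    code_rate,
    enumerate_valid_codewords,
    exact_max_code_set,
    position_to_codeword,
    set_fitness,
)
from sterncode.codeset import codeword_to_position, profile_is_feasible

from helpers import naive_edit_distance

FAST = dict(population=1024, iterations=1, candidate_budget=5, restarts=3)


class TestDecoding:
    def test_examples(self):
        assert position_to_codeword([0.2, 1.7, 2.9, 3.99]) == "ACGT"
        assert position_to_codeword([4.0, 4.0]) == "TT"

    def test_round_trip_all_length_4_codewords(self):
        for tup in itertools.product("ACGT", repeat=4):
            word = "".join(tup)
            assert position_to_codeword(codeword_to_position(word)) == word

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            position_to_codeword([0.5, float("nan")])


class TestCodeRate:
    def test_boundary_values(self):
        assert code_rate(1, 5) == 0.0
        assert code_rate(4**7, 7) == pytest.approx(1.0)

    def test_table_sized_example(self):
        # log4(101)/8; equals half the per-bit reading log2(101)/8 ~ 0.832
        assert code_rate(101, 8) == pytest.approx(math.log(101, 4) / 8)
        assert code_rate(101, 8) == pytest.approx(0.4162, abs=5e-4)

    def test_invalid_size_rejected(self):
        with pytest.raises(ValueError):
            code_rate(0, 4)


class TestSetFitness:
    def test_single_pair_distance_sum(self):
        profile = ConstraintProfile(
            n=4, d=1, gc_low=0.0, gc_high=1.0, no_runlength=False
        )
        assert set_fitness("TTTT", ["AAAA"], profile) == pytest.approx(4.0)

    def test_empty_set_valid_word_scores_zero(self):
        profile = ConstraintProfile(n=4, d=2)
        assert set_fitness("ACGT", [], profile) == pytest.approx(0.0)

    def test_penalties_dominate_distance_sum(self):
        profile = ConstraintProfile(n=4, d=2)
        # "TTTT" violates GC (0 G/C, needs 2) and runlength (3 repeats)
        assert set_fitness("TTTT", ["ACGT"], profile) < 0.0
        # duplicate membership is penalized below any admissible score
        assert set_fitness("ACGT", ["ACGT"], profile) < 0.0

    def test_distance_sum_matches_explicit_loop(self, rng):
        profile = ConstraintProfile(
            n=6, d=1, gc_low=0.0, gc_high=1.0, no_runlength=False
        )
        bases = "ACGT"
        members = [
            "".join(bases[i] for i in rng.integers(0, 4, size=6)) for _ in range(5)
        ]
        members = list(dict.fromkeys(members))
        s = "ACGTAC"
        expected = sum(naive_edit_distance(s, m) for m in members)
        if s not in members and min(
            naive_edit_distance(s, m) for m in members
        ) >= 1:
            assert set_fitness(s, members, profile) == pytest.approx(expected)


class TestBuilder:
    def test_reaches_known_size_n4_d3(self):
        cs = build_code_set(
            ConstraintProfile(n=4, d=3), BuilderConfig(seed=1, **FAST)
        )
        assert cs.size >= 6
        assert cs.validate().valid

    def test_output_always_passes_independent_validator(self):
        for n, d in [(4, 2), (5, 3), (6, 4)]:
            cs = build_code_set(
                ConstraintProfile(n=n, d=d), BuilderConfig(seed=3, **FAST)
            )
            assert cs.validate().valid
            assert len(set(cs.codewords)) == cs.size

    def test_d1_recovers_every_valid_codeword(self):
        profile = ConstraintProfile(n=4, d=1)
        cs = build_code_set(profile, BuilderConfig(seed=0, **FAST))
        assert cs.size == len(enumerate_valid_codewords(profile))

    def test_deterministic_for_fixed_config(self):
        cfg = BuilderConfig(seed=11, **FAST)
        a = build_code_set(ConstraintProfile(n=5, d=3), cfg)
        b = build_code_set(ConstraintProfile(n=5, d=3), cfg)
        assert a.codewords == b.codewords

    def test_size_monotone_in_restarts(self):
        profile = ConstraintProfile(n=5, d=3)
        sizes = []
        for restarts in (1, 2, 4):
            cfg = BuilderConfig(
                seed=7,
                population=1024,
                iterations=1,
                candidate_budget=5,
                restarts=restarts,
            )
            sizes.append(build_code_set(profile, cfg).size)
        assert sizes == sorted(sizes)

    def test_infeasible_profile_raises(self):
        profile = ConstraintProfile(n=4, d=1, gc_low=0.1, gc_high=0.2)
        assert not profile_is_feasible(profile)
        with pytest.raises(InfeasibleProfileError):
            build_code_set(profile, BuilderConfig(seed=0, **FAST))

    def test_random_engine_obeys_same_admission_rule(self):
        cfg = BuilderConfig(seed=5, engine="random", **FAST)
        cs = build_code_set(ConstraintProfile(n=5, d=3), cfg)
        assert cs.validate().valid
        assert cs.provenance["engine"] == "random"

    def test_spread_guide_still_yields_valid_sets(self):
        cfg = BuilderConfig(seed=5, guide="spread", **FAST)
        cs = build_code_set(ConstraintProfile(n=5, d=3), cfg)
        assert cs.validate().valid

    def test_ua_constraint_enforced_when_enabled(self):
        profile = ConstraintProfile(n=4, d=2, uncorrelated_address=True)
        cs = build_code_set(profile, BuilderConfig(seed=2, **FAST))
        assert cs.validate().valid  # validator re-checks UA

    def test_provenance_records_run(self, tmp_path):
        cfg = BuilderConfig(seed=9, **FAST)
        cs = build_code_set(ConstraintProfile(n=4, d=3), cfg)
        assert cs.provenance["seed"] == 9
        assert len(cs.provenance["restart_sizes"]) == cfg.restarts
        cs.to_json(tmp_path / "set.json")
        assert (tmp_path / "set.json").exists()
        assert cs.rate == pytest.approx(code_rate(cs.size, 4))


class TestExactOracle:
    def test_complete_graph_when_d1(self):
        profile = ConstraintProfile(n=4, d=1)
        oracle = exact_max_code_set(profile)
        assert oracle.size == len(enumerate_valid_codewords(profile))

    def test_known_maximum_n4_d3(self):
        assert exact_max_code_set(ConstraintProfile(n=4, d=3)).size == 6

    def test_relaxing_d_never_shrinks_maximum(self):
        sizes = {
            d: exact_max_code_set(ConstraintProfile(n=4, d=d)).size
            for d in (1, 2, 3, 4)
        }
        assert sizes[1] >= sizes[2] >= sizes[3] >= sizes[4]

    def test_degenerate_limit_all_words(self):
        profile = ConstraintProfile(
            n=3, d=1, gc_low=0.0, gc_high=1.0, no_runlength=False
        )
        assert exact_max_code_set(profile).size == 4**3

    def test_oracle_at_least_heuristic(self):
        for d in (3, 4):
            profile = ConstraintProfile(n=4, d=d)
            oracle = exact_max_code_set(profile)
            heur = build_code_set(profile, BuilderConfig(seed=1, **FAST))
            assert oracle.size >= heur.size
            assert oracle.validate().valid

    def test_ua_variant_is_validator_clean(self):
        profile = ConstraintProfile(n=4, d=2, uncorrelated_address=True)
        oracle = exact_max_code_set(profile)
        assert oracle.validate().valid

    def test_guard_refuses_large_n(self):
        with pytest.raises(ValueError, match="n <= 6"):
            exact_max_code_set(ConstraintProfile(n=7, d=3))
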