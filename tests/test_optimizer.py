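"""STOA/LSTOA update rules, Levy steps, and whole-run behaviour."""

import dataclasses
import math

import numpy as np
import pytest

from sterncode import (
    OptimizerConfig,
    levy_step,
    lstoa_optimize,
    migrate,
    sa_schedule,
    spiral_attack,
)


def make_config(**kw):
    defaults = dict(
        bounds=((-100.0, 100.0),) * 2,
        population=30,
        max_iterations=100,
        seed=0,
    )
    defaults.update(kw)
    return OptimizerConfig(**defaults)


def sphere(x):
    return float(np.sum(np.asarray(x) ** 2))


class TestSchedule:
    def test_endpoints_and_midpoint(self):
        cfg = make_config(cf=2.0, max_iterations=100)
        assert sa_schedule(0, cfg) == pytest.approx(2.0)
        assert sa_schedule(100, cfg) == pytest.approx(0.0)
        assert sa_schedule(50, cfg) == pytest.approx(1.0)

    def test_linearly_decreasing(self):
        cfg = make_config(cf=3.0, max_iterations=10)
        vals = [sa_schedule(z, cfg) for z in range(11)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_out_of_range_rejected(self):
        cfg = make_config(max_iterations=10)
        with pytest.raises(ValueError):
            sa_schedule(11, cfg)
        with pytest.raises(ValueError):
            sa_schedule(-1, cfg)


class TestMigrate:
    def test_collapses_at_best_position_on_final_iteration(self):
        cfg = make_config(max_iterations=50)
        rng = np.random.default_rng(1)
        best = np.array([1.0, -2.0])
        c, m, d = migrate(best.copy(), best, 50, cfg, rng)
        assert np.allclose(c, 0.0) and np.allclose(m, 0.0) and np.allclose(d, 0.0)

    def test_cb_bounded_by_half(self):
        cfg = make_config()
        rng = np.random.default_rng(2)
        pos = np.array([2.0, 2.0])
        best = np.array([4.0, 4.0])
        for z in range(50):
            _, m, _ = migrate(pos, best, 1, cfg, rng)
            cb = m[0] / (best - pos)[0]
            assert 0.0 <= cb <= 0.5

    def test_deterministic_under_fixed_seed(self):
        cfg = make_config()
        a = migrate(np.ones(2), np.zeros(2), 3, cfg, np.random.default_rng(7))
        b = migrate(np.ones(2), np.zeros(2), 3, cfg, np.random.default_rng(7))
        for x, y in zip(a, b):
            assert np.array_equal(x, y)


class TestSpiralAttack:
    def test_zero_best_yields_zero_position(self):
        cfg = make_config()
        out = spiral_attack(np.ones(2), np.zeros(2), np.random.default_rng(0), cfg)
        assert np.allclose(out, 0.0)

    def test_reproducible(self):
        cfg = make_config()
        a = spiral_attack(np.ones(3), np.ones(3), np.random.default_rng(5), cfg)
        b = spiral_attack(np.ones(3), np.ones(3), np.random.default_rng(5), cfg)
        assert np.array_equal(a, b)


class TestLevyStep:
    def test_symmetric_around_zero(self):
        rng = np.random.default_rng(11)
        steps = np.array([levy_step(1, 1.5, rng)[0] for _ in range(100_000)])
        se = steps.std() / math.sqrt(len(steps))
        assert abs(steps.mean()) < 3 * se

    def test_tail_index_near_beta(self):
        """Hill estimator on the top 1% of |step| should bracket beta=1.5."""
        rng = np.random.default_rng(13)
        steps = np.abs(np.array([levy_step(1, 1.5, rng)[0] for _ in range(100_000)]))
        top = np.sort(steps)[-1000:]
        hill = 1.0 / np.mean(np.log(top[1:] / top[0]))
        assert 1.2 <= hill <= 1.8

    def test_beta_out_of_range_rejected(self):
        rng = np.random.default_rng(0)
        for beta in (0.0, -1.0, 2.5):
            with pytest.raises(ValueError):
                levy_step(3, beta, rng)

    def test_fixed_seed_reproducible(self):
        a = levy_step(5, 1.5, np.random.default_rng(3))
        b = levy_step(5, 1.5, np.random.default_rng(3))
        assert np.array_equal(a, b)


class TestLstoaRun:
    def test_constant_objective_gives_flat_history(self):
        cfg = make_config(max_iterations=20)
        res = lstoa_optimize(lambda x: 7.25, cfg)
        assert res.best_fitness == 7.25
        assert np.all(res.history == 7.25)

    def test_sphere_2d_converges(self):
        cfg = make_config(max_iterations=500)
        res = lstoa_optimize(sphere, cfg)
        assert res.best_fitness <= 1e-6

    def test_history_is_monotone_non_increasing(self):
        cfg = make_config(max_iterations=150, seed=4)
        res = lstoa_optimize(sphere, cfg)
        assert np.all(np.diff(res.history) <= 0)

    def test_bit_identical_repeat_runs(self):
        cfg = make_config(max_iterations=80, seed=9)
        a = lstoa_optimize(sphere, cfg)
        b = lstoa_optimize(sphere, cfg)
        assert np.array_equal(a.history, b.history)
        assert np.array_equal(a.best_position, b.best_position)

    def test_positions_respect_bounds(self):
        seen = []

        def probe(x):
            seen.append(np.asarray(x).copy())
            return sphere(x)

        cfg = make_config(max_iterations=60, seed=2, bounds=((-1.0, 2.0), (0.5, 3.0)))
        lstoa_optimize(probe, cfg)
        arr = np.stack(seen)
        assert arr[:, 0].min() >= -1.0 and arr[:, 0].max() <= 2.0
        assert arr[:, 1].min() >= 0.5 and arr[:, 1].max() <= 3.0

    def test_levy_start_one_is_plain_stoa_and_beta_is_dead(self):
        base = make_config(max_iterations=120, seed=6, levy_start_fraction=1.0)
        h1 = lstoa_optimize(sphere, base).history
        h2 = lstoa_optimize(
            sphere, dataclasses.replace(base, levy_beta=1.1)
        ).history
        assert np.array_equal(h1, h2)

    def test_levy_phase_changes_trajectory(self):
        def record(store):
            def f(x):
                store.append(np.asarray(x).copy())
                return sphere(x)

            return f

        on_pts, off_pts = [], []
        on = make_config(max_iterations=120, seed=6, levy_start_fraction=0.1)
        off = make_config(max_iterations=120, seed=6, levy_start_fraction=1.0)
        lstoa_optimize(record(on_pts), on)
        lstoa_optimize(record(off_pts), off)
        assert not np.array_equal(np.stack(on_pts), np.stack(off_pts))

    def test_convergence_trend_with_doubling_budget(self):
        finals = {}
        for iters in (50, 100):
            vals = []
            for seed in range(10):
                cfg = make_config(max_iterations=iters, seed=seed)
                vals.append(lstoa_optimize(sphere, cfg).best_fitness)
            finals[iters] = float(np.median(vals))
        assert finals[100] <= finals[50]

    def test_best_fitness_reevaluates_at_best_position(self):
        cfg = make_config(max_iterations=60, seed=8)
        res = lstoa_optimize(sphere, cfg)
        assert res.best_fitness == pytest.approx(sphere(res.best_position))

    def test_nonfinite_objective_aborts_with_diagnostic(self):
        cfg = make_config(max_iterations=10)
        with pytest.raises(RuntimeError, match="non-finite"):
            lstoa_optimize(lambda x: float("nan"), cfg)

    def test_static_penalty_steers_away_from_violations(self):
        # minimize sphere subject to x0 >= 1 (violation = 1 - x0)
        cfg = make_config(max_iterations=300, seed=1)
        res = lstoa_optimize(
            sphere, cfg, constraints=[lambda x: 1.0 - x[0]]
        )
        assert res.best_position[0] >= 1.0 - 1e-6

    def test_vectorized_objective_runs_and_respects_contracts(self):
        cfg = make_config(max_iterations=100, seed=3)
        res = lstoa_optimize(
            lambda block: np.sum(block**2, axis=1), cfg, vectorized=True
        )
        res2 = lstoa_optimize(
            lambda block: np.sum(block**2, axis=1), cfg, vectorized=True
        )
        assert np.all(np.diff(res.history) <= 0)
        assert np.array_equal(res.history, res2.history)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(population=1),
            dict(cf=0.0),
            dict(levy_beta=0.0),
            dict(levy_beta=2.2),
            dict(levy_start_fraction=1.5),
            dict(max_iterations=0),
            dict(bounds=()),
            dict(bounds=((1.0, -1.0),)),
        ],
    )
    def test_bad_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            make_config(**kw)

    def test_result_serializes_to_json(self, tmp_path):
        cfg = make_config(max_iterations=10)
        res = lstoa_optimize(sphere, cfg)
        out = tmp_path / "run.json"
        res.to_json(out)
        assert out.exists() and '"best_fitness"' in out.read_text()
        res.history_csv(tmp_path / "h.csv")
        lines = (tmp_path / "h.csv").read_text().splitlines()
        assert lines[0] == "iteration,best_fitness" and len(lines) == 12
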