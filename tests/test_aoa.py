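"""The population metaheuristic: schedules, updates, full optimization."""

import math

import numpy as np
import pytest

from aoadl import aoa
from aoadl.errors import ObjectiveError, ParameterError


def make_config(**kw):
    defaults = dict(population=5, max_iterations=10,
                    lower=np.array([-1.0, -1.0]), upper=np.array([1.0, 1.0]),
                    seed=7)
    defaults.update(kw)
    return aoa.AOAConfig(**defaults)


class TestInitialization:
    def test_degenerate_bounds_collapse_to_point(self, rng):
        cfg = make_config(lower=np.zeros(2), upper=np.zeros(2))
        pop = aoa.initialize_population(cfg, rng)
        for obj in pop:
            assert np.array_equal(obj.x, np.zeros(2))

    def test_seeded_determinism(self):
        cfg = make_config()
        p1 = aoa.initialize_population(cfg, np.random.default_rng(7))
        p2 = aoa.initialize_population(cfg, np.random.default_rng(7))
        for a, b in zip(p1, p2):
            assert np.array_equal(a.x, b.x)
            assert np.array_equal(a.density, b.density)

    def test_positions_uniform_in_bounds(self):
        cfg = make_config(population=1000, lower=np.array([0.0]),
                          upper=np.array([1.0]))
        pop = aoa.initialize_population(cfg, np.random.default_rng(0))
        xs = np.array([o.x[0] for o in pop])
        assert abs(xs.mean() - 0.5) < 0.05
        assert xs.min() >= 0 and xs.max() <= 1

    def test_small_population_rejected(self):
        with pytest.raises(ParameterError):
            make_config(population=1)


class TestSchedules:
    def test_transfer_operator_reaches_one_at_tmax(self):
        for tmax in (1, 10, 100):
            assert aoa.transfer_operator(tmax, tmax) == 1.0

    def test_transfer_operator_closed_form(self):
        assert math.isclose(aoa.transfer_operator(0, 100), math.exp(-1))
        assert math.isclose(aoa.transfer_operator(50, 100), math.exp(-0.5))

    def test_density_decrease_closed_form(self):
        assert aoa.density_decrease(100, 100) == 0.0
        assert math.isclose(aoa.density_decrease(0, 100), math.e)
        assert math.isclose(aoa.density_decrease(50, 100), math.exp(0.5) - 0.5)

    def test_monotonicity_and_single_crossing(self):
        tmax = 200
        tf = [aoa.transfer_operator(t, tmax) for t in range(tmax + 1)]
        d = [aoa.density_decrease(t, tmax) for t in range(tmax + 1)]
        assert all(a < b for a, b in zip(tf, tf[1:]))
        assert all(a > b for a, b in zip(d, d[1:]))
        signs = [np.sign(a - b) for a, b in zip(tf, d)]
        crossings = sum(1 for s1, s2 in zip(signs, signs[1:]) if s1 != s2 and s2 != 0 or (s1 != s2 and s1 != 0))
        # they cross exactly once inside (0, tmax)
        assert sum(1 for s1, s2 in zip(signs, signs[1:]) if s1 < s2) == 1

    def test_out_of_range_iteration_rejected(self):
        with pytest.raises(ParameterError):
            aoa.transfer_operator(11, 10)
        with pytest.raises(ParameterError):
            aoa.density_decrease(-1, 10)


class TestDensityVolumeUpdate:
    def _best(self):
        return aoa.BestRecord(np.zeros(1), np.array([0.8]), np.array([0.8]),
                              np.zeros(1), 0.0, 1)

    def test_at_best_unchanged(self, rng):
        obj = aoa.ObjectState(np.zeros(1), np.array([0.8]), np.array([0.8]), np.zeros(1))
        aoa.update_density_volume(obj, self._best(), rng)
        assert np.allclose(obj.volume, 0.8)

    def test_forced_full_and_half_steps(self, forced_rng):
        for forced, expected in ((1.0, 0.8), (0.5, 0.5)):
            obj = aoa.ObjectState(np.zeros(1), np.array([0.2]), np.array([0.2]), np.zeros(1))
            aoa.update_density_volume(obj, self._best(), forced_rng(forced))
            assert np.allclose(obj.volume, expected)
            assert np.allclose(obj.density, expected)

    def test_stays_between_old_and_best(self, rng):
        best = self._best()
        for _ in range(50):
            v0 = rng.random(3)
            obj = aoa.ObjectState(np.zeros(3), v0.copy(), v0.copy(), np.zeros(3))
            aoa.update_density_volume(obj, best, rng)
            lo = np.minimum(v0, 0.8)
            hi = np.maximum(v0, 0.8)
            assert np.all(obj.volume >= lo - 1e-12) and np.all(obj.volume <= hi + 1e-12)


class TestAcceleration:
    def test_exploration_all_ones(self, forced_rng):
        obj = aoa.ObjectState(np.zeros(1), np.ones(1), np.ones(1), np.zeros(1))
        pop = [aoa.ObjectState(np.zeros(1), np.ones(1), np.ones(1), np.ones(1))]
        best = aoa.BestRecord(np.zeros(1), np.ones(1), np.ones(1), np.ones(1), 0.0, 1)
        acc = aoa.update_acceleration(obj, pop, best, tf=0.3, rng=forced_rng(0.5))
        assert np.allclose(acc, 2.0)  # (1 + 1*1)/(1*1)

    def test_exploitation_formula(self, rng):
        obj = aoa.ObjectState(np.zeros(1), np.array([0.5]), np.array([0.5]), np.zeros(1))
        best = aoa.BestRecord(np.zeros(1), np.array([0.5]), np.array([0.5]),
                              np.array([1.0]), 0.0, 1)
        acc = aoa.update_acceleration(obj, [obj], best, tf=0.9, rng=rng)
        assert np.allclose(acc, 4.0)  # (0.5 + 0.5*1)/(0.5*0.5)

    def test_denominator_guard_keeps_finite(self, rng):
        obj = aoa.ObjectState(np.zeros(1), np.zeros(1), np.zeros(1), np.zeros(1))
        best = aoa.BestRecord(np.zeros(1), np.array([0.5]), np.array([0.5]),
                              np.array([1.0]), 0.0, 1)
        acc = aoa.update_acceleration(obj, [obj], best, tf=0.9, rng=rng)
        assert np.all(np.isfinite(acc))


class TestNormalization:
    def test_affine_map_example(self):
        out = aoa.normalize_acceleration(np.array([[2.0], [4.0], [6.0]]))
        assert np.allclose(out.ravel(), [0.1, 0.55, 1.0])

    def test_minimum_maps_to_lower_limit(self, rng):
        accs = rng.standard_normal((6, 3))
        out = aoa.normalize_acceleration(accs)
        for dim in range(3):
            assert math.isclose(out[np.argmin(accs[:, dim]), dim], 0.1)
            assert math.isclose(out[np.argmax(accs[:, dim]), dim], 1.0)

    def test_degenerate_population_maps_to_midpoint(self):
        out = aoa.normalize_acceleration(np.full((4, 2), 3.3))
        assert np.allclose(out, 0.55)


class TestPositionUpdate:
    def _setup(self):
        cfg = make_config(lower=np.array([-10.0]), upper=np.array([10.0]))
        obj = aoa.ObjectState(np.zeros(1), np.ones(1) / 2, np.ones(1) / 2, np.zeros(1))
        best = aoa.BestRecord(np.zeros(1), np.ones(1) / 2, np.ones(1) / 2,
                              np.zeros(1), 0.0, 1)
        return cfg, obj, best

    def test_exploration_fixed_point(self, rng):
        cfg, obj, best = self._setup()
        new = aoa.update_position(obj, best, obj.x.copy(), tf=0.3, d=1.0,
                                  t_frac=1.0, norm_accel=np.array([0.5]),
                                  rng=rng, config=cfg)
        assert np.allclose(new, obj.x)

    def test_exploitation_fixed_point(self, rng):
        cfg, obj, best = self._setup()
        obj.x = best.x.copy()
        new = aoa.update_position(obj, best, obj.x.copy(), tf=0.9, d=1.0,
                                  t_frac=1.0, norm_accel=np.array([0.5]),
                                  rng=rng, config=cfg)
        assert np.allclose(new, best.x)

    def test_exploration_forced_half_step(self, forced_rng):
        cfg, obj, best = self._setup()
        new = aoa.update_position(obj, best, np.array([1.0]), tf=0.3, d=1.0,
                                  t_frac=1.0, norm_accel=np.array([0.5]),
                                  rng=forced_rng(0.5), config=cfg)
        assert np.allclose(new, 0.5)  # 0 + 2 * 0.5 * 0.5 * 1 * (1 - 0)


class TestErrorRate:
    def test_direct_formula(self):
        preds = np.zeros(100)
        truth = np.zeros(100)
        truth[:5] = 1
        assert aoa.fitness_error_rate(preds, truth) == 5.0

    def test_extremes(self):
        assert aoa.fitness_error_rate([1, 1], [1, 1]) == 0.0
        assert aoa.fitness_error_rate([0, 0], [1, 1]) == 100.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            aoa.fitness_error_rate([], [])
        with pytest.raises(ParameterError):
            aoa.fitness_error_rate([0], [0, 1])


class TestOptimize:
    def test_constant_objective(self):
        cfg = make_config(max_iterations=5)
        best, trace = aoa.optimize(lambda x: 3.25, cfg)
        assert best.fitness == 3.25
        assert best.iteration_found == 1
        assert [row[1] for row in trace] == [3.25] * 5

    def test_sphere_seed1(self):
        cfg = aoa.AOAConfig(population=20, max_iterations=100,
                            lower=np.array([-5.0, -5.0]),
                            upper=np.array([5.0, 5.0]), seed=1)
        best, _ = aoa.optimize(lambda x: float(np.sum(x ** 2)), cfg)
        assert best.fitness <= 1e-2

    def test_trace_non_increasing_and_positions_bounded(self):
        rastrigin = lambda x: float(10 * x.size + np.sum(x ** 2 - 10 * np.cos(2 * np.pi * x)))
        for seed in range(5):
            cfg = aoa.AOAConfig(population=10, max_iterations=30,
                                lower=np.array([-5.12, -5.12]),
                                upper=np.array([5.12, 5.12]), seed=seed)
            best, trace = aoa.optimize(rastrigin, cfg)
            fits = [row[1] for row in trace]
            assert all(a >= b for a, b in zip(fits, fits[1:]))
            assert np.all(best.x >= cfg.lower) and np.all(best.x <= cfg.upper)

    def test_densities_volumes_stay_in_unit_interval(self):
        cfg = make_config(max_iterations=25, seed=3)
        seen = []

        def objective(x):
            return float(np.sum(x ** 2))

        rng = np.random.default_rng(cfg.seed)
        pop = aoa.initialize_population(cfg, rng)
        best = None
        for t in range(1, cfg.max_iterations + 1):
            for obj in pop:
                obj.fitness = objective(obj.x)
            leader = min(pop, key=lambda o: o.fitness)
            if best is None or leader.fitness < best.fitness:
                best = aoa.BestRecord(leader.x.copy(), leader.density.copy(),
                                      leader.volume.copy(), leader.accel.copy(),
                                      leader.fitness, t)
            for obj in pop:
                aoa.update_density_volume(obj, best, rng)
                seen.append((obj.density.copy(), obj.volume.copy()))
        for d, v in seen:
            assert np.all((d > 0) & (d < 1)) and np.all((v > 0) & (v < 1))

    def test_nonfinite_objective_reports_position(self):
        cfg = make_config()
        with pytest.raises(ObjectiveError) as exc:
            aoa.optimize(lambda x: float("nan"), cfg)
        assert exc.value.position is not None

    def test_beats_random_search_on_sphere_and_rastrigin(self):
        sphere = lambda x: float(np.sum(x ** 2))
        rastrigin = lambda x: float(10 * x.size + np.sum(x ** 2 - 10 * np.cos(2 * np.pi * x)))
        for fn, bound in ((sphere, 5.0), (rastrigin, 5.12)):
            finals, randoms = [], []
            for seed in range(20):
                cfg = aoa.AOAConfig(population=20, max_iterations=100,
                                    lower=np.array([-bound] * 2),
                                    upper=np.array([bound] * 2), seed=seed)
                best, _ = aoa.optimize(fn, cfg)
                finals.append(best.fitness)
                r = np.random.default_rng(seed)
                xs = r.uniform(-bound, bound, size=(2000, 2))
                randoms.append(min(fn(x) for x in xs))
            assert np.median(finals) < np.median(randoms)


class TestTuning:
    def test_stub_objective_recovers_optimum(self):
        space = [aoa.SearchDimension("lr", "log", -3.0, -1.0)]
        best, fit, log = aoa.tune_hyperparameters(
            space, lambda p: abs(p["lr"] - 0.01), population=10,
            max_iterations=30, seed=0)
        assert abs(best["lr"] - 0.01) < 1e-3
        assert len(log) == 10 * 30

    def test_integer_decode_round_half_up(self):
        dim = aoa.SearchDimension("k", "int", 1, 5)
        assert dim.decode(2.7) == 3
        assert dim.decode(2.5) == 3
        assert dim.decode(2.4) == 2

    def test_categorical_decode_bins(self):
        dim = aoa.SearchDimension("bs", "cat", choices=(8, 16, 32))
        assert dim.decode(0.2) == 8
        assert dim.decode(1.9) == 16
        assert dim.decode(2.999) == 32

    def test_seeded_runs_identical_logs(self):
        space = [aoa.SearchDimension("a", "real", 0.0, 1.0)]
        _, _, log1 = aoa.tune_hyperparameters(space, lambda p: p["a"],
                                              population=5, max_iterations=5, seed=2)
        _, _, log2 = aoa.tune_hyperparameters(space, lambda p: p["a"],
                                              population=5, max_iterations=5, seed=2)
        assert log1 == log2

    def test_empty_space_rejected(self):
        with pytest.raises(ParameterError):
            aoa.tune_hyperparameters([], lambda p: 0.0)
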