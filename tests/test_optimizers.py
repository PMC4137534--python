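import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from swarmselect.optimizers import (
    CSState,
    OptimizerConfig,
    PSOState,
    cs_step,
    decode,
    init_cs,
    init_pso,
    levy_step,
    pso_step,
    run_optimizer,
    sfl_sort_partition,
    sfl_worst_update,
    sfllf_worst_update,
)


def sphere(x):
    return -float(np.sum((x - 0.5001) ** 2))


class OnesRng:
    """Stub generator whose uniform draws are all ones (forced rand()=1)."""

    def random(self, size=None):
        return np.ones(size) if size is not None else 1.0

    def integers(self, n):
        return 0

    def permutation(self, n):
        return np.arange(n)


class TestDecode:
    def test_rule_application(self):
        np.testing.assert_array_equal(decode([0.6, 0.4, 0.51]), [0, 2])

    def test_boundary_excluded(self):
        np.testing.assert_array_equal(decode([0.5, 0.5001]), [1])

    def test_all_zeros_empty(self):
        assert decode(np.zeros(5)).size == 0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            decode([0.2, np.nan])

    @given(arrays(float, st.integers(1, 30),
                  elements=st.floats(0, 1, allow_nan=False)))
    @settings(max_examples=100, deadline=None)
    def test_mask_is_strictly_greater_indices(self, pos):
        mask = decode(pos)
        expected = {i for i, v in enumerate(pos) if v > 0.5}
        assert set(mask) == expected


class TestLevyStep:
    def test_zero_scale_gives_zero_vector(self):
        rng = np.random.default_rng(0)
        np.testing.assert_array_equal(levy_step(1.5, 0.0, 8, rng), np.zeros(8))

    def test_seed_reproducibility(self):
        a = levy_step(1.5, 1.0, 100, np.random.default_rng(7))
        b = levy_step(1.5, 1.0, 100, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("lam", [0.5, 1.0, 3.0, 3.5])
    def test_lambda_out_of_range(self, lam):
        with pytest.raises(ValueError):
            levy_step(lam, 1.0, 4, np.random.default_rng(0))

    def test_negative_alpha(self):
        with pytest.raises(ValueError):
            levy_step(1.5, -1.0, 4, np.random.default_rng(0))

    def test_heavy_tail_hill_index(self):
        draws = np.abs(levy_step(1.5, 1.0, 100_000, np.random.default_rng(1)))
        x = np.sort(draws)[::-1]
        k = 1000
        hill = np.mean(np.log(x[:k] / x[k]))
        assert 1.2 <= 1.0 / hill <= 1.8


class TestPSO:
    def test_degenerate_coefficients_freeze(self):
        rng = np.random.default_rng(0)
        cfg = OptimizerConfig(algorithm="pso", dim=4, pop_size=6)
        state = init_pso(cfg, sphere, rng)
        state.velocities = rng.normal(size=(6, 4)) * 0.1
        before = state.positions.copy()
        pso_step(state, sphere, rng, w=0.0, c1=0.0, c2=0.0, vmax=1.0)
        np.testing.assert_array_equal(state.velocities, np.zeros((6, 4)))
        np.testing.assert_array_equal(state.positions, before)

    def test_forced_rand_hand_values(self):
        state = PSOState(
            positions=np.array([[0.2]]),
            velocities=np.array([[0.0]]),
            pbest_positions=np.array([[0.4]]),
            pbest_fitness=np.array([-1.0]),
            gbest_position=np.array([0.6]),
            gbest_fitness=-1.0,
        )
        pso_step(state, lambda x: -2.0, OnesRng(), w=1.0, c1=1.0, c2=1.0, vmax=1.0)
        assert state.velocities[0, 0] == pytest.approx(0.6)
        assert state.positions[0, 0] == pytest.approx(0.8)

    def test_velocity_clamp(self):
        state = PSOState(
            positions=np.array([[0.0]]),
            velocities=np.array([[0.0]]),
            pbest_positions=np.array([[1.0]]),
            pbest_fitness=np.array([0.0]),
            gbest_position=np.array([1.0]),
            gbest_fitness=0.0,
        )
        pso_step(state, lambda x: -1.0, OnesRng(), w=1.0, c1=2.1, c2=2.1, vmax=0.1)
        assert abs(state.velocities[0, 0]) <= 0.1

    def test_gbest_non_decreasing(self):
        rng = np.random.default_rng(4)
        cfg = OptimizerConfig(algorithm="pso", dim=6, pop_size=10)
        state = init_pso(cfg, sphere, rng)
        prev = state.gbest_fitness
        for _ in range(30):
            pso_step(state, sphere, rng, vmax=0.1)
            assert state.gbest_fitness >= prev
            prev = state.gbest_fitness
            assert state.positions.min() >= 0.0 and state.positions.max() <= 1.0

    def test_table_defaults(self):
        cfg = OptimizerConfig()
        assert (cfg.pop_size, cfg.generations) == (50, 200)
        assert (cfg.w, cfg.c1, cfg.c2) == (0.9, 2.1, 2.1)
        assert (cfg.alpha, cfg.lam) == (1.0, 1.5)
        assert (cfg.n_memeplexes, cfg.frogs_per_memeplex, cfg.shuffles) == (10, 5, 20)


class TestCuckooSearch:
    def test_pa_zero_no_reinitialization(self):
        rng = np.random.default_rng(2)
        cfg = OptimizerConfig(algorithm="cs", dim=4, pop_size=8)
        state = init_cs(cfg, sphere, rng)
        nests_before = state.nests.copy()
        cs_step(state, sphere, rng, alpha=0.0, lam=1.5, pa=0.0)
        np.testing.assert_array_equal(state.nests, nests_before)

    def test_alpha_zero_state_unchanged(self):
        rng = np.random.default_rng(3)
        cfg = OptimizerConfig(algorithm="cs", dim=5, pop_size=6)
        state = init_cs(cfg, sphere, rng)
        fits_before = state.fitness.copy()
        cs_step(state, sphere, rng, alpha=0.0, lam=1.5, pa=0.0)
        np.testing.assert_array_equal(state.fitness, fits_before)

    @pytest.mark.parametrize("mode", ["mix", "uniform"])
    def test_best_fitness_non_decreasing(self, mode):
        rng = np.random.default_rng(5)
        cfg = OptimizerConfig(algorithm="cs", dim=6, pop_size=10)
        state = init_cs(cfg, sphere, rng)
        prev = state.best_fitness
        for _ in range(20):
            cs_step(state, sphere, rng, abandon_mode=mode)
            assert state.best_fitness >= prev
            prev = state.best_fitness
            assert state.nests.min() >= 0.0 and state.nests.max() <= 1.0

    def test_nest_count_fixed(self):
        rng = np.random.default_rng(6)
        cfg = OptimizerConfig(algorithm="cs", dim=3, pop_size=7)
        state = init_cs(cfg, sphere, rng)
        for _ in range(5):
            cs_step(state, sphere, rng)
        assert state.nests.shape == (7, 3)


class TestSFLPartition:
    def test_nine_frogs_three_memeplexes(self):
        fitness = np.array([9, 8, 7, 6, 5, 4, 3, 2, 1], dtype=float)
        mems = sfl_sort_partition(fitness, 3)
        # already descending: rank i == frog i
        np.testing.assert_array_equal(mems[0], [0, 3, 6])
        np.testing.assert_array_equal(mems[1], [1, 4, 7])
        np.testing.assert_array_equal(mems[2], [2, 5, 8])

    def test_single_memeplex(self):
        fitness = np.array([1.0, 3.0, 2.0])
        mems = sfl_sort_partition(fitness, 1)
        np.testing.assert_array_equal(mems[0], [1, 2, 0])

    def test_round_robin_on_unsorted_input(self):
        fitness = np.array([1.0, 9.0, 5.0, 7.0])
        mems = sfl_sort_partition(fitness, 2)
        np.testing.assert_array_equal(mems[0], [1, 2])  # ranks 0, 2
        np.testing.assert_array_equal(mems[1], [3, 0])  # ranks 1, 3

    def test_indivisible_is_error(self):
        with pytest.raises(ValueError):
            sfl_sort_partition(np.ones(10), 3)

    def test_stable_on_ties(self):
        mems = sfl_sort_partition(np.ones(4), 2)
        np.testing.assert_array_equal(mems[0], [0, 2])
        np.testing.assert_array_equal(mems[1], [1, 3])


class TestWorstFrogUpdate:
    def test_forced_rand_moves_worst_to_best(self):
        # rand()=1, |Xb - Xw| <= Dmax, fitness improves at Xb -> Xw' == Xb
        positions = np.array([[0.8, 0.8], [0.5, 0.5]])
        fitness = np.array([sphere(positions[0]), -10.0])
        xg = positions[0].copy()
        sfl_worst_update(positions, fitness, xg, sphere, OnesRng(), dmax=0.5)
        np.testing.assert_allclose(positions[1], [0.8, 0.8])
        assert fitness[1] == pytest.approx(sphere(np.array([0.8, 0.8])))

    def test_xw_equals_xb_falls_through_to_global(self):
        # all frogs identical, so Xw == Xb: attempt 1 is a zero step with no
        # improvement; attempt 2 leaps the (first-indexed) worst frog to Xg
        positions = np.array([[0.2, 0.2], [0.2, 0.2]])
        fitness = np.array([sphere(positions[0])] * 2)
        xg = np.array([0.5, 0.5])
        sfl_worst_update(positions, fitness, xg, sphere, OnesRng(), dmax=1.0)
        np.testing.assert_allclose(positions[0], xg)
        np.testing.assert_allclose(positions[1], [0.2, 0.2])

    def test_all_attempts_fail_random_replacement(self):
        calls = {"n": 0}

        def hostile(x):
            calls["n"] += 1
            return -100.0 if calls["n"] <= 2 else -5.0

        rng = np.random.default_rng(0)
        positions = np.array([[0.9, 0.1], [0.3, 0.7]])
        fitness = np.array([-1.0, -2.0])
        before = positions[1].copy()
        sfl_worst_update(positions, fitness, positions[0].copy(), hostile, rng, 0.5)
        assert not np.array_equal(positions[1], before)
        assert fitness[1] == -5.0  # replacement accepted unconditionally

    def test_only_worst_frog_moves(self):
        rng = np.random.default_rng(1)
        positions = rng.random((5, 3))
        fitness = np.array([sphere(p) for p in positions])
        w = int(np.argmin(fitness))
        others_before = [positions[i].copy() for i in range(5) if i != w]
        sfl_worst_update(positions, fitness, positions[0].copy(), sphere, rng, 0.5)
        others_after = [positions[i] for i in range(5) if i != w]
        for a, b in zip(others_before, others_after):
            np.testing.assert_array_equal(a, b)

    def test_sfllf_lf_zero_always_random_replacement(self):
        rng = np.random.default_rng(2)
        positions = np.array([[0.45, 0.55], [0.3, 0.7]])
        fitness = np.array([sphere(positions[0]), sphere(positions[1])])
        before = positions[1].copy()
        sfllf_worst_update(positions, fitness, positions[0].copy(), sphere, rng,
                           lam=1.5, lf=0.0, dmax=0.5)
        # LF=0 makes both attempts zero steps (no strict improvement), so the
        # worst frog is re-seeded uniformly at random
        assert not np.array_equal(positions[1], before)
        assert fitness[1] == pytest.approx(sphere(positions[1]))

    def test_sfllf_forced_ones_matches_sfl_forced_rand(self):
        ones_levy = lambda lam, alpha, dim, rng: np.ones(dim)
        pos_a = np.array([[0.8, 0.8], [0.5, 0.5]])
        fit_a = np.array([sphere(pos_a[0]), -10.0])
        sfllf_worst_update(pos_a, fit_a, pos_a[0].copy(), sphere, OnesRng(),
                           lam=1.5, lf=1.0, dmax=0.5, levy_sampler=ones_levy)
        pos_b = np.array([[0.8, 0.8], [0.5, 0.5]])
        fit_b = np.array([sphere(pos_b[0]), -10.0])
        sfl_worst_update(pos_b, fit_b, pos_b[0].copy(), sphere, OnesRng(), dmax=0.5)
        np.testing.assert_array_equal(pos_a, pos_b)
        np.testing.assert_array_equal(fit_a, fit_b)


class TestRunOptimizer:
    def test_zero_generations_returns_initial_best(self):
        cfg = OptimizerConfig(algorithm="pso", dim=5, pop_size=12, generations=0)
        res = run_optimizer(cfg, sphere, seed=3)
        rng = np.random.default_rng(3)
        init = rng.random((12, 5))
        expected = max(sphere(p) for p in init)
        assert res.best_fitness == pytest.approx(expected)
        assert res.trace == [pytest.approx(expected)]
        assert res.evaluations == 12

    def test_unknown_algorithm(self):
        with pytest.raises(ValueError, match="unknown algorithm"):
            run_optimizer(OptimizerConfig(algorithm="annealing"), sphere, 0)

    def test_sfl_pop_size_mismatch(self):
        cfg = OptimizerConfig(algorithm="sfl", pop_size=40)
        with pytest.raises(ValueError, match="memeplex"):
            run_optimizer(cfg, sphere, 0)

    def test_sfl_generations_not_divisible(self):
        cfg = OptimizerConfig(algorithm="sfl", generations=201)
        with pytest.raises(ValueError, match="divisible"):
            run_optimizer(cfg, sphere, 0)

    @pytest.mark.parametrize("algo", ["pso", "cs", "sfl", "sfllf"])
    def test_determinism(self, algo):
        cfg = OptimizerConfig(algorithm=algo, dim=6, pop_size=10,
                              generations=20, shuffles=5, n_memeplexes=5,
                              frogs_per_memeplex=2)
        a = run_optimizer(cfg, sphere, seed=11)
        b = run_optimizer(cfg, sphere, seed=11)
        np.testing.assert_array_equal(a.best_position, b.best_position)
        assert a.best_fitness == b.best_fitness
        assert a.trace == b.trace
        assert a.evaluations == b.evaluations

    @pytest.mark.parametrize("algo", ["pso", "cs", "sfl", "sfllf"])
    def test_trace_monotone_and_positions_bounded(self, algo):
        cfg = OptimizerConfig(algorithm=algo, dim=5, pop_size=10,
                              generations=20, shuffles=5, n_memeplexes=5,
                              frogs_per_memeplex=2)
        res = run_optimizer(cfg, sphere, seed=0)
        assert len(res.trace) == 21
        assert all(b >= a for a, b in zip(res.trace, res.trace[1:]))
        assert res.best_position.min() >= 0.0
        assert res.best_position.max() <= 1.0
        assert res.best_fitness == res.trace[-1]

    @pytest.mark.parametrize("algo", ["pso", "cs", "sfl", "sfllf"])
    def test_quick_surrogate_progress(self, algo):
        cfg = OptimizerConfig(algorithm=algo, dim=8, generations=60,
                              shuffles=20)
        res = run_optimizer(cfg, sphere, seed=1)
        assert res.best_fitness > res.trace[0]
        assert res.best_fitness > -0.2
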