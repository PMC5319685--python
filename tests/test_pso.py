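"""Unit and property tests for the particle swarm optimizer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emdcast import mlp, pso
from emdcast.errors import InvalidInputError


@pytest.mark.parametrize(
    "n_i, n_h, n_0, expected", [(3, 14, 1, 71), (1, 1, 1, 4), (2, 3, 1, 13)]
)
def test_particle_dimension(n_i, n_h, n_0, expected):
    assert pso.particle_dimension(n_i, n_h, n_0) == expected


class TestSchedules:
    def test_inertia_endpoints_and_midpoint(self):
        cfg = pso.PSOConfig()
        assert pso.inertia_weight(0, cfg) == pytest.approx(0.9)
        assert pso.inertia_weight(cfg.iterations, cfg) == pytest.approx(0.3)
        assert pso.inertia_weight(cfg.iterations // 2, cfg) == pytest.approx(0.6)

    def test_inertia_monotone_non_increasing(self):
        cfg = pso.PSOConfig()
        values = [pso.inertia_weight(t, cfg) for t in range(cfg.iterations + 1)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_learning_factor_endpoints(self):
        cfg = pso.PSOConfig()
        assert pso.learning_factors(0, cfg) == pytest.approx((2.5, 0.5))
        assert pso.learning_factors(cfg.iterations, cfg) == pytest.approx((0.5, 2.5))

    def test_learning_factors_sum_constant(self):
        cfg = pso.PSOConfig()
        for t in range(0, cfg.iterations + 1, 17):
            c1, c2 = pso.learning_factors(t, cfg)
            assert c1 + c2 == pytest.approx(3.0)

    def test_degenerate_schedules_constant(self):
        cfg = pso.PSOConfig(
            inertia_start=0.5, inertia_end=0.5, c1_start=1.0, c1_end=1.0,
            c2_start=2.0, c2_end=2.0,
        )
        for t in (0, 50, 200):
            assert pso.inertia_weight(t, cfg) == 0.5
            assert pso.learning_factors(t, cfg) == (1.0, 2.0)

    def test_out_of_range_iteration(self):
        cfg = pso.PSOConfig()
        with pytest.raises(InvalidInputError):
            pso.inertia_weight(-1, cfg)
        with pytest.raises(InvalidInputError):
            pso.learning_factors(cfg.iterations + 1, cfg)


class TestEncodeDecode:
    def test_dimension_of_paper_architecture(self):
        p = mlp.init_params(3, 14, seed=0)
        assert pso.encode(p).size == 71

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_i=st.integers(1, 4), n_h=st.integers(1, 6))
    def test_round_trip_bijection(self, seed, n_i, n_h):
        p = mlp.init_params(n_i, n_h, seed=seed)
        vec = pso.encode(p)
        q = pso.decode(vec, n_i, n_h)
        assert np.array_equal(pso.encode(q), vec)

    def test_zero_vector_is_zero_network(self):
        p = pso.decode(np.zeros(71), 3, 14)
        assert mlp.forward(p, np.array([0.5, -0.5, 2.0])) == 0.0

    def test_wrong_length_rejected(self):
        with pytest.raises(InvalidInputError):
            pso.decode(np.zeros(70), 3, 14)


class TestFitness:
    def test_exact_network_has_zero_fitness(self):
        p = mlp.init_params(2, 3, seed=1)
        X = np.random.default_rng(0).uniform(-1, 1, (5, 2))
        y = mlp.predict(p, X)
        assert pso.fitness(pso.encode(p), X, y) == pytest.approx(0.0, abs=1e-15)

    def test_zero_position_zero_targets(self):
        X = np.zeros((3, 2))
        assert pso.fitness(np.zeros(13), X, np.zeros(3)) == 0.0

    def test_zero_position_unit_targets(self):
        X = np.zeros((2, 2))
        assert pso.fitness(np.zeros(13), X, np.array([1.0, -1.0])) == 1.0


class _FixedUniformRng:
    """Stub generator returning a constant for every uniform draw."""

    def __init__(self, value: float):
        self.value = value

    def uniform(self, low=0.0, high=1.0, size=None):
        return np.full(size, self.value) if size else self.value


def _state(positions, velocities, pbests, pfits, gbest, gfit):
    return pso.SwarmState(
        positions=np.asarray(positions, dtype=float),
        velocities=np.asarray(velocities, dtype=float),
        personal_bests=np.asarray(pbests, dtype=float),
        personal_best_fitness=np.asarray(pfits, dtype=float),
        global_best=np.asarray(gbest, dtype=float),
        global_best_fitness=float(gfit),
    )


class TestStep:
    def test_pure_inertia_advances_by_velocity(self):
        # w=1, c1=c2=0: velocity unchanged, position += velocity
        cfg = pso.PSOConfig(
            inertia_start=1.0, inertia_end=1.0,
            c1_start=0.0, c1_end=0.0, c2_start=0.0, c2_end=0.0,
        )
        state = _state([[0.0], [1.0]], [[0.5], [-0.5]], [[0.0], [1.0]],
                       [0.0, 1.0], [0.0], 0.0)
        sphere = lambda x: float(np.sum(x * x))
        pso.step(state, cfg, sphere, np.random.default_rng(0))
        assert np.allclose(state.velocities, [[0.5], [-0.5]])
        assert np.allclose(state.positions, [[0.5], [0.5]])

    def test_converged_particle_stays_fixed(self):
        state = _state([[1.0], [1.0]], [[0.0], [0.0]], [[1.0], [1.0]],
                       [0.0, 0.0], [1.0], 0.0)
        cfg = pso.PSOConfig()
        pso.step(state, cfg, lambda x: float(np.sum((x - 1) ** 2)),
                 np.random.default_rng(1))
        assert np.allclose(state.positions, 1.0)

    def test_hand_derived_update_with_clamping(self):
        # 1-D: X=0, V=0, P_i=P_g=1, w=0.5, c1=c2=2, r1=r2=0.5
        # raw V' = 0.5*0 + 2*0.5*1 + 2*0.5*1 = 2, clamped to v_max=1, X'=1
        cfg = pso.PSOConfig(
            inertia_start=0.5, inertia_end=0.5,
            c1_start=2.0, c1_end=2.0, c2_start=2.0, c2_end=2.0,
        )
        state = _state([[0.0], [0.9]], [[0.0], [0.0]], [[1.0], [1.0]],
                       [0.0, 0.5], [1.0], 0.0)
        pso.step(state, cfg, lambda x: float(np.sum(x * x)), _FixedUniformRng(0.5))
        assert state.velocities[0, 0] == pytest.approx(1.0)
        assert state.positions[0, 0] == pytest.approx(1.0)


class TestOptimize:
    def test_sphere_benchmark(self):
        hits = 0
        for seed in range(10):
            _, best, history = pso.optimize(
                lambda x: float(np.sum(x * x)), 5, pso.PSOConfig(seed=seed)
            )
            assert np.all(np.diff(history) <= 0)
            hits += best < 1e-3
        assert hits >= 9

    def test_constant_objective_constant_history(self):
        _, best, history = pso.optimize(
            lambda x: 2.0, 3, pso.PSOConfig(iterations=20, seed=0)
        )
        assert best == 2.0
        assert np.all(history == 2.0)

    def test_same_seed_identical_history(self):
        obj = lambda x: float(np.sum(np.abs(x)))
        cfg = pso.PSOConfig(iterations=30, seed=11)
        _, _, h1 = pso.optimize(obj, 4, cfg)
        _, _, h2 = pso.optimize(obj, 4, cfg)
        assert np.array_equal(h1, h2)

    def test_velocities_stay_clamped(self):
        cfg = pso.PSOConfig(iterations=25, seed=3, v_max=0.5, v_min=-0.5)
        rng = np.random.default_rng(cfg.seed)
        obj = lambda x: float(np.sum(x * x))
        state = pso.init_swarm(obj, 6, cfg, rng)
        for _ in range(cfg.iterations):
            pso.step(state, cfg, obj, rng)
            assert np.all(state.velocities <= cfg.v_max)
            assert np.all(state.velocities >= cfg.v_min)

    def test_trace_written(self, tmp_path):
        path = tmp_path / "trace.csv"
        pso.optimize(lambda x: float(np.sum(x * x)), 2,
                     pso.PSOConfig(iterations=5, seed=0), trace_path=str(path))
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "iteration,best_fitness"
        assert len(lines) == 6
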