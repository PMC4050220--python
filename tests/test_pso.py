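"""Swarm mechanics: schedule, updates, decoding, bookkeeping, full runs."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from snpbarcode import (
    Barcode,
    SwarmConfig,
    SyntheticSpec,
    decode,
    exhaustive_best,
    generate,
    inertia_weight,
    init_population,
    run_pso,
    step,
    update_position,
    update_velocity,
)
from snpbarcode.pso import Particle, SwarmState


class _FixedUniformRng:
    """Stub RNG returning a constant for uniform draws (update arithmetic)."""

    def __init__(self, value):
        self.value = value

    def uniform(self, low=0.0, high=1.0, size=None):
        if size is None:
            return self.value
        return np.full(size, self.value)


class TestInertiaWeight:
    @pytest.mark.parametrize("iteration,expected", [(0, 0.9), (100, 0.4), (50, 0.65)])
    def test_linear_schedule(self, iteration, expected):
        assert inertia_weight(iteration, SwarmConfig()) == pytest.approx(expected)

    def test_constant_decrement(self):
        cfg = SwarmConfig()
        ws = [inertia_weight(t, cfg) for t in range(cfg.max_iterations + 1)]
        steps = np.diff(ws)
        assert np.allclose(steps, steps[0]) and steps[0] < 0

    def test_out_of_range_iteration(self):
        with pytest.raises(ValueError):
            inertia_weight(101, SwarmConfig())


class TestVelocityAndPosition:
    def test_hand_arithmetic(self):
        # w=0.5, v=1, c1=c2=2, r1=r2=0.5, (pbest-x)=2, (gbest-x)=-1 -> 1.5
        cfg = SwarmConfig(k=2)
        p = Particle(
            position=np.zeros(4),
            velocity=np.full(4, 1.0),
            pbest_position=np.full(4, 2.0),
            pbest_fitness=0,
            pbest_barcode=Barcode((1, 2), (1, 1)),
        )
        v = update_velocity(
            p, np.full(4, -1.0), 0.5, cfg, cfg.velocity_clamp(5), _FixedUniformRng(0.5)
        )
        assert np.allclose(v, 1.5)

    def test_stationary_point(self):
        cfg = SwarmConfig(k=2)
        x = np.array([1.0, 4.0, 2.0, 3.0])
        p = Particle(x, np.zeros(4), x.copy(), 0, Barcode((1, 4), (2, 3)))
        v = update_velocity(p, x, 0.9, cfg, cfg.velocity_clamp(5), _FixedUniformRng(0.7))
        assert np.allclose(v, 0.0)

    @given(
        st.floats(-50, 50), st.floats(-50, 50), st.floats(-50, 50),
        st.floats(0, 1), st.floats(0, 1),
    )
    def test_velocity_always_clamped(self, v0, pb, gb, r1, r2):
        cfg = SwarmConfig(k=2)
        v_max = cfg.velocity_clamp(5)
        p = Particle(
            np.full(4, 2.0), np.full(4, v0), np.full(4, pb), 0,
            Barcode((1, 2), (1, 1)),
        )
        v = update_velocity(p, np.full(4, gb), 0.9, cfg, v_max, _FixedUniformRng(r1))
        assert (np.abs(v) <= v_max + 1e-12).all()

    def test_position_update_and_clamp(self):
        x = np.array([3.0, 5.0, 2.0, 3.0])
        v = np.array([1.5, 2.0, 0.0, 1.0])
        out = update_position(x, v, m=5)
        assert np.allclose(out, [4.5, 5.0, 2.0, 3.0])

    def test_zero_velocity_is_identity(self):
        x = np.array([2.2, 4.1, 1.5, 2.9])
        assert np.allclose(update_position(x.copy(), np.zeros(4), 5), x)


class TestDecode:
    def test_rounding_of_example_vector(self):
        rng = np.random.default_rng(0)
        bc = decode(np.array([1.2, 4.4, 2.0, 3.0]), m=5, rng=rng)
        assert bc.snp_indices == (1, 4) and bc.genotype_codes == (2, 3)

    def test_half_away_from_zero_rounds_up(self):
        rng = np.random.default_rng(0)
        bc = decode(np.array([3.5, 1.0, 2.5, 1.0]), m=5, rng=rng)
        assert 4 in bc.snp_indices
        assert bc.genotype_codes[bc.snp_indices.index(4)] == 3

    def test_collision_repaired_and_coordinate_overwritten(self):
        rng = np.random.default_rng(42)
        pos = np.array([3.0, 3.2, 1.0, 2.0])
        bc = decode(pos, m=5, rng=rng)
        assert len(set(bc.snp_indices)) == 2
        assert pos[1] == float(pos[1]) == int(pos[1])  # repaired to an integer
        assert int(pos[1]) in bc.snp_indices

    @given(st.lists(st.floats(-10, 10), min_size=4, max_size=4), st.integers(0, 2**16))
    def test_decoded_barcode_always_valid(self, raw, seed):
        rng = np.random.default_rng(seed)
        bc = decode(np.array(raw), m=5, rng=rng)
        assert len(set(bc.snp_indices)) == 2
        assert all(1 <= i <= 5 for i in bc.snp_indices)
        assert all(g in (1, 2, 3) for g in bc.genotype_codes)


class TestSwarmRuns:
    def test_k_larger_than_m_rejected(self):
        ds = generate(SyntheticSpec(seed=0))
        with pytest.raises(ValueError):
            init_population(SwarmConfig(k=6), 5, np.random.default_rng(0), ds)

    def test_initial_population_invariants(self):
        ds = generate(SyntheticSpec(seed=0))
        state = init_population(SwarmConfig(k=2, seed=1), 5, np.random.default_rng(1), ds)
        assert len(state.particles) == 50
        for p in state.particles:
            assert len(set(p.pbest_barcode.snp_indices)) == 2
        assert state.gbest_fitness == max(p.pbest_fitness for p in state.particles)

    def test_fixed_seed_reproduces_trajectory(self):
        ds = generate(SyntheticSpec(seed=3))
        r1 = run_pso(ds, SwarmConfig(k=2, seed=99))
        r2 = run_pso(ds, SwarmConfig(k=2, seed=99))
        assert r1.barcode == r2.barcode and r1.trace == r2.trace

    def test_gbest_monotone_nondecreasing(self):
        ds = generate(SyntheticSpec(seed=4))
        res = run_pso(ds, SwarmConfig(k=3, seed=7))
        assert all(b >= a for a, b in zip(res.trace, res.trace[1:]))

    def test_converged_swarm_is_a_fixed_point(self):
        ds = generate(SyntheticSpec(seed=5))
        pos = np.array([1.0, 4.0, 3.0, 3.0])
        bc = Barcode((1, 4), (3, 3))
        particles = [
            Particle(pos.copy(), np.zeros(4), pos.copy(), 12, bc) for _ in range(2)
        ]
        state = SwarmState(particles, pos.copy(), 12, bc)
        step(state, ds, SwarmConfig(k=2), np.random.default_rng(0))
        assert state.gbest_fitness == 12 and state.gbest_barcode == bc
        assert np.allclose(state.particles[0].position, pos)

    def test_never_exceeds_exhaustive_maximum(self):
        for s in range(5):
            ds = generate(SyntheticSpec(seed=s))
            opt = exhaustive_best(ds, 2)[0][3]
            assert run_pso(ds, SwarmConfig(k=2, seed=100 + s)).fitness <= opt

    def test_unique_global_optimum_found(self):
        # every HIGH subject carries the planted barcode, no LOW subject does
        spec = SyntheticSpec(seed=8, carrier_prob_high=1.0, carrier_prob_low=0.0)
        ds = generate(spec)
        n_high, _ = ds.group_sizes()
        res = run_pso(ds, SwarmConfig(k=2, seed=8))
        assert res.fitness == n_high
        assert res.barcode == spec.planted_barcode.canonical()

    def test_run_requires_dichotomized_dataset(self):
        ds = generate(SyntheticSpec(seed=0))
        ds.group = None
        with pytest.raises(ValueError):
            run_pso(ds, SwarmConfig(k=2, seed=0))


class TestSwarmConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(population_size=1), dict(max_iterations=0), dict(w_min=1.0, w_max=0.4),
         dict(k=1), dict(objective="maximal")],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SwarmConfig(**kwargs)
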