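"""Particle swarm mechanics: initialization, updates, opposition, convergence."""

import numpy as np
import pytest

from noedv.data_io import GenotypeDataset
from noedv.exhaustive_search import exhaustive_search
from noedv.pso_search import (
    Particle,
    PsoParams,
    inertia_weight,
    initialize_swarm,
    opposite_position,
    pso_search,
    run_pso,
    step,
    update_position,
    update_velocity,
)
from noedv.simulator import (
    SimulationConfig,
    interaction_threshold_model,
    simulate_dataset,
)


def small_dataset(seed=0, m=200, n=20):
    rng = np.random.default_rng(seed)
    geno = rng.integers(0, 3, size=(m, n))
    pheno = rng.integers(0, 2, size=m)
    pheno[:2] = [0, 1]
    return GenotypeDataset(geno, pheno)


class _FixedRng:
    """Stub generator returning a constant for uniform draws."""

    def __init__(self, value):
        self.value = value

    def uniform(self, lo=0.0, hi=1.0):
        return self.value


class TestParams:
    @pytest.mark.parametrize(
        "kwargs", [dict(particles=0), dict(iterations=0), dict(c1=0.0), dict(max_order=0)]
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PsoParams(max_order=kwargs.pop("max_order", 2), **kwargs)


class TestInitialize:
    def test_domains_and_order_mix(self):
        ds = small_dataset()
        swarm = initialize_swarm(ds, PsoParams(max_order=3, particles=100, seed=1))
        orders = [p.order for p in swarm.particles]
        # order 1 is enumerated exhaustively, so particles target orders >= 2
        assert set(orders) == {2, 3}
        for p in swarm.particles:
            assert len(set(p.position.tolist())) == p.order
            assert all(1 <= s <= 20 for s in p.position)
            assert np.all(np.abs(p.velocity) <= 19)
            assert np.array_equal(p.pbest, p.position)  # slot-aligned initial pbest

    def test_same_seed_bit_identical(self):
        ds = small_dataset()
        params = PsoParams(max_order=3, particles=50, seed=9)
        a, b = initialize_swarm(ds, params), initialize_swarm(ds, params)
        for pa, pb in zip(a.particles, b.particles):
            assert pa.order == pb.order
            assert np.array_equal(pa.position, pb.position)
            assert np.array_equal(pa.velocity, pb.velocity)
        assert a.gbest == b.gbest
        assert np.array_equal(a.counts, b.counts)

    def test_order1_only_swarm_has_single_gbest_key(self):
        ds = small_dataset()
        swarm = initialize_swarm(ds, PsoParams(max_order=1, particles=30, seed=2))
        assert set(swarm.gbest) == {1}

    def test_max_order_exceeding_snp_count_rejected(self):
        ds = small_dataset(n=5)
        with pytest.raises(ValueError):
            initialize_swarm(ds, PsoParams(max_order=6, particles=5, seed=0))

    def test_counts_tally_initial_pbests(self):
        ds = small_dataset()
        swarm = initialize_swarm(ds, PsoParams(max_order=3, particles=40, seed=3))
        assert swarm.counts.sum() == sum(p.order for p in swarm.particles)


class TestInertiaWeight:
    def test_formula_arithmetic(self):
        counts = np.array([10, 2, 4, 7])
        assert inertia_weight(counts, 3) == pytest.approx(0.75)

    def test_rarest_snp_explores(self):
        assert inertia_weight(np.array([10, 2, 4]), 2) == 1.0
        assert inertia_weight(np.array([10, 2, 4]), 1) == 0.0

    def test_all_equal_counts_degenerate_rule(self):
        assert inertia_weight(np.array([5, 5, 5]), 2) == 1.0


class TestVelocityUpdate:
    def test_stationary_at_consensus(self):
        p = Particle(order=1, position=np.array([7]), velocity=np.array([0.0]),
                     pbest=(7,), pbest_ci=0.0)
        v = update_velocity(p, (7,), np.zeros(20, dtype=int), PsoParams(max_order=1),
                            _FixedRng(0.5), 20)
        assert v[0] == 0.0

    def test_formula_arithmetic_with_zero_inertia(self):
        # W=0 via counts: pbest SNP is the most frequent
        counts = np.zeros(100, dtype=int)
        counts[19] = 5  # SNP 20 most frequent -> W=0
        p = Particle(order=1, position=np.array([10]), velocity=np.array([3.0]),
                     pbest=(20,), pbest_ci=0.0)
        v = update_velocity(p, (30,), counts, PsoParams(max_order=1, c1=2.0, c2=2.0),
                            _FixedRng(0.5), 100)
        # 0*3 + 1*(20-10) + 1*(30-10) = 30
        assert v[0] == pytest.approx(30.0)

    def test_out_of_range_resampled_into_bounds(self):
        rng = np.random.default_rng(0)
        counts = np.zeros(100, dtype=int)
        p = Particle(order=1, position=np.array([1]), velocity=np.array([99.0]),
                     pbest=(100,), pbest_ci=0.0)
        for _ in range(20):
            v = update_velocity(p, (100,), counts, PsoParams(max_order=1, c1=2.0, c2=2.0),
                                rng, 100)
            assert -99 <= v[0] <= 99

    def test_order_mismatch_is_an_error(self):
        p = Particle(order=2, position=np.array([1, 2]), velocity=np.zeros(2),
                     pbest=(1, 2), pbest_ci=0.0)
        with pytest.raises(RuntimeError):
            update_velocity(p, (5,), np.zeros(10, dtype=int), PsoParams(max_order=2),
                            _FixedRng(0.5), 10)


class TestPositionUpdate:
    def test_rounding_arithmetic(self):
        p = Particle(order=1, position=np.array([10]), velocity=np.zeros(1),
                     pbest=(10,), pbest_ci=0.0)
        new = update_position(p, np.array([5.4]), 100, np.random.default_rng(0))
        assert new[0] == 15

    def test_out_of_range_redrawn_uniform(self):
        p = Particle(order=1, position=np.array([98]), velocity=np.zeros(1),
                     pbest=(98,), pbest_ci=0.0)
        rng = np.random.default_rng(0)
        draws = {int(update_position(p, np.array([7.0]), 100, rng)[0]) for _ in range(50)}
        assert all(1 <= d <= 100 for d in draws)
        assert len(draws) > 5  # genuinely random, not clamped to the boundary

    def test_zero_velocity_is_identity(self):
        p = Particle(order=3, position=np.array([3, 9, 15]), velocity=np.zeros(3),
                     pbest=(3, 9, 15), pbest_ci=0.0)
        new = update_position(p, np.zeros(3), 20, np.random.default_rng(0))
        assert new.tolist() == [3, 9, 15]

    def test_duplicates_redrawn_until_distinct(self):
        p = Particle(order=2, position=np.array([5, 6]), velocity=np.zeros(2),
                     pbest=(5, 6), pbest_ci=0.0)
        for seed in range(10):
            new = update_position(p, np.array([1.0, 0.0]), 20, np.random.default_rng(seed))
            assert len(set(new.tolist())) == 2


class TestOpposition:
    def test_mirror_arithmetic(self):
        assert opposite_position((1, 50, 100), 100) == (100, 51, 1)

    def test_involution(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pos = tuple(rng.choice(np.arange(1, 51), size=3, replace=False).tolist())
            assert opposite_position(opposite_position(pos, 50), 50) == pos

    def test_center_fixed_point_for_odd_n(self):
        assert opposite_position((13,), 25) == (13,)


class TestStepAndSearch:
    def test_gbest_monotone_and_counts_invariant(self):
        ds = small_dataset()
        params = PsoParams(max_order=3, particles=40, iterations=8, seed=11)
        swarm = initialize_swarm(ds, params)
        sum_orders = sum(p.order for p in swarm.particles)
        prev = dict(swarm.history[-1])
        for g in range(1, params.iterations + 1):
            step(swarm)
            current = swarm.history[-1]
            for order, score in prev.items():
                assert current[order] >= score
            prev = dict(current)
            assert swarm.counts.sum() == (g + 1) * sum_orders

    def test_pbest_unchanged_when_candidates_worse(self, xor_noise_dataset):
        params = PsoParams(max_order=2, particles=30, iterations=3, seed=5)
        swarm = run_pso(xor_noise_dataset, params)
        for p in swarm.particles:
            assert p.pbest_ci >= swarm.evaluated[p.order][p.pbest_combo] - 1e-15
            assert len(set(p.pbest.tolist())) == p.order

    def test_reported_tuples_valid_and_sorted(self):
        ds = small_dataset()
        results = pso_search(ds, PsoParams(max_order=3, particles=60, iterations=5, seed=7), top_k=5)
        for order, recs in results.items():
            assert len(recs) <= 5
            ncis = [r.nci for r in recs]
            assert ncis == sorted(ncis, reverse=True)
            for r in recs:
                assert r.order == order and len(set(r.snps)) == order
                assert all(1 <= s <= ds.n_snps for s in r.snps)

    def test_same_seed_identical_output(self):
        ds = small_dataset()
        params = PsoParams(max_order=2, particles=50, iterations=5, seed=123)
        assert pso_search(ds, params, top_k=10) == pso_search(ds, params, top_k=10)

    def test_order1_swarm_converges_to_top_mi_snp(self):
        model = interaction_threshold_model(baseline=0.1, risk=0.9)
        sim = simulate_dataset(model, SimulationConfig(n_snps=15, cases=500, controls=500, seed=21))
        best_mi = exhaustive_search(sim.dataset, max_order=1, top_k=1)[1][0].snps
        results = pso_search(
            sim.dataset, PsoParams(max_order=1, particles=60, iterations=10, seed=22), top_k=1
        )
        assert results[1][0].snps == best_mi

    def test_planted_pair_recovered(self):
        model = interaction_threshold_model()
        sim = simulate_dataset(model, SimulationConfig(n_snps=40, cases=800, controls=800, seed=31))
        results = pso_search(
            sim.dataset, PsoParams(max_order=2, particles=200, iterations=10, seed=32), top_k=10
        )
        assert any(r.snps == sim.truth for r in results[2])
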