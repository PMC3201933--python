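"""Eco-evolutionary simulator: inhibition rule, fitness, dynamics, lineages."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strepnet.ecoevo import (
    P,
    R,
    S,
    CommunityState,
    ModelParams,
    Snapshot,
    apply_hgt,
    build_inhibition_matrix,
    community_density,
    compute_fitness,
    functional_diversity,
    invasion_succeeds,
    producer_invasion_threshold,
    run,
    sample_distributed_costs,
    sample_isolates,
    step_generation,
    turnover_fraction,
)


def state_of(Z, counts, lineage=None):
    Z = np.asarray(Z, dtype=np.int8)
    g = Z.shape[0]
    st_ = CommunityState(
        Z=Z,
        counts=np.asarray(counts, dtype=np.int64),
        ids=np.arange(g, dtype=np.int64),
        lineage=lineage or {i: (-1, 0) for i in range(g)},
        next_id=g,
    )
    return st_


class TestInhibitionMatrix:
    def test_hand_rule_application(self):
        Z = np.array([[P, S], [S, R]])
        A = build_inhibition_matrix(Z)
        assert A[1, 0] and not A[0, 1]  # strain 0 inhibits strain 1

    def test_all_sensitive_pair_is_empty(self):
        assert not build_inhibition_matrix(np.full((2, 3), S)).any()

    def test_diagonal_always_zero(self):
        rng = np.random.default_rng(0)
        Z = rng.integers(0, 3, size=(12, 40)).astype(np.int8)
        assert not np.diagonal(build_inhibition_matrix(Z)).any()

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 70))
    def test_bitmask_path_matches_dense_rule(self, seed, L):
        """Oracle: direct (P, S) overlap test over all pairs and positions."""
        rng = np.random.default_rng(seed)
        Z = rng.integers(0, 3, size=(6, L)).astype(np.int8)
        A = build_inhibition_matrix(Z)
        expected = np.zeros_like(A)
        for i in range(6):
            for j in range(6):
                expected[i, j] = any(
                    Z[j, a] == P and Z[i, a] == S for a in range(L))
        assert np.array_equal(A, expected)


class TestFitness:
    def test_single_all_sensitive_strain_is_neutral(self):
        st_ = state_of(np.full((1, 4), S), [100])
        p = ModelParams(L=4, N=100)
        assert compute_fitness(st_, p) == pytest.approx([1.0])

    def test_hand_evaluated_invader_resident_pair(self):
        # rare producer (n=0.01, c_P=0.02) vs all-sensitive resident
        L = 4
        Z = np.full((2, L), S)
        Z[1, 0] = P
        st_ = state_of(Z, [9900, 100])
        p = ModelParams(L=L, N=10_000, eps=0.05, lam=0.15, eta=0.7,
                        cost_P=0.02, cost_R=0.005)
        f = compute_fitness(st_, p)
        assert f[1] == pytest.approx(0.98 * (1 + 0.05 * 0.85 * 0.99))
        assert f[0] == pytest.approx(1 * (1 - 0.05 * 0.01))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_zero_sum_identity(self, seed):
        """sum_i n_i (G_i - H_i) = 0 for any state (index-relabeling identity);
        at lam = 0 the mean relative interaction fitness effect vanishes."""
        rng = np.random.default_rng(seed)
        g = rng.integers(2, 10)
        Z = rng.integers(0, 3, size=(g, 8)).astype(np.int8)
        counts = rng.integers(1, 50, size=g)
        st_ = state_of(Z, counts)
        p = ModelParams(L=8, N=int(counts.sum()), lam=0.0, cost_P=0.0, cost_R=0.0)
        f = compute_fitness(st_, p)
        n = st_.abundances
        assert abs(float(n @ (f - 1.0))) < 1e-12

    def test_costs_multiply_per_position(self):
        Z = np.array([[P, R, S, R]])
        st_ = state_of(Z, [10])
        p = ModelParams(L=4, N=10, cost_P=0.1, cost_R=0.05)
        f = compute_fitness(st_, p)
        assert f[0] == pytest.approx(0.9 * 0.95 * 0.95)


class TestDynamics:
    def test_no_mutation_single_genotype_unchanged(self):
        p = ModelParams(L=4, N=500, mu=0.0)
        st_ = CommunityState.founder(p)
        rng = np.random.default_rng(0)
        step_generation(st_, p, rng)
        assert st_.generation == 1
        assert st_.n_genotypes == 1 and st_.counts[0] == 500

    def test_population_size_conserved(self):
        p = ModelParams(L=6, N=300, mu=1e-3, seed=1)
        st_ = CommunityState.founder(p)
        rng = np.random.default_rng(1)
        for _ in range(200):
            step_generation(st_, p, rng)
            assert st_.counts.sum() == 300

    def test_missing_rng_is_an_error(self):
        p = ModelParams(L=4, N=100)
        with pytest.raises(ValueError):
            step_generation(CommunityState.founder(p), p, None)

    def test_neutral_drift_preserves_mean_frequency(self):
        """Two neutral genotypes: mean frequency across replicates stays at
        its initial value (binomial martingale), within 3 SE."""
        p = ModelParams(L=2, N=200, mu=0.0, eps=1e-9, cost_P=0.0, cost_R=0.0)
        freqs = []
        for rep in range(400):
            Z = np.array([[S, S], [R, S]])
            st_ = state_of(Z, [150, 50])
            rng = np.random.default_rng(1000 + rep)
            for _ in range(30):
                step_generation(st_, p, rng)
            is_b = (st_.Z[:, 0] == R)
            freqs.append(st_.counts[is_b].sum() / 200)
        mean = np.mean(freqs)
        se = np.std(freqs) / np.sqrt(len(freqs))
        assert abs(mean - 0.25) < 3 * se + 1e-9

    def test_same_seed_bit_identical_trajectories(self):
        p = ModelParams(L=6, N=400, mu=5e-4, seed=7)
        res1 = run(p, n_generations=300, burn_in=100, record_every=50, sample_K=8,
                   n_sample_draws=2)
        res2 = run(p, n_generations=300, burn_in=100, record_every=50, sample_K=8,
                   n_sample_draws=2)
        for a, b in zip(res1["records"], res2["records"]):
            assert a == b


class TestHGT:
    def test_all_sensitive_donor_changes_nothing(self):
        p = ModelParams(L=4, N=100, hgt_prob=1.0)
        st_ = state_of(np.full((1, 4), S), [100])
        before = st_.Z.copy()
        apply_hgt(st_, p, np.random.default_rng(0))
        assert np.array_equal(np.unique(st_.Z, axis=0), np.unique(before, axis=0))

    def test_forced_transfer_gains_donor_production(self):
        Z = np.array([[S, S, S, S], [P, R, S, S]])
        p = ModelParams(L=4, N=100, hgt_prob=1.0)
        st_ = state_of(Z, [50, 50])
        apply_hgt(st_, p, np.random.default_rng(2))
        # some recipient must now carry a gained P or R at position 0/1
        gained = [row for row in st_.Z if (row[:2] > 0).any() and not
                  np.array_equal(row, Z[1])]
        assert gained
        assert st_.counts.sum() == 100

    def test_requires_positive_rate(self):
        p = ModelParams(L=4, N=100, hgt_prob=0.0)
        with pytest.raises(ValueError):
            apply_hgt(CommunityState.founder(p), p, np.random.default_rng(0))


class TestSamplingAndLineages:
    def test_single_genotype_divergences_zero(self):
        p = ModelParams(L=4, N=100)
        st_ = CommunityState.founder(p)
        st_.generation = 500
        draws = sample_isolates(st_, K=6, n_draws=1, rng=np.random.default_rng(0))
        matrix, div = draws[0]
        assert not matrix.values.any()
        assert not div.any()

    def test_split_time_recovered(self):
        # genotype 1 branched from genotype 0 at generation 40
        Z = np.array([[S, S], [P, S]], dtype=np.int8)
        st_ = state_of(Z, [50, 50], lineage={0: (-1, 0), 1: (0, 40)})
        st_.generation = 100
        draws = sample_isolates(st_, K=12, n_draws=1, rng=np.random.default_rng(1))
        _, div = draws[0]
        vals = np.unique(div)
        assert set(vals.tolist()) <= {0.0, 60.0}
        assert 60.0 in vals

    def test_sibling_split_at_earlier_branch(self):
        # 1 branched at 20, 2 branched at 70, both from 0; pair (1,2) split at 20
        Z = np.array([[S, S], [P, S], [R, S]], dtype=np.int8)
        st_ = state_of(Z, [0, 50, 50],
                       lineage={0: (-1, 0), 1: (0, 20), 2: (0, 70)})
        st_.counts = np.array([0, 50, 50], dtype=np.int64)
        st_.prune()
        st_.generation = 100
        draws = sample_isolates(st_, K=10, n_draws=1, rng=np.random.default_rng(2))
        _, div = draws[0]
        assert set(np.unique(div).tolist()) <= {0.0, 80.0}
        assert 80.0 in np.unique(div)


class TestDiversityAndTurnover:
    def test_one_class_gives_one(self):
        st_ = state_of(np.full((1, 4), S), [100])
        assert functional_diversity(st_) == pytest.approx(1.0)

    def test_four_equal_classes_give_four(self):
        # four strains, each producing a private antibiotic, all else sensitive
        Z = np.full((4, 4), S)
        np.fill_diagonal(Z, P)
        st_ = state_of(Z, [25, 25, 25, 25])
        assert functional_diversity(st_) == pytest.approx(4.0)

    def test_closed_form_half_quarter_quarter(self):
        Z = np.full((3, 4), S)
        np.fill_diagonal(Z, P)
        st_ = state_of(Z, [50, 25, 25])
        assert functional_diversity(st_) == pytest.approx(2 ** 1.5)

    def test_turnover_identity_and_disjoint(self):
        p = ModelParams(L=4, N=100)
        st_ = CommunityState.founder(p)
        s1 = Snapshot.of(st_)
        assert turnover_fraction(s1, s1) == 1.0
        st2 = state_of(np.array([[P, S, S, S]]), [100])
        s2 = Snapshot.of(st2)
        s2 = Snapshot(run_id=s1.run_id, generation=10, profiles=s2.profiles)
        assert turnover_fraction(s1, s2) == 0.0

    def test_mismatched_runs_rejected(self):
        a = Snapshot(run_id=1, generation=0, profiles={b"x": 1})
        b = Snapshot(run_id=2, generation=0, profiles={b"x": 1})
        with pytest.raises(ValueError):
            turnover_fraction(a, b)


class TestInvasionThreshold:
    def test_complete_spite_gives_zero(self):
        assert producer_invasion_threshold(ModelParams(lam=1.0)) == 0.0

    def test_closed_form_value(self):
        p = ModelParams(eps=0.05, lam=0.15)
        assert producer_invasion_threshold(p) == pytest.approx(0.040766, abs=1e-5)

    def test_simulation_brackets_threshold(self):
        p = ModelParams(L=8, N=1500, mu=0.0, seed=0)
        cmax = producer_invasion_threshold(p)
        rng = np.random.default_rng(3)
        below = sum(invasion_succeeds(p, 0.5 * cmax, rng) for _ in range(5))
        above = sum(invasion_succeeds(p, 1.5 * cmax, rng) for _ in range(5))
        assert below >= 4 and above <= 1


class TestDistributedCosts:
    def test_samples_within_interval(self):
        p = ModelParams(L=40, cost_R=0.005)
        rng = np.random.default_rng(0)
        c = sample_distributed_costs(p, rng)
        cmax = producer_invasion_threshold(p)
        assert c.shape == (40,)
        assert (c >= 0.005).all() and (c <= cmax).all()

    def test_mean_matches_uniform_moments(self):
        p = ModelParams(L=2000, cost_R=0.01)
        rng = np.random.default_rng(1)
        c = np.concatenate([sample_distributed_costs(p, rng) for _ in range(50)])
        cmax = producer_invasion_threshold(p)
        se = (cmax - 0.01) / np.sqrt(12) / np.sqrt(c.size)
        assert abs(c.mean() - (0.01 + cmax) / 2) < 3 * se

    def test_resistance_cost_above_threshold_rejected(self):
        p = ModelParams(cost_R=0.5)
        with pytest.raises(ValueError):
            sample_distributed_costs(p, np.random.default_rng(0))


class TestRunProtocol:
    def test_records_and_snapshots_produced(self):
        p = ModelParams(L=6, N=500, mu=1e-3, seed=3)
        res = run(p, n_generations=200, burn_in=100, record_every=50, sample_K=8,
                  n_sample_draws=2)
        assert len(res["records"]) == 3
        gens = [r["generation"] for r in res["records"]]
        assert gens == [100, 150, 200]
        assert all(r["diversity"] >= 1.0 for r in res["records"])
        assert len(res["snapshots"]) == 3

    def test_grid_scan_reports_every_cost_combination(self):
        from strepnet.ecoevo import grid_scan
        p = ModelParams(L=6, N=400, mu=1e-3, seed=5)
        frame = grid_scan(p, np.array([0.01, 0.03]), np.array([0.005]),
                          n_generations=300, burn_in=200, record_every=50,
                          sample_K=8, n_sample_draws=2)
        assert len(frame) == 2
        assert set(frame.columns) >= {"cost_P", "cost_R", "density", "Q",
                                      "above_diagonal", "seed"}
        assert frame["above_diagonal"].all()
        assert frame["density"].between(0, 1).all()
        with pytest.raises(ValueError):
            grid_scan(p, np.array([]), np.array([0.005]))

    def test_community_density_matches_sampled_density_without_clones(self):
        Z = np.full((3, 4), S)
        np.fill_diagonal(Z, P)
        st_ = state_of(Z, [40, 30, 30])
        # every distinct pair interacts both ways here
        assert community_density(st_) == pytest.approx(1.0)
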