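"""Coalescent simulator: validation, closed-form means, bounds, determinism."""

import numpy as np
import pytest

from evokit.coalescent import (
    Genealogy,
    drop_mutations,
    run_replicates,
    simulate_genealogy,
)
from evokit.demography import (
    DemographicModel,
    Merge,
    MigrationEpoch,
    SampleConfig,
    SizeChange,
    validate_model,
)
from oracles import harmonic


def two_pop_split(tau=1.0):
    return DemographicModel(
        populations=[("A", 1.0), ("B", 1.0)],
        merges=[Merge(tau, "B", "A")],
    )


class TestValidation:
    def test_minimal_model_is_valid(self, const_model):
        rep = validate_model(const_model, SampleConfig([("A", 5, 0.0)]))
        assert rep.ok and not rep.errors

    def test_two_isolated_pops_is_non_closing(self):
        model = DemographicModel(populations=[("A", 1.0), ("B", 1.0)])
        rep = validate_model(model, SampleConfig([("A", 2, 0.0), ("B", 2, 0.0)]))
        assert any("non-closing" in e for e in rep.errors)

    def test_positive_migration_closes_two_pop_model(self):
        model = DemographicModel(
            populations=[("A", 1.0), ("B", 1.0)],
            migration_epochs=[MigrationEpoch(0.0, ((0.0, 1.0), (1.0, 0.0)))],
        )
        rep = validate_model(model, SampleConfig([("A", 2, 0.0), ("B", 2, 0.0)]))
        assert rep.ok

    def test_sampling_after_merge_rejected(self):
        rep = validate_model(
            two_pop_split(tau=1.0),
            SampleConfig([("A", 2, 0.0), ("B", 2, 2.0)]),
        )
        assert any("not live at sampling time" in e for e in rep.errors)

    def test_bad_sizes_and_times_reported(self):
        model = DemographicModel(
            populations=[("A", -1.0)],
            size_changes=[SizeChange(-0.5, "A", 2.0)],
        )
        rep = validate_model(model, SampleConfig([("A", 2, 0.0)]))
        assert len(rep.errors) >= 2

    def test_simulate_rejects_invalid_model(self):
        model = DemographicModel(populations=[("A", 1.0), ("B", 1.0)])
        with pytest.raises(ValueError, match="non-closing"):
            simulate_genealogy(model, SampleConfig([("A", 1, 0.0), ("B", 1, 0.0)]), 1)


class TestGenealogy:
    def test_pair_coalescence_mean_matches_closed_form(self, const_model):
        # E[T2] = x/2 in 4N0 units; x=1 here
        samples = SampleConfig([("A", 2, 0.0)])
        times = [
            simulate_genealogy(
                const_model, samples, seed=np.random.default_rng([13, i])
            ).root_time
            for i in range(3000)
        ]
        mean, se = np.mean(times), np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(mean - 0.5) < 3 * se

    def test_pair_coalescence_scales_with_population_size(self):
        model = DemographicModel(populations=[("A", 4.0)])
        samples = SampleConfig([("A", 2, 0.0)])
        times = [
            simulate_genealogy(model, samples, seed=np.random.default_rng([17, i])).root_time
            for i in range(3000)
        ]
        mean, se = np.mean(times), np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(mean - 2.0) < 3 * se

    def test_split_model_bounds_cross_population_mrca(self):
        samples = SampleConfig([("A", 1, 0.0), ("B", 1, 0.0)])
        model = two_pop_split(tau=1.0)
        for i in range(200):
            g = simulate_genealogy(model, samples, seed=np.random.default_rng([19, i]))
            assert g.root_time >= 1.0

    def test_serial_sample_bounds_root_time(self, const_model):
        samples = SampleConfig([("A", 1, 0.0), ("A", 1, 3.0)])
        for i in range(100):
            g = simulate_genealogy(const_model, samples, seed=np.random.default_rng([23, i]))
            assert g.root_time >= 3.0
            assert g.time[1] == pytest.approx(3.0)  # leaf keeps its sampling time

    def test_tree_shape_invariants(self, const_model):
        g = simulate_genealogy(const_model, SampleConfig([("A", 7, 0.0)]), seed=5)
        assert g.n_nodes == 2 * 7 - 1
        assert (g.parent[:-1] >= 0).all() and g.parent[g.root] == -1
        for v in range(g.n_nodes - 1):
            assert g.time[g.parent[v]] >= g.time[v]

    def test_identical_seed_identical_tree(self, const_model):
        s = SampleConfig([("A", 9, 0.0)])
        g1 = simulate_genealogy(const_model, s, seed=77)
        g2 = simulate_genealogy(const_model, s, seed=77)
        assert np.array_equal(g1.parent, g2.parent)
        assert np.array_equal(g1.time, g2.time)


class TestMutations:
    @staticmethod
    def fixed_pair_tree(t=0.5):
        # two leaves joined at time t: total branch length 2t
        return Genealogy(
            n_leaves=2,
            parent=np.array([2, 2, -1]),
            time=np.array([0.0, 0.0, t]),
            leaf_pops=["A", "A"],
        )

    def test_mutation_count_mean_is_theta_times_length(self):
        # total length 1 (t=0.5), theta=5 => E[S] = 5
        g = self.fixed_pair_tree(0.5)
        rng = np.random.default_rng(3)
        S = [drop_mutations(g, 5.0, seed=rng).S for _ in range(4000)]
        mean, se = np.mean(S), np.std(S, ddof=1) / np.sqrt(len(S))
        assert abs(mean - 5.0) < 3 * se

    def test_theta_to_zero_gives_no_sites(self):
        g = self.fixed_pair_tree(0.5)
        S = [drop_mutations(g, 1e-6, seed=np.random.default_rng(i)).S for i in range(200)]
        assert np.mean([s == 0 for s in S]) > 0.99

    def test_all_columns_segregating_and_positions_sorted(self, const_model):
        g = simulate_genealogy(const_model, SampleConfig([("A", 8, 0.0)]), seed=11)
        seg = drop_mutations(g, 20.0, seed=11)
        counts = seg.matrix.sum(axis=0)
        assert ((counts > 0) & (counts < 8)).all()
        assert (np.diff(seg.positions) >= 0).all()
        assert ((seg.positions > 0) & (seg.positions < 1)).all()

    def test_nonpositive_theta_rejected(self):
        with pytest.raises(ValueError):
            drop_mutations(self.fixed_pair_tree(), 0.0, seed=1)


class TestReplicates:
    def test_neutral_means_match_theory(self, neutral_reps):
        # E[S] = theta * H_{n-1}, E[pi] = theta at theta=5, n=20
        S = np.array([s.S for s in neutral_reps.stats], float)
        pi = np.array([s.pi for s in neutral_reps.stats])
        e_S = 5.0 * harmonic(20)
        assert abs(S.mean() - e_S) < 3 * S.std(ddof=1) / np.sqrt(S.size)
        assert abs(pi.mean() - 5.0) < 3 * pi.std(ddof=1) / np.sqrt(pi.size)

    def test_same_master_seed_is_bitwise_identical(self, const_model):
        s = SampleConfig([("A", 6, 0.0)])
        r1 = run_replicates(const_model, s, 2.0, 20, seed=9)
        r2 = run_replicates(const_model, s, 2.0, 20, seed=9)
        for a, b in zip(r1.replicates, r2.replicates):
            assert np.array_equal(a.positions, b.positions)
            assert np.array_equal(a.matrix, b.matrix)

    def test_replicates_reproducible_in_isolation(self, const_model):
        # replicate k of a long run equals replicate k of a prefix run
        s = SampleConfig([("A", 6, 0.0)])
        long = run_replicates(const_model, s, 2.0, 15, seed=31)
        short = run_replicates(const_model, s, 2.0, 5, seed=31)
        for a, b in zip(short.replicates, long.replicates[:5]):
            assert np.array_equal(a.matrix, b.matrix)

    def test_distributions_report_quantiles_and_undefined_counts(self, neutral_reps):
        d = neutral_reps.distributions
        assert set(d["S"]["quantiles"]) == {0.025, 0.25, 0.5, 0.75, 0.975}
        n_undef_td = sum(1 for s in neutral_reps.stats if s.tajima_d is None)
        assert d["tajima_d"]["n_undefined"] == n_undef_td

    def test_exchangeability_within_population(self, const_model):
        # splitting one sample entry into two entries of the same pop
        # leaves the summary-statistic distribution unchanged
        a = run_replicates(const_model, SampleConfig([("A", 12, 0.0)]), 3.0, 400, seed=57)
        b = run_replicates(
            const_model, SampleConfig([("A", 5, 0.0), ("A", 7, 0.0)]), 3.0, 400, seed=58
        )
        Sa = np.array([s.S for s in a.stats], float)
        Sb = np.array([s.S for s in b.stats], float)
        se = np.sqrt(Sa.var(ddof=1) / Sa.size + Sb.var(ddof=1) / Sb.size)
        assert abs(Sa.mean() - Sb.mean()) < 3 * se

    def test_invalid_rep_count_rejected(self, const_model, sample20):
        with pytest.raises(ValueError):
            run_replicates(const_model, sample20, 1.0, 0, seed=1)


def test_segregating_sites_mean_agrees_with_msprime():
    """Independent oracle: same model in msprime's ms-compatible units."""
    msprime = pytest.importorskip("msprime")
    theta, n, reps = 3.0, 10, 400
    mine = run_replicates(
        DemographicModel([("A", 1.0)]), SampleConfig([("A", n, 0.0)]),
        theta, reps, seed=71,
    )
    S_mine = np.array([s.S for s in mine.stats], float)
    # population_size=0.5, ploidy=1 => pair rate 2 per unit time (4N0 units)
    S_ms = []
    for i, ts in enumerate(
        msprime.sim_ancestry(
            samples=n, ploidy=1, population_size=0.5,
            num_replicates=reps, random_seed=71,
        )
    ):
        mts = msprime.sim_mutations(
            ts, rate=theta, random_seed=72 + i, discrete_genome=False
        )
        S_ms.append(mts.num_sites)
    S_ms = np.array(S_ms, float)
    se = np.sqrt(S_mine.var(ddof=1) / reps + S_ms.var(ddof=1) / reps)
    assert abs(S_mine.mean() - S_ms.mean()) < 3 * se
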