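"""Generator core: z draws, clustering, pair sampling, constraints, generation."""

import numpy as np
import pytest

from logicgen.generator_core import (
    GenomatorParams,
    build_clusters,
    build_constraints,
    clauses_satisfied,
    draw_z,
    generate,
    pattern_frequencies,
    sample_pair_universe,
    solve_constraints,
)

from conftest import make_matrix


class TestDrawZ:
    def test_zero_alpha_always_zero(self, rng):
        assert all(draw_z(0.0, rng) == 0 for _ in range(100))

    def test_alpha_half_is_one_third_one(self):
        g = np.random.default_rng(0)
        draws = np.array([draw_z(0.5, g) for _ in range(100_000)])
        assert set(draws.tolist()) == {0, 1}
        assert abs((draws == 1).mean() - 1 / 3) < 0.02

    def test_integer_alpha_uniform(self):
        g = np.random.default_rng(1)
        draws = np.array([draw_z(2.0, g) for _ in range(100_000)])
        assert set(draws.tolist()) == {0, 1, 2}
        for v in (0, 1, 2):
            assert abs((draws == v).mean() - 1 / 3) < 0.02

    def test_negative_alpha_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_z(-0.1, rng)


class TestBuildClusters:
    def test_full_and_singleton_clusters(self, random_matrix):
        n = random_matrix.n_haplotypes
        full = build_clusters(random_matrix, n)
        assert all(sorted(c.members) == list(range(n)) for c in full)
        single = build_clusters(random_matrix, 1)
        assert all(c.members == (c.seed_row,) for c in single)

    def test_oversized_cluster_rejected(self, random_matrix):
        with pytest.raises(ValueError):
            build_clusters(random_matrix, random_matrix.n_haplotypes + 1)

    def test_matches_brute_force_sort(self, rng):
        m = make_matrix(rng.integers(0, 2, size=(8, 20)))
        clusters = build_clusters(m, 3)
        for c in clusters:
            d = [
                (int(np.count_nonzero(m.rows[i] != m.rows[c.seed_row])), i)
                for i in range(8)
                if i != c.seed_row
            ]
            expected = (c.seed_row,) + tuple(i for _, i in sorted(d)[:2])
            assert c.members == expected


class TestSamplePairUniverse:
    def test_extremes(self, rng):
        assert sample_pair_universe(10, 0.0, rng).shape == (45, 2)
        assert sample_pair_universe(10, 1.0, rng).shape == (0, 2)

    def test_binomial_size(self):
        g = np.random.default_rng(5)
        k = sample_pair_universe(100, 0.99, g).shape[0]
        mean, sd = 4950 * 0.01, np.sqrt(4950 * 0.01 * 0.99)
        assert abs(k - mean) <= 3 * sd

    def test_bad_exclusion_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_pair_universe(10, 1.5, rng)


class TestPatternFrequencies:
    def test_hand_enumeration(self):
        m = make_matrix([[0, 0], [0, 1], [1, 1]])
        counts = pattern_frequencies(m, [0, 1, 2], (0, 1))
        assert counts.tolist() == [1, 1, 0, 1]  # 00, 01, 10, 11

    def test_single_and_identical_members(self):
        m = make_matrix([[1, 0], [1, 0], [1, 0]])
        assert pattern_frequencies(m, [1], (0, 1)).tolist() == [0, 0, 1, 0]
        assert pattern_frequencies(m, [0, 1, 2], (0, 1)).tolist() == [0, 0, 3, 0]

    def test_counts_sum_to_members(self, random_matrix, rng):
        members = rng.choice(20, size=11, replace=False)
        counts = pattern_frequencies(random_matrix, members, (3, 17))
        assert counts.sum() == 11


class TestBuildConstraints:
    def test_alpha_zero_forbids_exactly_unobserved(self, small_cohort):
        clusters = build_clusters(small_cohort, 20)
        cluster = clusters[5]
        pairs = sample_pair_universe(small_cohort.n_sites, 0.8, np.random.default_rng(2))
        problem = build_constraints(small_cohort, cluster, pairs, 0.0,
                                    np.random.default_rng(3))
        forbidden = {(a.pair, a.pattern) for a in problem.audit}
        expected = set()
        for i, j in pairs:
            counts = pattern_frequencies(small_cohort, cluster.members, (i, j))
            for p, c in enumerate(counts):
                if c == 0:
                    expected.add(((int(i), int(j)), (p >> 1, p & 1)))
        assert forbidden == expected
        assert all(a.drawn_z == 0 and a.observed_frequency == 0 for a in problem.audit)

    def test_all_four_safeguard(self):
        """A pair where every member shares pattern 11 keeps 11 allowed at huge z."""
        m = make_matrix([[1, 1], [1, 1], [1, 1]])
        from logicgen.generator_core import Cluster

        cluster = Cluster(seed_row=0, members=(0, 1, 2))
        problem = build_constraints(m, cluster, [(0, 1)], 50.0, np.random.default_rng(0))
        forbidden_patterns = {a.pattern for a in problem.audit}
        assert forbidden_patterns == {(0, 0), (0, 1), (1, 0)}
        # the cluster members still satisfy the CNF
        assert clauses_satisfied(problem, m.rows[0])

    def test_matches_recount_oracle(self, small_cohort):
        """Forbidden set equals an independent recount using the recorded z draws."""
        clusters = build_clusters(small_cohort, 20)
        cluster = clusters[0]
        pairs = sample_pair_universe(30, 0.5, np.random.default_rng(4))
        sub = small_cohort.subset_sites(range(30))
        problem = build_constraints(sub, cluster, pairs, 1.0, np.random.default_rng(5))
        z_by_pair = {}
        for a in problem.audit:
            z_by_pair.setdefault(a.pair, a.drawn_z)
            assert a.drawn_z == z_by_pair[a.pair]  # one z per pair
        for a in problem.audit:
            counts = pattern_frequencies(sub, cluster.members, a.pair)
            p = 2 * a.pattern[0] + a.pattern[1]
            assert counts[p] == a.observed_frequency
            assert a.observed_frequency <= a.drawn_z
        # completeness: every (pair, pattern) with freq <= z is forbidden
        # unless it was the safeguarded maximum
        forbidden = {(a.pair, a.pattern) for a in problem.audit}
        for pair, z in z_by_pair.items():
            counts = pattern_frequencies(sub, cluster.members, pair)
            low = [p for p in range(4) if counts[p] <= z]
            missing = [
                p for p in low if (pair, (p >> 1, p & 1)) not in forbidden
            ]
            if len(low) == 4:
                assert missing == [int(counts.argmax())]
            else:
                assert missing == []

    def test_forbidden_monotone_in_z(self, small_cohort):
        """Raising every z by one can only grow the pre-safeguard forbidden set."""
        clusters = build_clusters(small_cohort, 15)
        cluster = clusters[3]
        for pair in [(0, 1), (2, 40), (10, 70)]:
            counts = pattern_frequencies(small_cohort, cluster.members, pair)
            for z in range(0, 16):
                low_z = {p for p in range(4) if counts[p] <= z}
                low_z1 = {p for p in range(4) if counts[p] <= z + 1}
                assert low_z <= low_z1


class TestSolveConstraints:
    def test_unconstrained_problem(self):
        from logicgen.generator_core import ConstraintProblem

        problem = ConstraintProblem(n_vars=5, clauses=np.empty((0, 2), dtype=np.int64))
        model = solve_constraints(problem, np.random.default_rng(0))
        assert model.shape == (5,)

    def test_forced_pair(self):
        from logicgen.generator_core import ConstraintProblem

        # forbid 01, 10, 11 at sites (0, 1)
        clauses = np.array([[1, -2], [-1, 2], [-1, -2]])
        problem = ConstraintProblem(n_vars=5, clauses=clauses)
        model = solve_constraints(problem, np.random.default_rng(0))
        assert model[0] == 0 and model[1] == 0

    def test_random_problem_passes_checker(self, small_cohort):
        from logicgen.generator_core import Cluster

        cluster = Cluster(seed_row=0, members=tuple(range(20)))
        sub = small_cohort.subset_sites(range(50))
        pairs = sample_pair_universe(50, 0.0, np.random.default_rng(6))
        problem = build_constraints(sub, cluster, pairs, 0.5, np.random.default_rng(7))
        model = solve_constraints(problem, np.random.default_rng(8))
        if model is not None:
            assert clauses_satisfied(problem, model)


class TestGenerate:
    def test_zero_count(self, small_cohort):
        params = GenomatorParams(cluster_size=10, seed=0)
        synth, log = generate(small_cohort, params, 0)
        assert synth.rows.shape == (0, small_cohort.n_sites)
        assert log == []

    def test_deterministic_under_seed(self, small_cohort):
        params = GenomatorParams(cluster_size=10, exclusion_prob=0.5,
                                 privacy_alpha=0.5, seed=11)
        a, log_a = generate(small_cohort, params, 4)
        b, log_b = generate(small_cohort, params, 4)
        assert np.array_equal(a.rows, b.rows)
        assert log_a == log_b

    def test_no_hallucinated_pairs_at_strictest_setting(self, small_cohort):
        """alpha=0, L=0: every output pairwise pattern occurs in its source cluster."""
        params = GenomatorParams(cluster_size=20, exclusion_prob=0.0,
                                 privacy_alpha=0.0, seed=3)
        synth, log = generate(small_cohort, params, 2)
        clusters = build_clusters(small_cohort, 20)
        for k, rec in enumerate(log):
            members = clusters[rec.cluster_seed_row].members
            x = small_cohort.rows[list(members)]
            y = synth.rows[k]
            for i in range(small_cohort.n_sites):
                for j in range(i + 1, small_cohort.n_sites):
                    assert ((x[:, i] == y[i]) & (x[:, j] == y[j])).any()

    def test_cluster_too_large_rejected(self, small_cohort):
        params = GenomatorParams(cluster_size=1000)
        with pytest.raises(ValueError):
            generate(small_cohort, params, 1)

    def test_members_satisfy_alpha_zero_cnf(self, small_cohort):
        """Satisfiability guarantee: each member is a model of its cluster's CNF."""
        clusters = build_clusters(small_cohort, 12)
        pairs = sample_pair_universe(small_cohort.n_sites, 0.0, np.random.default_rng(9))
        for cluster in clusters[:10]:
            problem = build_constraints(small_cohort, cluster, pairs, 0.0,
                                        np.random.default_rng(10), collect_audit=False)
            for m_idx in cluster.members:
                assert clauses_satisfied(problem, small_cohort.rows[m_idx])
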