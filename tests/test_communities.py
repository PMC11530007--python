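"""K-S similarity, modularity communities, bootstrap CIs, DoLP quartile structure."""

import itertools

import numpy as np
import pytest
from scipy.stats import ks_2samp

from polaridar.communities import (
    RANGE_BIN_EDGES,
    TIME_BIN_EDGES,
    bootstrap_ci,
    cluster_profiles,
    detect_communities,
    dolp_summaries,
    ks_similarity,
    modularity_score,
    observation_quartiles,
    quartile_flows,
    shared_quartile_fraction,
)
from polaridar.diversity import ClusterSolution

from .oracles import max_modularity_bruteforce


def _solution(labels):
    return ClusterSolution(labels=np.asarray(labels), method="hca", mode="unpol")


class TestProfiles:
    def test_bin_axes(self):
        assert TIME_BIN_EDGES.size == 97  # 96 fifteen-minute bins
        assert TIME_BIN_EDGES[1] - TIME_BIN_EDGES[0] == 900.0
        assert RANGE_BIN_EDGES.size == 21  # 20 log-spaced bins, 48-427 m
        assert RANGE_BIN_EDGES[0] == pytest.approx(48.0)
        assert RANGE_BIN_EDGES[-1] == pytest.approx(427.0)

    def test_single_member_profile(self):
        sol = _solution([0, 1, 1])
        profs = cluster_profiles(sol, np.array([3600.0, 50000.0, 60000.0]),
                                 np.array([100.0, 200.0, 210.0]))
        lone = profs[0]
        assert lone.time_prob.max() == 1.0 and lone.time_prob.sum() == 1.0
        assert lone.range_prob.max() == 1.0

    def test_profiles_normalized(self, rng):
        labels = rng.integers(0, 4, 400)
        times = rng.uniform(0, 86400, 400)
        ranges = rng.uniform(48, 427, 400)
        for p in cluster_profiles(_solution(labels), times, ranges):
            assert p.time_prob.sum() == pytest.approx(1.0, abs=1e-12)
            assert p.range_prob.sum() == pytest.approx(1.0, abs=1e-12)

    def test_evening_species_mass(self, rng):
        """A cluster active only in the evening has >90% of time mass after 17:00."""
        times = np.concatenate([
            rng.normal(20.5 * 3600, 1800, 300),  # evening guild
            rng.uniform(0, 86400, 300),
        ])
        labels = np.repeat([0, 1], 300)
        profs = cluster_profiles(_solution(labels), times, np.full(600, 100.0))
        evening_bins = (TIME_BIN_EDGES[:-1] + 450.0) > 17 * 3600
        assert profs[0].time_prob[evening_bins].sum() > 0.9


class TestKSSimilarity:
    def test_identical_samples_and_symmetry(self, rng):
        stamps = np.concatenate([rng.normal(0, 1, 40)] * 2 + [rng.normal(5, 1, 40)])
        labels = np.repeat([0, 1, 2], 40)
        sim = ks_similarity(_solution(labels), stamps)
        assert sim.values[0, 1] == pytest.approx(1.0)  # identical member stamps
        assert np.allclose(sim.values, sim.values.T)
        assert np.all(np.diag(sim.values) == 1.0)
        assert sim.values[0, 2] < 0.01

    def test_small_sample_exact_pvalue_matches_enumeration(self, rng):
        """Exact two-sample K-S p-value equals exhaustive label permutation."""
        x = rng.normal(0, 1, 4)
        y = rng.normal(0.8, 1, 5)
        d_obs = ks_2samp(x, y, method="exact").statistic

        def ks_stat(a, b):
            allv = np.sort(np.concatenate([a, b]))
            fa = np.searchsorted(np.sort(a), allv, side="right") / a.size
            fb = np.searchsorted(np.sort(b), allv, side="right") / b.size
            return np.max(np.abs(fa - fb))

        pooled = np.concatenate([x, y])
        count = total = 0
        for combo in itertools.combinations(range(9), 4):
            a = pooled[list(combo)]
            b = pooled[[i for i in range(9) if i not in combo]]
            total += 1
            if ks_stat(a, b) >= d_obs - 1e-12:
                count += 1
        p_enum = count / total
        stamps = np.concatenate([x, y])
        labels = np.repeat([0, 1], [4, 5])
        sim = ks_similarity(_solution(labels), stamps)
        assert sim.values[0, 1] == pytest.approx(p_enum, abs=1e-9)

    def test_degenerate_cluster_skipped(self, rng):
        stamps = np.concatenate([rng.normal(0, 1, 30), rng.normal(4, 1, 30), [0.0]])
        labels = np.array([0] * 30 + [1] * 30 + [2])
        with pytest.warns(RuntimeWarning, match="fewer than"):
            sim = ks_similarity(_solution(labels), stamps)
        assert sim.values.shape == (2, 2)


class TestCommunities:
    def _block_matrix(self):
        A = np.full((8, 8), 0.01)
        A[:4, :4] = 0.9
        A[4:, 4:] = 0.9
        np.fill_diagonal(A, 1.0)
        return A

    def test_two_blocks_recovered_at_global_optimum(self):
        A = self._block_matrix()
        part = detect_communities(A)
        groups = [part.assignment[i] for i in range(8)]
        assert len(set(groups[:4])) == 1 and len(set(groups[4:])) == 1
        assert groups[0] != groups[4]
        assert part.modularity == pytest.approx(max_modularity_bruteforce(A), abs=1e-9)

    def test_uniform_matrix_single_community(self):
        part = detect_communities(np.ones((6, 6)))
        assert set(part.assignment.values()) == {0}
        assert part.modularity <= 1e-9

    def test_all_zero_matrix(self):
        part = detect_communities(np.zeros((5, 5)))
        assert part.modularity == 0.0
        assert set(part.assignment.values()) == {0}

    def test_exact_equals_bruteforce_random_instances(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 9))
            A = rng.uniform(0, 1, (n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            part = detect_communities(A, method="exact")
            assert part.modularity == pytest.approx(
                max_modularity_bruteforce(A), abs=1e-9
            )

    def test_louvain_deterministic_and_finds_blocks(self):
        A = self._block_matrix()
        p1 = detect_communities(A, method="louvain")
        p2 = detect_communities(A, method="louvain")
        assert p1.assignment == p2.assignment
        assert p1.modularity == pytest.approx(max_modularity_bruteforce(A), abs=1e-9)

    def test_modularity_score_consistency(self, rng):
        A = rng.uniform(0, 1, (10, 10))
        A = (A + A.T) / 2
        labels = rng.integers(0, 3, 10)
        # single community of everything scores exactly zero
        assert modularity_score(A, np.zeros(10)) == pytest.approx(0.0, abs=1e-12)
        assert -1.0 <= modularity_score(A, labels) <= 1.0


class TestBootstrap:
    def test_constant_sample_degenerate_ci(self):
        mean, lo, hi = bootstrap_ci(np.full(20, 3.5), np.mean, seed=0)
        assert mean == lo == hi == 3.5

    def test_single_resample(self, rng):
        values = rng.normal(0, 1, 15)
        mean, lo, hi = bootstrap_ci(values, np.mean, n_boot=1, seed=3)
        assert lo == pytest.approx(hi)
        assert mean == pytest.approx(lo)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.array([]), np.mean)

    def test_deterministic(self, rng):
        v = rng.normal(0, 1, 50)
        assert bootstrap_ci(v, np.mean, seed=7) == bootstrap_ci(v, np.mean, seed=7)


class TestDoLPSummaries:
    def test_whole_pool_cluster_not_significant(self, rng):
        dolp = rng.uniform(0.2, 0.8, 200)
        sol = _solution(np.zeros(200, dtype=int))
        (s,) = dolp_summaries(sol, dolp, n_boot=300, seed=1)
        assert not s.significant
        assert s.ci_low <= s.mean_dolp <= s.ci_high

    def test_glossy_cluster_significant_and_q1(self, rng):
        dolp = np.concatenate([rng.normal(0.9, 0.02, 60), rng.normal(0.45, 0.1, 540)])
        labels = np.concatenate([np.zeros(60, int), rng.integers(1, 6, 540)])
        summaries = dolp_summaries(_solution(labels), np.clip(dolp, 0, 1),
                                   n_boot=500, seed=2)
        glossy = next(s for s in summaries if s.cluster_id == 0)
        assert glossy.significant
        assert glossy.quartile == 1

    def test_four_clusters_one_per_quartile(self, rng):
        means = [0.9, 0.6, 0.4, 0.1]
        dolp = np.concatenate([rng.normal(m, 0.01, 50) for m in means])
        labels = np.repeat(np.arange(4), 50)
        summaries = dolp_summaries(_solution(labels), np.clip(dolp, 0, 1),
                                   n_boot=200, seed=3)
        assert [s.quartile for s in summaries] == [1, 2, 3, 4]

    def test_shuffled_labels_rarely_significant(self, rng):
        """Random clusters of real observations: < 10% spurious significance."""
        dolp = rng.uniform(0.1, 0.9, 600)
        labels = rng.integers(0, 20, 600)  # labels independent of dolp
        summaries = dolp_summaries(_solution(labels), dolp, n_boot=400, seed=4)
        frac = np.mean([s.significant for s in summaries])
        assert frac < 0.10

    def test_singleton_flagged(self, rng):
        dolp = rng.uniform(0, 1, 21)
        labels = np.array([0] + [1] * 20)
        summaries = dolp_summaries(_solution(labels), dolp, n_boot=100, seed=5)
        assert summaries[0].degenerate


class TestQuartileFlows:
    def test_identity_is_diagonal(self, rng):
        q = rng.integers(1, 5, 400)
        table, non_adj = quartile_flows(q, q)
        assert np.all(table == np.diag(np.diag(table)))
        assert non_adj == 0.0
        shared = shared_quartile_fraction([q, q, q])
        assert all(v == pytest.approx(1.0) for v in shared.values())

    def test_row_sums_conserved(self, rng):
        qa, qb = rng.integers(1, 5, 500), rng.integers(1, 5, 500)
        table, _ = quartile_flows(qa, qb)
        for k in range(4):
            assert table[k].sum() == np.sum(qa == k + 1)

    def test_independent_assignments_off_diagonal_mass(self):
        rng = np.random.default_rng(1234)
        qa, qb = rng.integers(1, 5, 4000), rng.integers(1, 5, 4000)
        table, _ = quartile_flows(qa, qb)
        off = 1.0 - np.trace(table) / table.sum()
        assert abs(off - 0.75) < 0.03

    def test_universe_mismatch(self):
        with pytest.raises(ValueError):
            quartile_flows(np.ones(3, int), np.ones(4, int))

    def test_quartile_inheritance(self, rng):
        dolp = np.concatenate([rng.normal(m, 0.01, 30) for m in (0.9, 0.6, 0.4, 0.1)])
        labels = np.repeat(np.arange(4), 30)
        sol = _solution(labels)
        summaries = dolp_summaries(sol, np.clip(dolp, 0, 1), n_boot=100, seed=6)
        q = observation_quartiles(sol, summaries)
        assert np.array_equal(q, np.repeat([1, 2, 3, 4], 30))
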