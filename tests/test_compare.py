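"""Network agreement: graph correlation, QAP, bootstrap, differential
networks, degree diagnostics."""

import networkx as nx
import numpy as np
import pytest

from netconsist import (SyntheticScenario, bootstrap_consistency,
                        compare_correlations, degree_distribution,
                        degree_variance_profile, differential_network,
                        graph_correlation, multi_network_intersection,
                        qap_test, simulate)


def _graph(nodes, edges):
    G = nx.Graph()
    G.add_nodes_from(nodes)
    G.add_edges_from(edges)
    return G


class TestGraphCorrelation:
    def test_identical_networks(self):
        A = _graph(range(5), [(0, 1), (2, 3)])
        assert graph_correlation(A, A) == pytest.approx(1.0)

    def test_complement_gives_minus_one(self):
        A = _graph(range(4), [(0, 1), (2, 3)])
        B = nx.complement(A)
        assert graph_correlation(A, B) == pytest.approx(-1.0)

    def test_four_node_hand_value(self):
        # dyads (12,13,14,23,24,34): a=(1,1,0,0,0,0), b=(1,0,0,0,0,1)
        A = _graph([1, 2, 3, 4], [(1, 2), (1, 3)])
        B = _graph([1, 2, 3, 4], [(1, 2), (3, 4)])
        assert graph_correlation(A, B) == pytest.approx(0.25)

    def test_symmetric_and_relabel_invariant(self, rng):
        for _ in range(10):
            A = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(2**31)))
            B = nx.gnp_random_graph(8, 0.4, seed=int(rng.integers(2**31)))
            if not (0 < A.number_of_edges() < 28
                    and 0 < B.number_of_edges() < 28):
                continue
            r = graph_correlation(A, B)
            assert graph_correlation(B, A) == pytest.approx(r)
            perm = dict(zip(range(8), rng.permutation(8).tolist()))
            assert graph_correlation(
                nx.relabel_nodes(A, perm),
                nx.relabel_nodes(B, perm)) == pytest.approx(r)

    def test_mismatched_nodes_rejected(self):
        with pytest.raises(ValueError):
            graph_correlation(_graph([1, 2, 3], [(1, 2)]),
                              _graph([1, 2, 4], [(1, 2)]))

    def test_degenerate_graphs_rejected(self):
        with pytest.raises(ValueError):
            graph_correlation(_graph([1, 2, 3], []),
                              _graph([1, 2, 3], [(1, 2)]))


class TestQAP:
    def test_exact_path_graph_automorphisms(self):
        # identical path graphs: only identity and reversal reach corr 1
        P = nx.path_graph(5)
        assert qap_test(P, P, exact=True) == pytest.approx(2 / 120)

    def test_seeded_determinism(self):
        A = nx.gnp_random_graph(10, 0.3, seed=1)
        B = nx.gnp_random_graph(10, 0.3, seed=2)
        assert qap_test(A, B, 199, seed=5) == qap_test(A, B, 199, seed=5)

    def test_pvalue_bounds(self):
        A = nx.gnp_random_graph(12, 0.3, seed=3)
        B = nx.gnp_random_graph(12, 0.3, seed=4)
        p = qap_test(A, B, 99, seed=0)
        assert 1 / 100 <= p <= 1.0


class TestBootstrap:
    def test_identical_datasets_give_degenerate_ci(self, chain_data):
        expr = chain_data.continuous.iloc[:, :60]
        cov = chain_data.covariates.iloc[:60]
        res = bootstrap_consistency(
            expr, cov, "continuous", expr.copy(), cov.copy(), "continuous",
            target_edges=9, n_boot=10, seed=0)
        assert res.correlation == pytest.approx(1.0)
        assert res.ci[0] == pytest.approx(1.0, abs=1e-9)
        assert res.ci[1] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(res.replicates, 1.0)

    def test_seeded_determinism(self, chain_data):
        expr_a = chain_data.counts.iloc[:, :50]
        cov_a = chain_data.covariates.iloc[:50]
        expr_b = chain_data.continuous.iloc[:, 50:120]
        cov_b = chain_data.covariates.iloc[50:120]
        kw = dict(target_edges=9, n_boot=8, seed=11)
        r1 = bootstrap_consistency(expr_a, cov_a, "counts",
                                   expr_b, cov_b, "continuous", **kw)
        r2 = bootstrap_consistency(expr_a, cov_a, "counts",
                                   expr_b, cov_b, "continuous", **kw)
        assert r1.ci == r2.ci
        assert np.array_equal(r1.replicates, r2.replicates)

    def test_ci_covers_full_data_estimate(self):
        """Percentile bootstrap CI covers the full-data graph correlation in
        most outer replicates.  The comparison is the confounder-correction
        design: corrected vs uncorrected analyses of one dataset, with the
        resample shared between the two arms so the replication noise of the
        two-step procedure largely cancels."""
        covered = 0
        outer = 10
        for k in range(outer):
            data = simulate(SyntheticScenario(p=15, n=100, seed=300 + k,
                                              partial_corr_strength=0.3))
            res = bootstrap_consistency(
                data.continuous, data.covariates, "continuous",
                data.continuous, data.covariates, "continuous",
                target_edges=20, n_boot=40, seed=k,
                correct_confounders=True, correct_confounders_b=False,
                share_resamples=True)
            if res.ci[0] - 1e-12 <= res.correlation <= res.ci[1] + 1e-12:
                covered += 1
        assert covered >= 8

    def test_paired_comparison_formula(self):
        from netconsist.compare import ComparisonResult
        a = ComparisonResult("x", "y", 0.5,
                             replicates=np.linspace(0.4, 0.6, 99),
                             resample_signature="s")
        b = ComparisonResult("x", "y", 0.3,
                             replicates=np.linspace(0.1, 0.3, 99),
                             resample_signature="s")
        # every paired difference positive, B=99 -> p = 1/100
        assert compare_correlations(a, b) == pytest.approx(0.01)
        # identical streams -> p ~ 1
        assert compare_correlations(a, a) == pytest.approx(1.0)

    def test_unpaired_streams_rejected(self):
        from netconsist.compare import ComparisonResult
        a = ComparisonResult("x", "y", 0.5, replicates=np.ones(10),
                             resample_signature="s1")
        b = ComparisonResult("x", "y", 0.5, replicates=np.ones(10),
                             resample_signature="s2")
        with pytest.raises(ValueError):
            compare_correlations(a, b)

    def test_paired_null_calibration(self, rng):
        """Percentile-bootstrap duality: when the bootstrap replicate
        differences are centred on an observed difference that is itself
        null-distributed, the paired p-value is approximately uniform."""
        from netconsist.compare import ComparisonResult
        from scipy import stats
        pvals = []
        for _ in range(300):
            observed_diff = rng.normal()
            d = rng.normal(loc=observed_diff, scale=1.0, size=199)
            a = ComparisonResult("x", "y", 0.0, replicates=d,
                                 resample_signature="s")
            b = ComparisonResult("x", "y", 0.0, replicates=np.zeros(199),
                                 resample_signature="s")
            pvals.append(compare_correlations(a, b))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestSetOperations:
    def test_differential_basic(self):
        A = _graph([1, 2, 3], [(1, 2), (1, 3)])
        B = _graph([1, 2, 3], [(1, 3)])
        assert set(differential_network(A, B).edges) == {(1, 2)}
        assert differential_network(A, A).number_of_edges() == 0

    def test_partition_invariant(self, rng):
        for _ in range(50):
            A = nx.gnp_random_graph(10, 0.3, seed=int(rng.integers(2**31)))
            B = nx.gnp_random_graph(10, 0.3, seed=int(rng.integers(2**31)))
            ab = {tuple(sorted(e)) for e in differential_network(A, B).edges}
            ba = {tuple(sorted(e)) for e in differential_network(B, A).edges}
            both = {tuple(sorted(e))
                    for e in multi_network_intersection(A, B).edges}
            ea = {tuple(sorted(e)) for e in A.edges}
            eb = {tuple(sorted(e)) for e in B.edges}
            assert ab == ea - eb
            assert ab | ba | both == ea | eb

    def test_intersection_identity_and_disjoint(self):
        A = _graph(range(4), [(0, 1), (2, 3)])
        assert set(multi_network_intersection(A, A, A).edges) == set(A.edges)
        B = _graph(range(4), [(0, 2)])
        assert multi_network_intersection(A, B).number_of_edges() == 0


class TestDegreeDiagnostics:
    def test_regular_graph_flagged_degenerate(self):
        G = nx.cycle_graph(6)
        prof = degree_variance_profile(G, {i: float(i + 1) for i in G.nodes})
        assert prof.degenerate and prof.spearman == 0.0

    def test_perfect_rank_agreement(self):
        G = nx.Graph()
        G.add_nodes_from(range(5))
        G.add_edges_from([(0, 1), (0, 2), (0, 3), (1, 2)])
        variances = {n: float(1 + G.degree(n)) for n in G.nodes}
        prof = degree_variance_profile(G, variances)
        assert prof.spearman == pytest.approx(1.0)

    def test_degree_distribution_star_and_empty(self):
        star = nx.star_graph(4)
        dist = degree_distribution(star)
        assert dist.max_degree == 4
        assert dist.counts.to_dict() == {1: 4, 4: 1}
        empty = _graph(range(3), [])
        d0 = degree_distribution(empty)
        assert d0.max_degree == 0 and d0.gini == 0.0

    def test_gini_orders_tail_heaviness(self):
        from netconsist import degree_gini
        assert degree_gini(np.array([4, 1, 1, 1, 1])) > degree_gini(
            np.array([2, 2, 2, 1, 1]))
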