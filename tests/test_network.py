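"""Differential product-correlation network: pair statistics, edge criteria,
validation diagnostics and the degree-ranked hub predictor."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import _oracles as oracles
from agingaccel import (SimulationSpec, build_network, build_reference_pools,
                        compute_aging_scores, degree_distribution_fit,
                        degree_ranking, fisher_overlap_test, generate_cohort,
                        hypergeom_pvalue, pair_product_correlations,
                        zscore_normalize)
from agingaccel.network import AccelNetwork, edge_table
from conftest import make_matrix


def _scores_for(m, values):
    return pd.Series(np.asarray(values, dtype=float), index=m.sample_ids)


def _records(gene_pairs, r_ad, p_ad, r_n, p_n):
    ad = pd.DataFrame([{"gene_i": i, "gene_j": j, "r": ra, "p": pa}
                       for (i, j), ra, pa in zip(gene_pairs, r_ad, p_ad)])
    n = pd.DataFrame([{"gene_i": i, "gene_j": j, "r": rn, "p": pn}
                      for (i, j), rn, pn in zip(gene_pairs, r_n, p_n)])
    return ad.rename(columns={"r": "r", "p": "p"}), n


class TestPairCorrelations:
    def test_product_equal_to_score_gives_r_one(self):
        vals = np.array([[1.0, 2.0, 3.0, 4.0, 5.0],
                         [1.0, 1.0, 1.0, 1.0, 1.0]])
        m = make_matrix(vals)
        recs = pair_product_correlations(m, _scores_for(m, vals[0]))
        assert recs.iloc[0]["r"] == pytest.approx(1.0)
        assert recs.iloc[0]["p"] < 1e-6

    def test_orthogonalized_product_gives_r_zero(self):
        prod = np.array([1.0, -1.0, 1.0, -1.0])
        score = np.array([1.0, 1.0, -1.0, -1.0])
        m = make_matrix(np.vstack([prod, np.ones(4)]))
        recs = pair_product_correlations(m, _scores_for(m, score))
        assert abs(recs.iloc[0]["r"]) < 1e-12

    def test_matches_textbook_pearson_on_fixture(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(4, 5))
        m = make_matrix(vals)
        s = rng.normal(size=5)
        recs = pair_product_correlations(m, _scores_for(m, s))
        for row in recs.itertuples():
            u = vals[m.genes.index(row.gene_i)] * vals[m.genes.index(row.gene_j)]
            assert row.r == pytest.approx(oracles.pearson_r(u, s), abs=1e-12)

    def test_zero_variance_product_excluded_with_warning(self):
        vals = np.array([[0.0, 0.0, 0.0, 0.0], [1.0, 2.0, 3.0, 4.0],
                         [2.0, 1.0, 4.0, 3.0]])
        m = make_matrix(vals)
        with pytest.warns(UserWarning, match="zero-variance"):
            recs = pair_product_correlations(m, _scores_for(m, [1, 2, 3, 4.0]))
        # pairs involving the all-zero gene are gone
        assert set(zip(recs.gene_i, recs.gene_j)) == {("G2", "G3")}

    def test_chunked_equals_dense(self):
        rng = np.random.default_rng(1)
        g, n = 100, 40
        vals = rng.normal(size=(g, n))
        m = make_matrix(vals)
        s = rng.normal(size=n)
        recs = pair_product_correlations(m, _scores_for(m, s), chunk_rows=7)
        dense = oracles.dense_pair_product_correlations(vals, m.genes, s)
        assert len(recs) == len(dense) == g * (g - 1) // 2
        for row in recs.itertuples():
            assert row.r == pytest.approx(dense[(row.gene_i, row.gene_j)],
                                          abs=1e-10)


class TestBuildNetwork:
    GENES = ["A", "B", "C", "D"]

    def test_all_criteria_met_keeps_edge(self):
        ad, n = _records([("A", "B")], [0.4], [0.01], [-0.3], [0.01])
        net = build_network(ad, n, self.GENES)
        assert net.edge_set == {("A", "B")}

    def test_same_sign_rejected(self):
        ad, n = _records([("A", "B")], [0.4], [0.01], [0.3], [0.01])
        net = build_network(ad, n, self.GENES)
        assert net.edge_set == set()

    @pytest.mark.parametrize("p_ad,p_n", [(0.2, 0.01), (0.01, 0.2)])
    def test_p_threshold_applies_to_both_conditions(self, p_ad, p_n):
        ad, n = _records([("A", "B")], [0.4], [p_ad], [-0.3], [p_n])
        assert build_network(ad, n, self.GENES).edge_set == set()

    def test_fdr_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        pairs = [(f"g{i}", f"g{j}") for i in range(10) for j in range(i + 1, 10)]
        r_ad = rng.uniform(0.1, 0.9, len(pairs))
        r_n = -rng.uniform(0.1, 0.9, len(pairs))
        p = rng.uniform(0, 0.2, len(pairs))
        ad, n = _records(pairs, r_ad, p, r_n, p)
        genes = sorted({g for pr in pairs for g in pr})
        sizes = [len(build_network(ad, n, genes, fdr_threshold=f).edge_set)
                 for f in (0.05, 0.1, 0.2, 0.5)]
        assert sizes == sorted(sizes)

    def test_condition_swap_symmetry(self):
        rng = np.random.default_rng(3)
        pairs = [("A", "B"), ("A", "C"), ("B", "C"), ("C", "D")]
        ad, n = _records(pairs, [0.5, 0.4, -0.2, 0.6], [0.01, 0.03, 0.01, 0.2],
                         [-0.5, 0.4, 0.3, -0.1], [0.02, 0.01, 0.01, 0.01])
        assert build_network(ad, n, self.GENES).edge_set == \
            build_network(n, ad, self.GENES).edge_set

    def test_mismatched_universe_is_error(self):
        ad, n = _records([("A", "B"), ("A", "C")], [0.4, 0.4], [0.01, 0.01],
                         [-0.3, -0.3], [0.01, 0.01])
        with pytest.raises(ValueError, match="universes"):
            build_network(ad, n.iloc[:1], self.GENES)

    def test_planted_edges_recovered_on_synthetic_cohort(self):
        spec = SimulationSpec(n_genes=300, n_samples_normal=300, n_samples_ad=300,
                              n_aging_markers=10, n_ad_markers=10,
                              n_planted_edges=20, seed=17)
        m, truth = generate_cohort(spec)
        m = zscore_normalize(m)
        pools = build_reference_pools(m, truth.aging_markers)
        scores = compute_aging_scores(m, pools)["atan"]
        recs = {dx: pair_product_correlations(m.where(m.samples.diagnosis == dx),
                                              scores)
                for dx in ("AD", "normal")}
        net = build_network(recs["AD"], recs["normal"], m.genes)
        planted = set(truth.planted_edges)
        recovered = len(net.edge_set & planted) / len(planted)
        assert recovered >= 0.8
        # null pairs: neither gene carries any planted structure
        structured = (set(truth.aging_markers) | set(truth.ad_markers)
                      | {g for e in truth.planted_edges for g in e})
        null_genes = [g for g in m.genes if g not in structured]
        null_universe = len(null_genes) * (len(null_genes) - 1) // 2
        null_edges = sum(1 for e in net.edge_set
                         if e[0] not in structured and e[1] not in structured)
        assert null_edges / null_universe <= 0.2

    def test_edge_table_round_trips_statistics(self):
        ad, n = _records([("A", "B")], [0.4], [0.01], [-0.3], [0.02])
        net = build_network(ad, n, self.GENES)
        tab = edge_table(net)
        assert tab.loc[0, "r_ad"] == 0.4 and tab.loc[0, "r_normal"] == -0.3


class TestFisherOverlap:
    def _net(self, edges, genes):
        g = nx.Graph()
        g.add_edges_from(edges)
        return AccelNetwork(graph=g, genes=genes)

    def test_identical_networks_are_enriched(self):
        genes = [f"g{i}" for i in range(20)]
        edges = [("g0", "g1"), ("g2", "g3"), ("g4", "g5"), ("g6", "g7"),
                 ("g8", "g9")]
        res = fisher_overlap_test(self._net(edges, genes), self._net(edges, genes))
        assert res["p"] < 1e-6

    def test_disjoint_edge_sets_near_one(self):
        genes = [f"g{i}" for i in range(30)]
        a = self._net([("g0", "g1"), ("g2", "g3")], genes)
        b = self._net([("g4", "g5"), ("g6", "g7")], genes)
        assert fisher_overlap_test(a, b)["p"] > 0.9

    def test_table_matches_hypergeometric_tail(self):
        # a=3, b=1, c=1, d=15 -> one-sided p = P(X >= 3) with N=20, M=4, n=4
        genes = [f"g{i}" for i in range(20)]

        class Fake(AccelNetwork):
            pass
        from scipy.stats import fisher_exact
        _, p = fisher_exact([[3, 1], [1, 15]], alternative="greater")
        assert p == pytest.approx(hypergeom_pvalue(20, 4, 4, 3), abs=1e-12)

    def test_empty_network_is_error(self):
        genes = [f"g{i}" for i in range(10)]
        a = self._net([("g0", "g1")], genes)
        b = self._net([], genes)
        with pytest.raises(ValueError, match="at least one edge"):
            fisher_overlap_test(a, b)


class TestDegreeDistribution:
    def test_exact_power_law_fixture_gives_minus_one(self):
        # counts proportional to d^-2 over degrees {1,2,3,6}
        seq = [6] + [3] * 4 + [2] * 9 + [1] * 36
        g = nx.havel_hakimi_graph(seq)
        net = AccelNetwork(graph=g, genes=[str(n) for n in g.nodes])
        fit = degree_distribution_fit(net)
        np.testing.assert_allclose(fit["probabilities"],
                                   [36 / 50, 9 / 50, 4 / 50, 1 / 50])
        assert fit["loglog_pearson_r"] == pytest.approx(-1.0, abs=1e-9)

    def test_uniform_degree_graph_is_error(self):
        g = nx.cycle_graph(10)
        net = AccelNetwork(graph=g, genes=[str(n) for n in g.nodes])
        with pytest.raises(ValueError, match="distinct degree"):
            degree_distribution_fit(net)

    def test_preferential_attachment_is_strongly_log_linear(self):
        g = nx.barabasi_albert_graph(1000, 2, seed=0)
        net = AccelNetwork(graph=g, genes=list(g.nodes))
        fit = degree_distribution_fit(net)
        assert fit["loglog_pearson_r"] <= -0.8
        # oracle: direct correlation computation on the same points
        expected = oracles.pearson_r(np.log10(fit["degrees"]),
                                     np.log10(fit["probabilities"]))
        assert fit["loglog_pearson_r"] == pytest.approx(expected, abs=1e-12)


class TestHubPredictor:
    def test_degree_ranking_is_deterministic_under_shuffle(self):
        g = nx.Graph([("B", "C"), ("A", "B"), ("B", "D"), ("C", "D")])
        net1 = AccelNetwork(graph=g, genes=["A", "B", "C", "D", "E"])
        net2 = AccelNetwork(graph=g, genes=["E", "D", "C", "B", "A"])
        r1, r2 = degree_ranking(net1), degree_ranking(net2)
        assert r1.genes == r2.genes
        assert r1.genes[0] == "B"            # degree 3
        assert r1.genes[1:3] == ["C", "D"]   # tie at 2, lexicographic
        assert r1.genes[-1] == "E"           # isolated gene ranked last

    def test_hub_predictor_composes_with_predictor_machinery(self, small_cohort):
        from agingaccel import hub_predictor, split_cohort, task_labels
        m, truth = small_cohort
        m = zscore_normalize(m)
        pools = build_reference_pools(m, truth.aging_markers)
        scores = compute_aging_scores(m, pools)["atan"]
        recs = {dx: pair_product_correlations(m.where(m.samples.diagnosis == dx),
                                              scores)
                for dx in ("AD", "normal")}
        net = build_network(recs["AD"], recs["normal"], m.genes)
        train, test = split_cohort(m, "disease", seed=1)
        res = hub_predictor(net, train, test, task_labels(train, "disease"),
                            task_labels(test, "disease"), top_models=10,
                            folds=5, seed=1)
        assert 0.0 <= res["auc"] <= 1.0
        assert set(res["panel"]) <= set(m.genes)
        # hubs attach to disease-relevant genes, so the predictor beats chance
        assert res["auc"] > 0.5
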