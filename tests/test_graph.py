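"""Graph binarisation, network measures, null models and AUC integration."""

import numpy as np
import networkx as nx
import pytest

import oracles
from conftest import complete_graph, cycle_graph, path_graph, star_graph
from msnpipe import (
    BinaryGraph,
    SparsityScheme,
    auc_over_sparsity,
    compute_feature_set,
    random_reference_networks,
    threshold_by_sparsity,
)
from msnpipe.graph import (
    GraphFeatureExtractor,
    assortativity,
    betweenness_centrality,
    characteristic_path_length,
    clustering_coefficient,
    degree_centrality,
    global_efficiency,
    local_efficiency,
    normalized_global_features,
    small_worldness,
)


def G(adj):
    return BinaryGraph(np.asarray(adj))


class TestThresholding:
    def test_edge_counts_at_canonical_levels(self, msn):
        for level in SparsityScheme().levels:
            g = threshold_by_sparsity(msn, level)
            assert g.n_edges == int(np.round(level * 68 * 67 / 2))
        assert threshold_by_sparsity(msn, 0.05).n_edges == 114  # round(113.9)

    def test_full_level_gives_complete_graph(self, msn):
        g = threshold_by_sparsity(msn, 1.0)
        assert g.n_edges == 2278

    def test_retains_highest_weights(self, msn):
        g = threshold_by_sparsity(msn, 0.1)
        w = msn.values[np.triu_indices(68, 1)]
        kept = g.adjacency[np.triu_indices(68, 1)].astype(bool)
        assert w[kept].min() >= w[~kept].max()

    def test_tie_break_deterministic_and_lexicographic(self):
        w = np.full((5, 5), 0.5)
        np.fill_diagonal(w, 1.0)
        g = threshold_by_sparsity(w, 0.3)  # round(0.3*10) = 3 of 10 equal edges
        expect = np.zeros((5, 5), dtype=int)
        for i, j in [(0, 1), (0, 2), (0, 3)]:  # first in (i, j) order
            expect[i, j] = expect[j, i] = 1
        assert np.array_equal(g.adjacency, expect)
        g2 = threshold_by_sparsity(w, 0.3)
        assert np.array_equal(g.adjacency, g2.adjacency)

    @pytest.mark.parametrize("level", [0.0, -0.1, 1.5])
    def test_invalid_level_rejected(self, msn, level):
        with pytest.raises(ValueError, match="sparsity"):
            threshold_by_sparsity(msn, level)

    def test_ge_nondecreasing_in_sparsity(self, msn):
        ge = [global_efficiency(threshold_by_sparsity(msn, s))
              for s in SparsityScheme().levels]
        assert all(b >= a - 1e-12 for a, b in zip(ge, ge[1:]))


class TestMeasuresOnToyGraphs:
    def test_degree(self):
        assert degree_centrality(G(complete_graph(4))).tolist() == [3, 3, 3, 3]
        assert degree_centrality(G(star_graph(5))).tolist() == [5, 1, 1, 1, 1, 1]
        assert degree_centrality(G(np.zeros((3, 3), int))).tolist() == [0, 0, 0]

    def test_clustering(self):
        assert clustering_coefficient(G(complete_graph(3))).tolist() == [1, 1, 1]
        assert clustering_coefficient(G(star_graph(4)))[0] == 0.0

    def test_betweenness(self):
        assert betweenness_centrality(G(path_graph(3))).tolist() == [0, 1, 0]
        bc = betweenness_centrality(G(star_graph(4)))
        assert bc[0] == 6.0  # C(4,2) pairs all route via the hub
        assert bc[1:].tolist() == [0, 0, 0, 0]  # every leaf

    def test_local_efficiency(self):
        assert local_efficiency(G(complete_graph(4))).tolist() == [1, 1, 1, 1]
        assert local_efficiency(G(star_graph(4)))[0] == 0.0
        assert local_efficiency(G(np.zeros((2, 2), int))).tolist() == [0, 0]

    def test_global_efficiency(self):
        assert global_efficiency(G(complete_graph(5))) == 1.0
        assert global_efficiency(G(path_graph(3))) == pytest.approx(5 / 6)
        assert global_efficiency(G(np.zeros((2, 2), int))) == 0.0

    def test_characteristic_path_length(self):
        assert characteristic_path_length(G(complete_graph(4))).value == 1.0
        r = characteristic_path_length(G(path_graph(3)))
        assert r.value == pytest.approx(4 / 3) and not r.fragmented
        # two disjoint edges: CPL over connected pairs only, flagged
        adj = np.zeros((4, 4), int)
        adj[0, 1] = adj[1, 0] = adj[2, 3] = adj[3, 2] = 1
        r = characteristic_path_length(G(adj))
        assert r.value == 1.0 and r.fragmented

    def test_assortativity(self):
        assert assortativity(G(star_graph(4))) == pytest.approx(-1.0)
        with pytest.warns(UserWarning, match="regular"):
            assert np.isnan(assortativity(G(cycle_graph(5))))
        assert assortativity(G(path_graph(4))) == pytest.approx(
            oracles.bf_assortativity(path_graph(4).tolist())
        )


class TestOracleAgreement:
    """Spot-check against brute force and networkx on random graphs.

    The exhaustive <=7-node sweep lives in the acceptance suite.
    """

    @pytest.mark.parametrize("seed", range(8))
    def test_random_graphs_match_both_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 12)
        adj = (rng.random((n, n)) < 0.4).astype(int)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        g = G(adj)
        nxg = g.to_networkx()
        assert np.allclose(clustering_coefficient(g),
                           [nx.clustering(nxg, i) for i in range(n)])
        assert np.allclose(betweenness_centrality(g),
                           oracles.bf_betweenness(adj.tolist()))
        assert np.allclose(local_efficiency(g), oracles.bf_local_efficiency(adj.tolist()))
        assert global_efficiency(g) == pytest.approx(oracles.bf_global_efficiency(adj.tolist()))
        assert global_efficiency(g) == pytest.approx(nx.global_efficiency(nxg))
        cpl = characteristic_path_length(g).value
        assert cpl == pytest.approx(oracles.bf_cpl(adj.tolist()), nan_ok=True)
        ast = assortativity(g)
        if not np.isnan(ast):
            assert ast == pytest.approx(nx.degree_assortativity_coefficient(nxg))


class TestRandomReferences:
    def test_degree_sequence_preserved_and_deterministic(self, msn):
        g = threshold_by_sparsity(msn, 0.15)
        randoms = random_reference_networks(g, n_random=5, seed=3)
        assert len(randoms) == 5
        deg = np.sort(degree_centrality(g))
        for r in randoms:
            assert np.array_equal(np.sort(degree_centrality(r)), deg)
            assert not np.array_equal(r.adjacency, g.adjacency)  # actually rewired
        again = random_reference_networks(g, n_random=5, seed=3)
        assert all(np.array_equal(a.adjacency, b.adjacency) for a, b in zip(randoms, again))

    def test_invalid_count_rejected(self, msn):
        with pytest.raises(ValueError, match="n_random"):
            random_reference_networks(threshold_by_sparsity(msn, 0.1), n_random=0)


class TestGlobalNormalization:
    def test_self_normalization_is_unity(self):
        adj = path_graph(6)
        adj[0, 3] = adj[3, 0] = 1
        g = G(adj)
        norm = normalized_global_features(g, [G(adj)] * 3)
        for key in ("ge", "cpl"):
            assert norm[key] == pytest.approx(1.0)

    def test_undefined_null_ast_flagged_missing(self):
        g = G(path_graph(4))
        with pytest.warns(UserWarning, match="AST"):
            norm = normalized_global_features(g, [G(cycle_graph(4))] * 2)
        assert np.isnan(norm["ast"])

    def test_hand_computed_ratio_on_toy_null_set(self):
        g = G(path_graph(4))  # GE = (1+1+1+1/2+1/2+1/3)/6... over ordered pairs
        nulls = [G(path_graph(4)), G(star_graph(3))]
        norm = normalized_global_features(g, nulls)
        ge_g = oracles.bf_global_efficiency(path_graph(4).tolist())
        ge_null = np.mean([oracles.bf_global_efficiency(path_graph(4).tolist()),
                           oracles.bf_global_efficiency(star_graph(3).tolist())])
        assert norm["ge"] == pytest.approx(ge_g / ge_null)

    def test_empty_null_set_rejected(self):
        with pytest.raises(ValueError):
            small_worldness(G(path_graph(4)), [])

    def test_er_graph_small_worldness_near_one(self):
        # a graph drawn from the same ensemble as its nulls has SW ~ 1
        rng = np.random.default_rng(0)
        n = 30
        adj = (rng.random((n, n)) < 0.25).astype(int)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        g = G(adj)
        sw = small_worldness(g, random_reference_networks(g, 50, seed=1))
        assert sw == pytest.approx(1.0, abs=0.1)

    def test_lattice_with_shortcuts_is_small_world(self):
        # Watts-Strogatz-style ring lattice with a few shortcuts: SW > 1
        wsg = nx.watts_strogatz_graph(40, 6, 0.1, seed=4)
        adj = nx.to_numpy_array(wsg).astype(int)
        g = G(adj)
        sw = small_worldness(g, random_reference_networks(g, 30, seed=2))
        assert sw > 1.3


class TestAUC:
    def test_constant_linear_and_zero_curves(self):
        scheme = SparsityScheme()
        assert auc_over_sparsity(np.full(10, 2.0), scheme) == pytest.approx(0.9)  # 0.45*2
        assert auc_over_sparsity(np.zeros(10), scheme) == 0.0
        ramp = np.linspace(0, 1, 10)
        assert auc_over_sparsity(ramp, scheme) == pytest.approx(0.225)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="levels"):
            auc_over_sparsity(np.ones(3), SparsityScheme())


class TestFeatureSet:
    def test_shapes_and_naive_recomputation(self, msn):
        scheme = SparsityScheme((0.1, 0.2, 0.3))
        fs = compute_feature_set(msn, scheme, n_random=3, seed=9)
        assert set(fs.nodal) == {"cc", "dc", "bc", "le"}
        assert all(v.shape == (68,) for v in fs.nodal.values())
        assert set(fs.global_) == {"sw", "ge", "ast", "cpl"}
        # oracle: independently loop the per-level operations and integrate
        dc_curve = np.stack([
            degree_centrality(threshold_by_sparsity(msn, s)) for s in scheme.levels
        ])
        assert np.allclose(fs.nodal["dc"], np.trapezoid(dc_curve, scheme.levels, axis=0))

    def test_extractor_dataframe_and_determinism(self, msn):
        ex = GraphFeatureExtractor(levels=(0.2, 0.4), n_random=3, random_state=0)
        df = ex.fit_transform([msn, msn])
        assert df.shape == (2, 4 * 68 + 4)
        assert "bc__lh-lateralorbitofrontal" in df.columns
        df2 = GraphFeatureExtractor(levels=(0.2, 0.4), n_random=3,
                                    random_state=0).fit_transform([msn, msn])
        assert np.allclose(df.to_numpy(), df2.to_numpy(), equal_nan=True)

    def test_tied_similarities_are_handled_deterministically(self):
        from msnpipe import MSNMatrix

        v = np.full((68, 68), 0.5)
        np.fill_diagonal(v, 1.0)
        m = MSNMatrix("ties", v)
        a = compute_feature_set(m, SparsityScheme((0.05,)), n_random=2, seed=1)
        b = compute_feature_set(m, SparsityScheme((0.05,)), n_random=2, seed=1)
        assert np.array_equal(a.nodal["dc"], b.nodal["dc"])
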