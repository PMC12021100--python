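"""Consensus association networks, Leiden communities, senescence overlay."""

import numpy as np
import pandas as pd
import pytest

from stratomics.assoc import (AssociationEdge, ConsensusNetwork, compare_to_random,
                              consensus_associations, finalize_network,
                              leiden_communities, sap_hca, senescence_overlay)
from stratomics.config import NetworkConfig
from stratomics.dpa import bh_adjust
from stratomics.layers import GeneSetCollection, LayerKind, OmicsLayer


def block_layers(rng, n=158):
    """Two correlated 4-feature blocks split across two layers + noise."""
    f, g = rng.standard_normal(n), rng.standard_normal(n)
    X = np.empty((n, 12))
    for j in range(4):
        X[:, j] = 0.95 * f + np.sqrt(1 - 0.9025) * rng.standard_normal(n)
    for j in range(4, 8):
        X[:, j] = 0.95 * g + np.sqrt(1 - 0.9025) * rng.standard_normal(n)
    for j in range(8, 12):
        X[:, j] = rng.standard_normal(n)
    ids = [f"s{i}" for i in range(n)]
    prot = OmicsLayer(LayerKind.PROTEOMICS, ids, [f"p{j}" for j in range(6)], X[:, :6])
    met = OmicsLayer(LayerKind.METABOLOMICS, ids, [f"m{j}" for j in range(6)], X[:, 6:])
    return prot, met


class TestConsensusAssociations:
    def test_resampled_equals_full_all_pairs_oracle(self, rng):
        prot, met = block_layers(rng)
        full = consensus_associations([prot, met],
                                      NetworkConfig(n_iter=1, per_layer=6), seed=1)
        resampled = consensus_associations([prot, met],
                                           NetworkConfig(n_iter=300, per_layer=4),
                                           seed=1)
        assert {(e.a, e.b) for e in full} == {(e.a, e.b) for e in resampled}

    def test_duplicated_feature_full_frequency(self, rng):
        n = 60
        ids = [f"s{i}" for i in range(n)]
        x = rng.standard_normal(n)
        vals = np.column_stack([x, x, rng.standard_normal(n)])
        layer = OmicsLayer(LayerKind.PROTEOMICS, ids, ["a", "dup", "z"], vals)
        noise = OmicsLayer(LayerKind.METABOLOMICS, ids, ["m0", "m1", "m2"],
                           rng.standard_normal((n, 3)))
        edges = consensus_associations([layer, noise],
                                       NetworkConfig(n_iter=50, per_layer=2), seed=0)
        pair = next(e for e in edges if {e.a, e.b} == {"prot:a", "prot:dup"})
        assert pair.frequency == 1.0
        assert pair.rho == pytest.approx(1.0)

    def test_too_few_samples_rejected(self, rng):
        ids = [f"s{i}" for i in range(4)]
        l = OmicsLayer(LayerKind.PROTEOMICS, ids, ["a", "b"],
                       rng.standard_normal((4, 2)))
        with pytest.raises(ValueError, match="5 samples"):
            consensus_associations([l], NetworkConfig(per_layer=2), seed=0)


class TestFinalize:
    def test_sign_routing_and_monotonicity(self, rng):
        n = 100
        ids = [f"s{i}" for i in range(n)]
        x = rng.standard_normal(n)
        vals = np.column_stack([x, -x + 0.05 * rng.standard_normal(n),
                                x + 0.05 * rng.standard_normal(n),
                                rng.standard_normal(n)])
        layer = OmicsLayer(LayerKind.PROTEOMICS, ids, ["a", "neg", "pos", "z"], vals)
        met = OmicsLayer(LayerKind.METABOLOMICS, ids, ["m0", "m1"],
                         rng.standard_normal((n, 2)))
        edges = consensus_associations([layer, met],
                                       NetworkConfig(n_iter=1, per_layer=4), seed=0)
        net = finalize_network(edges, [layer, met], final_fdr=5e-5)
        assert len(net.edges) <= len(edges)
        pairs = {(r["a"], r["b"]): r["sign"] for _, r in net.edges.iterrows()}
        assert pairs[("prot:a", "prot:neg")] == -1
        assert pairs[("prot:a", "prot:pos")] == 1
        neg_graph = net.graph("negative")
        assert neg_graph.has_edge("prot:a", "prot:neg")
        assert not neg_graph.has_edge("prot:a", "prot:pos")

    def test_empty_edges_rejected(self, rng):
        prot, met = block_layers(rng)
        with pytest.raises(ValueError, match="no consensus edges"):
            finalize_network([], [prot, met])


def clique_network(sizes, offset=0):
    edges = []
    nodes = []
    start = offset
    for s in sizes:
        members = [f"prot:q{start + i}" for i in range(s)]
        nodes.extend(members)
        for i in range(s):
            for j in range(i + 1, s):
                edges.append({"a": members[i], "b": members[j], "rho": 0.9,
                              "sign": 1, "frequency": 1.0, "fdr": 0.0})
        start += s
    node_df = pd.DataFrame({"layer": "proteomics", "regulation": "none"},
                           index=pd.Index(nodes, name="node"))
    return ConsensusNetwork(node_df, pd.DataFrame(edges))


class TestCommunities:
    def test_two_disjoint_cliques(self):
        net = leiden_communities(clique_network([40, 40]), min_size=30, seed=0)
        comms = {}
        for v, c in net.communities.items():
            comms.setdefault(c, set()).add(v)
        assert len(comms) == 2
        assert sorted(len(m) for m in comms.values()) == [40, 40]

    def test_clique_mean_degree(self):
        net = leiden_communities(clique_network([31]), min_size=30, seed=0)
        assert list(net.community_mean_degree.values()) == [30.0]
        assert net.most_central is not None

    def test_size_boundary_strictly_greater(self):
        net = leiden_communities(clique_network([30, 40]), min_size=30, seed=0)
        sizes = {}
        for v, c in net.communities.items():
            sizes[c] = sizes.get(c, 0) + 1
        assert sorted(sizes.values()) == [40]  # the size-30 community is dropped

    def test_empty_graph(self):
        empty = ConsensusNetwork(pd.DataFrame(columns=["layer", "regulation"]),
                                 pd.DataFrame(columns=["a", "b", "rho", "sign",
                                                       "frequency", "fdr"]))
        out = leiden_communities(empty, seed=0)
        assert out.communities == {} and out.most_central is None


class TestCompareToRandom:
    def test_er_graph_unremarkable_cliques_clustered(self, rng):
        import networkx as nx
        er = nx.gnm_random_graph(60, 180, seed=42)
        out_er = compare_to_random(er, n_random=100, seed=0)
        assert abs(out_er["clustering_z"]) < 3
        net = clique_network([15, 15])
        out_cl = compare_to_random(net.graph(), n_random=100, seed=0)
        assert out_cl["clustering_z"] > 3
        assert out_cl["density_z"] == 0.0


class TestSenescenceOverlay:
    def overlay_fixture(self, n_sap_sig=105, n_in=85):
        # constructed so 85/105 significant SAP sit in the central community
        sap = [f"q{i}" for i in range(120)]
        dpa = pd.DataFrame({
            "coef": 1.0,
            "fdr": [0.01] * n_sap_sig + [0.5] * (120 - n_sap_sig),
        }, index=sap)
        members = {f"prot:q{i}": 1 for i in range(n_in)}
        members.update({f"prot:x{i}": 1 for i in range(40)})   # pad community
        net = ConsensusNetwork(pd.DataFrame(columns=["layer", "regulation"]),
                               pd.DataFrame(columns=["a", "b", "rho", "sign",
                                                     "frequency", "fdr"]))
        net.communities = members
        net.community_mean_degree = {1: 10.0}
        net.most_central = 1
        sets = GeneSetCollection({"cellage": sap[:80], "csgene": sap[50:110],
                                  "sasp": sap[100:120]})
        return dpa, sets, net

    def test_fraction_reproduces_worked_example(self):
        dpa, sets, net = self.overlay_fixture()
        overlay = senescence_overlay(dpa, sets, net)
        assert len(overlay.significant) == 105
        assert overlay.in_central == 85
        assert overlay.fraction == pytest.approx(85 / 105, abs=1e-12)

    def test_all_inside_gives_one(self):
        dpa, sets, net = self.overlay_fixture(n_sap_sig=20, n_in=120)
        overlay = senescence_overlay(dpa, sets, net)
        assert overlay.fraction == 1.0

    def test_empty_significant_set_is_nan(self):
        dpa, sets, net = self.overlay_fixture(n_sap_sig=0)
        overlay = senescence_overlay(dpa, sets, net)
        assert np.isnan(overlay.fraction)

    def test_no_measured_sap_errors(self):
        dpa = pd.DataFrame({"coef": [1.0], "fdr": [0.01]}, index=["other"])
        sets = GeneSetCollection({"cellage": ["q1"]})
        net = ConsensusNetwork(pd.DataFrame(columns=["layer", "regulation"]),
                               pd.DataFrame(columns=["a", "b", "rho", "sign",
                                                     "frequency", "fdr"]))
        with pytest.raises(ValueError, match="senescence"):
            senescence_overlay(dpa, sets, net)


class TestSapHCA:
    def separated_layer(self, rng, gap=5.0):
        n = 40
        vals = rng.standard_normal((n, 10))
        vals[20:] += gap
        return OmicsLayer(LayerKind.PROTEOMICS, [f"s{i}" for i in range(n)],
                          [f"sap{j}" for j in range(10)], vals)

    def test_separated_groups_ari_one(self, rng):
        layer = self.separated_layer(rng)
        labels = [0] * 20 + [1] * 20
        out = sap_hca(layer, list(layer.feature_ids), labels)
        assert out["ari"] == pytest.approx(1.0)
        assert len(out["order"]) == 40

    def test_permuted_labels_ari_near_zero(self, rng):
        layer = self.separated_layer(rng)
        labels = rng.permutation([0] * 20 + [1] * 20)
        out = sap_hca(layer, list(layer.feature_ids), labels)
        assert abs(out["ari"]) < 0.15

    def test_too_few_features_rejected(self, rng):
        layer = self.separated_layer(rng)
        with pytest.raises(ValueError, match="2 senescence"):
            sap_hca(layer, ["sap0"], [0] * 40)


class TestSerialization:
    def test_edge_tsv_and_graphml_round_trip(self, tmp_path):
        import networkx as nx
        net = clique_network([5])
        net.write(tmp_path / "net")
        edges = pd.read_csv(tmp_path / "net_edges.tsv", sep="\t")
        assert len(edges) == 10
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert g.number_of_nodes() == 5 and g.number_of_edges() == 10
        back_weights = sorted(d["weight"] for _, _, d in g.edges(data=True))
        orig_weights = sorted(abs(r) for r in net.edges["rho"])
        np.testing.assert_allclose(back_weights, orig_weights)
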