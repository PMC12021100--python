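"""Resampling-based multi-omics consensus association network.

Per iteration a fixed number of features is sampled from every layer,
pooled, and all-pairs Spearman correlations are tested (t-approximation,
BH within the iteration).  A pair's consensus frequency is the fraction of
iterations in which both members were co-sampled AND the association was
significant; pairs reaching the vote threshold form the consensus set.
Full-data correlations are then recomputed, globally BH-adjusted, split by
sign into positive and negative networks, clustered with the Leiden
algorithm, and overlaid with senescence annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import adjusted_rand_score

from .config import NetworkConfig
from .dpa import bh_adjust
from .layers import GeneSetCollection, OmicsLayer


@dataclass
class AssociationEdge:
    a: str                      # layer-tagged node id, canonical a < b
    b: str
    frequency: float
    rho: float = float("nan")
    fdr: float = float("nan")

    @property
    def sign(self) -> int:
        return int(np.sign(self.rho))


def node_id(layer: OmicsLayer, feature: str) -> str:
    return f"{layer.layer_kind.value[:4]}:{feature}"


def _rank_standardize(values: np.ndarray) -> np.ndarray:
    """Average ranks per column, centred and scaled so the Pearson product of
    columns equals the Spearman rho."""
    ranks = np.apply_along_axis(stats.rankdata, 0, values)
    ranks -= ranks.mean(axis=0)
    norm = np.linalg.norm(ranks, axis=0)
    norm[norm == 0] = 1.0
    return ranks / norm


def _spearman_p(rho: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(rho, -0.9999999999, 0.9999999999)
    t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    return 2.0 * stats.t.sf(np.abs(t), n - 2)


def consensus_associations(layers: list[OmicsLayer], config: NetworkConfig | None = None,
                           seed: int = 0) -> list[AssociationEdge]:
    """Resampled all-pairs Spearman with within-iteration FDR and consensus
    voting over co-sampled iterations."""
    cfg = config or NetworkConfig()
    n = layers[0].n_samples
    if n < 5:
        raise ValueError("need at least 5 samples for rank correlation")
    for l in layers[1:]:
        if l.sample_ids != layers[0].sample_ids:
            raise ValueError("layers must share sample order")
    ranks = []
    names: list[str] = []
    offsets = []
    for l in layers:
        offsets.append(len(names))
        names.extend(node_id(l, f) for f in l.feature_ids)
        ranks.append(_rank_standardize(l.values))
    R = np.hstack(ranks)
    p_total = R.shape[1]
    cosampled = np.zeros((p_total, p_total), dtype=np.int32)
    significant = np.zeros((p_total, p_total), dtype=np.int32)
    rng = np.random.default_rng(seed)
    per = cfg.per_layer
    for it in range(cfg.n_iter):
        idx_parts = []
        for li, l in enumerate(layers):
            k = per
            if k > l.n_features:
                if it == 0:
                    warnings.warn(f"per_layer capped at {l.n_features} for "
                                  f"{l.layer_kind.value}", stacklevel=2)
                k = l.n_features
            idx_parts.append(offsets[li] + rng.choice(l.n_features, size=k, replace=False))
        idx = np.concatenate(idx_parts)
        sub = R[:, idx]
        C = sub.T @ sub
        iu = np.triu_indices(len(idx), k=1)
        pv = _spearman_p(C[iu], n)
        fdr = bh_adjust(pv)
        sig = fdr < cfg.fdr_within
        cosampled[np.ix_(idx, idx)] += 1
        si, sj = iu[0][sig], iu[1][sig]
        significant[idx[si], idx[sj]] += 1
        significant[idx[sj], idx[si]] += 1
    iu = np.triu_indices(p_total, k=1)
    cos = cosampled[iu]
    sig = significant[iu]
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(cos > 0, sig / np.maximum(cos, 1), 0.0)
    keep = (cos > 0) & (freq >= cfg.vote)
    edges = []
    full_rho = None
    ki, kj = iu[0][keep], iu[1][keep]
    for a_i, b_i, f in zip(ki, kj, freq[keep]):
        rho = float(R[:, a_i] @ R[:, b_i])
        a, b = names[a_i], names[b_i]
        if b < a:
            a, b = b, a
        edges.append(AssociationEdge(a, b, float(f), rho))
    return edges


@dataclass
class ConsensusNetwork:
    nodes: pd.DataFrame        # index: node id; columns: layer, regulation
    edges: pd.DataFrame        # a, b, rho, sign, frequency, fdr
    communities: dict[str, int] = field(default_factory=dict)
    community_mean_degree: dict[int, float] = field(default_factory=dict)
    most_central: int | None = None

    def graph(self, polarity: str = "both") -> nx.Graph:
        g = nx.Graph()
        for nid, row in self.nodes.iterrows():
            g.add_node(nid, **row.to_dict())
        for _, e in self.edges.iterrows():
            if polarity == "positive" and e["sign"] <= 0:
                continue
            if polarity == "negative" and e["sign"] >= 0:
                continue
            g.add_edge(e["a"], e["b"], weight=abs(float(e["rho"])),
                       rho=float(e["rho"]), sign=int(e["sign"]),
                       frequency=float(e["frequency"]))
        return g

    def write(self, prefix) -> None:
        self.edges.to_csv(f"{prefix}_edges.tsv", sep="\t", index=False)
        nx.write_graphml(self.graph(), f"{prefix}.graphml")


def finalize_network(edges: list[AssociationEdge], layers: list[OmicsLayer],
                     final_fdr: float = 5e-5,
                     dpa_results: pd.DataFrame | None = None) -> ConsensusNetwork:
    """Re-test consensus pairs on the full data and keep FDR < final_fdr;
    positive and negative associations are flagged by sign.  Nodes carry the
    differential-abundance regulation flag when results are supplied."""
    if not edges:
        raise ValueError("no consensus edges to finalize")
    n = layers[0].n_samples
    pv = _spearman_p(np.array([e.rho for e in edges]), n)
    fdr = bh_adjust(pv)
    kept = [e for e, f in zip(edges, fdr) if f < final_fdr]
    for e, f in zip(edges, fdr):
        e.fdr = float(f)
    if not kept:
        warnings.warn("all consensus edges filtered at the final FDR", stacklevel=2)
    edge_df = pd.DataFrame([{"a": e.a, "b": e.b, "rho": e.rho, "sign": e.sign,
                             "frequency": e.frequency, "fdr": e.fdr} for e in kept],
                           columns=["a", "b", "rho", "sign", "frequency", "fdr"])
    node_ids = sorted(set(edge_df["a"]) | set(edge_df["b"]))
    layer_of = {}
    for l in layers:
        for f in l.feature_ids:
            layer_of[node_id(l, f)] = l.layer_kind.value
    reg = {}
    if dpa_results is not None:
        for nid in node_ids:
            feat = nid.split(":", 1)[1]
            if feat in dpa_results.index:
                row = dpa_results.loc[feat]
                if row["fdr"] < 0.05:
                    reg[nid] = "up" if row["coef"] > 0 else "down"
    nodes = pd.DataFrame({
        "layer": [layer_of.get(nid, "unknown") for nid in node_ids],
        "regulation": [reg.get(nid, "none") for nid in node_ids],
    }, index=pd.Index(node_ids, name="node"))
    return ConsensusNetwork(nodes, edge_df)


def compare_to_random(graph: nx.Graph, n_random: int = 100, seed: int = 0) -> dict:
    """Density/clustering/degree summary against size-matched random graphs."""
    if graph.number_of_nodes() < 10:
        raise ValueError("need at least 10 nodes")
    n, m = graph.number_of_nodes(), graph.number_of_edges()
    obs_clust = nx.transitivity(graph)
    obs_density = nx.density(graph)
    degs = [d for _, d in graph.degree()]
    rng = np.random.default_rng(seed)
    rand_clust = []
    for _ in range(n_random):
        g = nx.gnm_random_graph(n, m, seed=int(rng.integers(2 ** 31)))
        rand_clust.append(nx.transitivity(g))
    mu, sd = float(np.mean(rand_clust)), float(np.std(rand_clust, ddof=1))
    z = (obs_clust - mu) / sd if sd > 0 else 0.0
    return {"density": obs_density, "clustering": obs_clust,
            "clustering_random_mean": mu, "clustering_z": float(z),
            "density_z": 0.0,  # identical by construction (same n, m)
            "mean_degree": float(np.mean(degs)), "max_degree": int(max(degs))}


def leiden_communities(network: ConsensusNetwork, min_size: int = 30,
                       seed: int = 0) -> ConsensusNetwork:
    """Leiden modularity partition; only communities with more than
    ``min_size`` members are reported.  Centrality = within-community mean
    degree; the most central community maximizes it."""
    import igraph as ig
    import leidenalg

    g = network.graph()
    if g.number_of_edges() == 0:
        network.communities = {}
        network.community_mean_degree = {}
        network.most_central = None
        return network
    nodes = list(g.nodes())
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges()]
    weights = [g[u][v]["weight"] for u, v in g.edges()]
    h = ig.Graph(n=len(nodes), edges=edges)
    part = leidenalg.find_partition(h, leidenalg.ModularityVertexPartition,
                                    weights=weights, seed=seed)
    membership = part.membership
    comm_members: dict[int, list[str]] = {}
    for v, c in zip(nodes, membership):
        comm_members.setdefault(c, []).append(v)
    reported = {c: ms for c, ms in comm_members.items() if len(ms) > min_size}
    communities = {v: c for c, ms in reported.items() for v in ms}
    mean_deg = {}
    for c, ms in reported.items():
        sub = g.subgraph(ms)
        mean_deg[c] = float(np.mean([d for _, d in sub.degree()]))
    network.communities = communities
    network.community_mean_degree = mean_deg
    network.most_central = max(mean_deg, key=lambda c: mean_deg[c]) if mean_deg else None
    return network


@dataclass
class SenescenceOverlay:
    universe: list[str]
    significant: list[str]
    in_central: int
    out_central: int

    @property
    def fraction(self) -> float:
        tot = self.in_central + self.out_central
        return self.in_central / tot if tot else float("nan")


def senescence_overlay(dpa_results: pd.DataFrame, sap_sources: GeneSetCollection,
                       network: ConsensusNetwork, fdr: float = 0.05,
                       layer_tag: str = "prot") -> SenescenceOverlay:
    """Fraction of significant senescence-associated proteins (SAP) that fall
    inside the network's most central community.

    SAP universe = union of the senescence sources intersected with measured
    proteins; significant SAP additionally pass the differential-abundance
    FDR threshold.
    """
    measured = set(dpa_results.index)
    universe = sorted(sap_sources.union() & measured)
    if not universe:
        raise ValueError("no senescence-annotated proteins measured")
    sig = [f for f in universe if dpa_results.loc[f, "fdr"] < fdr]
    central = network.most_central
    members = {v for v, c in network.communities.items() if c == central}
    in_c = sum(1 for f in sig if f"{layer_tag}:{f}" in members)
    return SenescenceOverlay(universe, sig, in_c, len(sig) - in_c)


def sap_hca(layer: OmicsLayer, sap_features: list[str], cluster_labels) -> dict:
    """Ward hierarchical clustering of samples on z-scored SAP features;
    the 2-cut labels are compared with the stratification by ARI."""
    feats = [f for f in sap_features if f in layer.feature_ids]
    if len(feats) < 2:
        raise ValueError("need at least 2 senescence-associated features")
    if layer.n_samples < 3:
        raise ValueError("need at least 3 samples")
    sub = layer.subset_features(feats)
    vals = sub.values
    sd = vals.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (vals - vals.mean(axis=0)) / sd
    link = linkage(Z, method="ward", metric="euclidean")
    cut = fcluster(link, t=2, criterion="maxclust")
    from scipy.cluster.hierarchy import leaves_list
    order = leaves_list(link).tolist()
    ari = float(adjusted_rand_score(np.asarray(cluster_labels), cut))
    return {"order": order, "labels": cut, "ari": ari}
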