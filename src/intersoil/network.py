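"""Spearman-thresholded co-occurrence networks and their topology.

Edges join OTU pairs whose all-samples Spearman correlation passes both a
magnitude threshold (|R| > r_min, default 0.6) and a significance threshold
(p < p_max, default 0.001), after a prevalence filter. Topological
properties (degree, density, clustering, modularity, path length) are
compared against Erdos-Renyi G(n, m) null ensembles matched on nodes and
edges, yielding z-scores and the small-world index
sigma = (C/C_rand)/(L/L_rand).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

from .io import InvariantError, OtuTable
from .simulate import GroundTruth


# ---------------------------------------------------------------------------
# edges
# ---------------------------------------------------------------------------

@dataclass
class EdgeList:
    """Retained co-occurrence edges with their statistics."""

    edges: pd.DataFrame       # columns: otu_i, otu_j, r, p, sign
    r_min: float
    p_max: float
    n_otus_tested: int
    skipped_constant: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.edges)


def spearman_edges(otu: OtuTable, r_min: float = 0.6, p_max: float = 0.001,
                   prevalence_min: float = 0.2,
                   use_relative: bool = True) -> EdgeList:
    """All-pairs Spearman correlation with magnitude + significance cutoffs.

    OTUs present (count > 0) in fewer than ``prevalence_min`` of samples are
    excluded before correlation; constant OTU vectors are skipped with a
    warning. Correlations run on per-sample relative abundances by default
    (``use_relative=False`` for raw counts).
    """
    if otu.counts.shape[0] < 5:
        raise InvariantError("need at least 5 samples for co-occurrence")
    if not (0.0 <= r_min <= 1.0):
        raise InvariantError("r_min must lie in [0, 1]")
    mat = otu.relative() if use_relative else otu.counts.astype(float)
    prevalence = (otu.counts > 0).mean(axis=0)
    mat = mat.loc[:, prevalence >= prevalence_min]
    constant = [c for c in mat.columns if mat[c].nunique() == 1]
    if constant:
        warnings.warn(f"{len(constant)} constant OTU vectors skipped",
                      stacklevel=2)
        mat = mat.drop(columns=constant)
    names = list(mat.columns)
    if len(names) < 2:
        return EdgeList(pd.DataFrame(
            columns=["otu_i", "otu_j", "r", "p", "sign"]),
            r_min, p_max, len(names), constant)
    rho, pval = sps.spearmanr(mat.to_numpy(dtype=float))
    rho = np.atleast_2d(rho)
    pval = np.atleast_2d(pval)
    iu = np.triu_indices(len(names), 1)
    keep = (np.abs(rho[iu]) > r_min) & (pval[iu] < p_max)
    rows = pd.DataFrame({
        "otu_i": np.asarray(names)[iu[0][keep]],
        "otu_j": np.asarray(names)[iu[1][keep]],
        "r": rho[iu][keep],
        "p": pval[iu][keep],
    })
    rows["sign"] = np.where(rows["r"] >= 0, "+", "-")
    return EdgeList(rows.reset_index(drop=True), r_min, p_max,
                    len(names), constant)


def build_graph(edges: EdgeList, otu: OtuTable | None = None) -> nx.Graph:
    """Undirected simple graph from an edge list.

    Node attributes carry the phylum when an OtuTable is supplied; OTUs
    filtered out before correlation never appear as isolated nodes.
    """
    g = nx.Graph()
    for row in edges.edges.itertuples(index=False):
        g.add_edge(row.otu_i, row.otu_j, weight=float(row.r),
                   p=float(row.p), sign=row.sign)
    if otu is not None:
        for node in g.nodes:
            g.nodes[node]["phylum"] = otu.rank_of(node, "phylum")
    return g


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass
class NetworkStats:
    n_nodes: int
    n_links: int
    average_degree: float | None
    density: float | None
    modularity: float | None
    n_communities: int | None
    average_clustering: float | None
    average_path_length: float | None   # largest connected component
    z_clustering: float | None = None
    z_path_length: float | None = None
    small_world_sigma: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def topology(g: nx.Graph) -> NetworkStats:
    """Graph-level topological property bundle.

    Modularity comes from deterministic greedy (agglomerative) modularity
    maximization; clustering is the mean local clustering coefficient over
    all nodes (0 for degree < 2); path length is averaged over the largest
    connected component.
    """
    n, m = g.number_of_nodes(), g.number_of_edges()
    if n == 0:
        return NetworkStats(0, 0, None, None, None, None, None, None)
    avg_degree = 2.0 * m / n
    density = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    clustering = nx.average_clustering(g) if n else None
    if m:
        communities = list(nx.community.greedy_modularity_communities(g))
        mod = nx.community.modularity(g, communities)
        n_comm = len(communities)
    else:
        mod, n_comm = None, None
    largest = max(nx.connected_components(g), key=len)
    sub = g.subgraph(largest)
    path = (nx.average_shortest_path_length(sub)
            if sub.number_of_nodes() > 1 else None)
    return NetworkStats(n, m, avg_degree, density, mod, n_comm,
                        clustering, path)


def null_model_compare(g: nx.Graph, n_random: int = 100,
                       seed: int | None = 0) -> NetworkStats:
    """Topology plus z-scores against Erdos-Renyi G(n, m) null ensembles.

    z = (observed - mean_null)/sd_null for clustering and path length
    (disconnected null draws use their largest component); small-world
    sigma = (C/C_rand)/(L/L_rand) with null-ensemble means.
    """
    if g.number_of_edges() < 1:
        raise InvariantError("need at least one edge for null comparison")
    stats = topology(g)
    rng = np.random.default_rng(seed)
    n, m = g.number_of_nodes(), g.number_of_edges()
    c_null, l_null = [], []
    for _ in range(n_random):
        r = nx.gnm_random_graph(n, m, seed=int(rng.integers(2 ** 31)))
        c_null.append(nx.average_clustering(r))
        comp = max(nx.connected_components(r), key=len)
        sub = r.subgraph(comp)
        if sub.number_of_nodes() > 1:
            l_null.append(nx.average_shortest_path_length(sub))
    c_null = np.asarray(c_null)
    l_null = np.asarray(l_null)

    def z(obs, null):
        if obs is None or null.size < 2:
            return None
        sd = null.std(ddof=1)
        return float((obs - null.mean()) / sd) if sd > 0 else None

    stats.z_clustering = z(stats.average_clustering, c_null)
    stats.z_path_length = z(stats.average_path_length, l_null)
    if (stats.average_clustering and stats.average_path_length
            and c_null.mean() > 0 and l_null.size and l_null.mean() > 0):
        stats.small_world_sigma = float(
            (stats.average_clustering / c_null.mean())
            / (stats.average_path_length / l_null.mean()))
    return stats


# ---------------------------------------------------------------------------
# planted-module recovery
# ---------------------------------------------------------------------------

def recover_planted_modules(otu: OtuTable, truth: GroundTruth,
                            r_min: float = 0.6, p_max: float = 0.001,
                            prevalence_min: float = 0.2) -> float | None:
    """Adjusted Rand index between detected communities and planted blocks.

    The network is built from the simulated table and communities come from
    greedy modularity maximization on the positive-association subgraph:
    modularity's null model reads an edge as affinity, and a strong negative
    correlation is evidence two taxa do *not* co-occur (under compositional
    closure, distinct blocks are necessarily anti-correlated), so negative
    edges act as antagonistic between-module links, not within-module ties.
    ARI is computed over network nodes that belong to a planted block
    (background OTUs have no true label); returns None when the graph has
    no edges on block members.
    """
    edges = spearman_edges(otu, r_min=r_min, p_max=p_max,
                           prevalence_min=prevalence_min)
    g = build_graph(edges, otu)
    nodes = [v for v in g.nodes if v in truth.block_membership]
    if not nodes or g.number_of_edges() == 0:
        return None
    positive = nx.Graph()
    positive.add_nodes_from(g.nodes)
    positive.add_edges_from((u, v) for u, v, d in g.edges(data=True)
                            if d.get("sign", "+") == "+")
    communities = list(nx.community.greedy_modularity_communities(positive))
    detected = {}
    for k, comm in enumerate(communities):
        for v in comm:
            detected[v] = k
    true_labels = [truth.block_membership[v] for v in nodes]
    found_labels = [detected[v] for v in nodes]
    return float(adjusted_rand_score(true_labels, found_labels))


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def write_network(g: nx.Graph, stats: NetworkStats, out_dir) -> list:
    """Export edges.tsv, graph.graphml and topology.json."""
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    edge_path = out_dir / "edges.tsv"
    rows = [{"otu_i": u, "otu_j": v, **d} for u, v, d in g.edges(data=True)]
    pd.DataFrame(rows).to_csv(edge_path, sep="\t", index=False)
    graphml_path = out_dir / "graph.graphml"
    nx.write_graphml(g, graphml_path)
    topo_path = out_dir / "topology.json"
    topo_path.write_text(json.dumps(stats.to_dict(), indent=2, sort_keys=True))
    return [edge_path, graphml_path, topo_path]
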