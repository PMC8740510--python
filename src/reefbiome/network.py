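"""Co-occurrence networks and keystoneness.

The network is built from pairwise Spearman correlations of OTU relative
abundances: an edge joins two OTUs when |rho| exceeds the correlation
threshold and the two-sided t-approximation p-value is below the
significance threshold (defaults |rho| > 0.8, p < 0.001, no multiple-testing
correction — a BH flag exists but is off by default).

Keystoneness of a node is the arithmetic mean of min-max-scaled degree,
(1 - betweenness centrality) and closeness centrality; the top nodes by
keystoneness whose mean relative abundance exceeds 1 per mille are the
keystone taxa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .tables import OtuTable

__all__ = [
    "filter_network_otus",
    "CooccurrenceNetwork",
    "build_network",
    "NodeTopology",
    "compute_topology",
    "min_max_scale",
    "keystoneness",
    "KeystoneRecord",
    "identify_keystones",
    "jaccard_index",
    "network_summary",
]


def filter_network_otus(table: OtuTable, min_prevalence: float = 0.5,
                        min_mean_rel_abund: float = 0.0001) -> OtuTable:
    """Keep OTUs with prevalence strictly above ``min_prevalence`` AND mean
    relative abundance strictly above ``min_mean_rel_abund``.

    Prevalence is the fraction of samples with a nonzero count.  The
    abundance floor is a required analysis choice: ``0.005`` mirrors the
    0.5% wording used for the abundant-OTU heatmaps, while ``0.0001``
    (the default here) is the magnitude compatible with networks of
    hundreds of nodes; see docs/methods.md.
    """
    prev = (table.counts > 0).mean(axis=0)
    mean_ra = table.mean_relative_abundance()
    keep = np.where((prev > min_prevalence) & (mean_ra > min_mean_rel_abund))[0]
    if keep.size == 0:
        warnings.warn("no OTU passes the network filters; empty subset",
                      stacklevel=2)
    return table.select_otus([table.otu_ids[i] for i in keep])


@dataclass
class CooccurrenceNetwork:
    """Undirected thresholded rank-correlation graph with node attributes."""

    graph: nx.Graph
    r_threshold: float
    p_threshold: float

    @property
    def nodes(self):
        return set(self.graph.nodes)

    @property
    def n_nodes(self):
        return self.graph.number_of_nodes()

    @property
    def n_edges(self):
        return self.graph.number_of_edges()

    def edge_set(self) -> set:
        return {frozenset(e) for e in self.graph.edges()}


def _spearman_matrix(x: np.ndarray):
    """All pairwise Spearman rho (mid-rank Pearson) over columns of x."""
    ranks = np.apply_along_axis(rankdata, 0, x)
    sd = ranks.std(axis=0)
    constant = sd == 0
    ranks = ranks - ranks.mean(axis=0)
    safe_sd = np.where(constant, 1.0, sd)
    z = ranks / safe_sd
    rho = (z.T @ z) / x.shape[0]
    rho = np.clip(rho, -1.0, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    return rho, constant


def _t_pvalues(rho: np.ndarray, n: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    return p


def build_network(subset: OtuTable, r_threshold: float = 0.8,
                  p_threshold: float = 0.001, keep_isolates: bool = False,
                  bh_correct: bool = False, seed=None) -> CooccurrenceNetwork:
    """Thresholded Spearman co-occurrence network on relative abundances.

    Edge rule: |rho| > r_threshold and p < p_threshold (strict).  Nodes with
    no surviving edge are dropped unless ``keep_isolates``.  Node attributes:
    mean relative abundance and phylum.  ``seed`` is accepted for signature
    stability (the t-approximation p needs no randomness).
    """
    if subset.n_samples < 4:
        raise ValueError("build_network needs at least 4 samples")
    if subset.n_otus < 2:
        raise ValueError("build_network needs at least 2 OTUs")
    x = subset.relative_abundance()
    rho, constant = _spearman_matrix(x)
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant OTU vector(s); their pairs skipped",
            stacklevel=2)
    n = subset.n_samples
    p = _t_pvalues(rho, n)
    iu = np.triu_indices(subset.n_otus, k=1)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests
        flat = p[iu]
        valid = ~np.isnan(flat)
        adj = flat.copy()
        if valid.any():
            adj[valid] = multipletests(flat[valid], method="fdr_bh")[1]
        p = p.copy()
        p[iu] = adj
        p.T[iu] = adj

    mean_ra = subset.mean_relative_abundance()
    g = nx.Graph()
    if keep_isolates:
        for j, otu in enumerate(subset.otu_ids):
            g.add_node(otu, mean_rel_abund=float(mean_ra[j]),
                       phylum=subset.phylum(otu))
    with np.errstate(invalid="ignore"):
        sel = (np.abs(rho) > r_threshold) & (p < p_threshold)
    for a, b in zip(*np.nonzero(np.triu(sel, k=1))):
        u, v = subset.otu_ids[a], subset.otu_ids[b]
        for node, j in ((u, a), (v, b)):
            if node not in g:
                g.add_node(node, mean_rel_abund=float(mean_ra[j]),
                           phylum=subset.phylum(node))
        g.add_edge(u, v, rho=float(rho[a, b]), p=float(p[a, b]),
                   sign="pos" if rho[a, b] > 0 else "neg")
    return CooccurrenceNetwork(graph=g, r_threshold=r_threshold,
                               p_threshold=p_threshold)


@dataclass
class NodeTopology:
    otu_id: str
    degree: int
    betweenness: float
    closeness: float
    scaled_degree: float = np.nan
    scaled_one_minus_betweenness: float = np.nan
    scaled_closeness: float = np.nan
    keystoneness: float = np.nan


def compute_topology(net: CooccurrenceNetwork) -> list:
    """Degree, normalized betweenness and Wasserman-Faust closeness per node.

    Betweenness is normalized by (n-1)(n-2)/2; closeness is the
    within-component value (n_c-1)/sum(d) rescaled by (n_c-1)/(n-1) so it is
    comparable across components.  Isolated nodes get 0 for both.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        return []
    btw = nx.betweenness_centrality(g, normalized=True)
    clo = nx.closeness_centrality(g, wf_improved=True)
    out = []
    for node in sorted(g.nodes()):
        out.append(NodeTopology(
            otu_id=node,
            degree=int(g.degree(node)),
            betweenness=float(btw[node]),
            closeness=float(clo[node]),
        ))
    return out


def min_max_scale(values) -> np.ndarray:
    """(x - min)/(max - min); a constant vector maps to all 0.5."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("min_max_scale needs a non-empty vector")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def keystoneness(topology: list) -> list:
    """Attach scaled components and the keystoneness score to each node.

    keystoneness = mean of min-max-scaled degree, (1 - betweenness) and
    closeness, scaled across all nodes of one network.
    """
    if not topology:
        return topology
    deg = min_max_scale([t.degree for t in topology])
    omb = min_max_scale([1.0 - t.betweenness for t in topology])
    clo = min_max_scale([t.closeness for t in topology])
    for t, a, b, c in zip(topology, deg, omb, clo):
        t.scaled_degree = float(a)
        t.scaled_one_minus_betweenness = float(b)
        t.scaled_closeness = float(c)
        t.keystoneness = float((a + b + c) / 3.0)
    return topology


@dataclass
class KeystoneRecord:
    otu_id: str
    keystoneness: float
    abundance_rank: int
    mean_rel_abund: float
    phylum: str


def identify_keystones(net: CooccurrenceNetwork, topology: list,
                       top_n: int = 10, min_abund: float = 0.001) -> list:
    """Keystone taxa: abundance floor first, then top_n by keystoneness.

    Nodes with mean relative abundance <= ``min_abund`` (default 1 per
    mille) are dropped before ranking.  Ties break by higher degree, then
    lexicographic otu_id.  ``abundance_rank`` is the node's rank (1 = most
    abundant) among all network nodes.
    """
    g = net.graph
    if any(np.isnan(t.keystoneness) for t in topology):
        raise ValueError("run keystoneness() before identify_keystones()")
    all_ab = sorted(
        ((g.nodes[t.otu_id].get("mean_rel_abund", 0.0), t.otu_id) for t in topology),
        key=lambda x: (-x[0], x[1]))
    ab_rank = {otu: i + 1 for i, (_, otu) in enumerate(all_ab)}
    survivors = [t for t in topology
                 if g.nodes[t.otu_id].get("mean_rel_abund", 0.0) > min_abund]
    survivors.sort(key=lambda t: (-t.keystoneness, -t.degree, t.otu_id))
    if len(survivors) < top_n:
        warnings.warn(
            f"only {len(survivors)} nodes pass the keystone abundance floor "
            f"(requested top {top_n})", stacklevel=2)
    records = []
    for t in survivors[:top_n]:
        records.append(KeystoneRecord(
            otu_id=t.otu_id,
            keystoneness=t.keystoneness,
            abundance_rank=ab_rank[t.otu_id],
            mean_rel_abund=float(g.nodes[t.otu_id].get("mean_rel_abund", 0.0)),
            phylum=g.nodes[t.otu_id].get("phylum", "unknown"),
        ))
    return records


def jaccard_index(nodes_a, nodes_b) -> float:
    """|A n B| / |A u B|; two empty sets give 0 (with a warning)."""
    a, b = set(nodes_a), set(nodes_b)
    union = a | b
    if not union:
        warnings.warn("Jaccard of two empty sets defined as 0", stacklevel=2)
        return 0.0
    return len(a & b) / len(union)


def network_summary(net: CooccurrenceNetwork, top_k: int = 5) -> dict:
    """Node/edge counts, edge signs, phylum tallies and top abundant nodes."""
    g = net.graph
    signs = [attrs["sign"] for _, _, attrs in g.edges(data=True)]
    phyla = pd.Series(
        [g.nodes[n].get("phylum", "unknown") for n in g.nodes()], dtype=object)
    by_ab = sorted(g.nodes(data=True),
                   key=lambda kv: (-kv[1].get("mean_rel_abund", 0.0), kv[0]))
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "n_positive_edges": signs.count("pos"),
        "n_negative_edges": signs.count("neg"),
        "n_phyla": int(phyla.nunique()) if len(phyla) else 0,
        "phylum_node_counts": phyla.value_counts().to_dict() if len(phyla) else {},
        "top_abundant_nodes": [n for n, _ in by_ab[:top_k]],
        "r_threshold": net.r_threshold,
        "p_threshold": net.p_threshold,
    }


def topology_frame(topology: list) -> pd.DataFrame:
    """Topology + keystoneness as a DataFrame indexed by otu_id."""
    if not topology:
        return pd.DataFrame(columns=[
            "degree", "betweenness", "closeness", "scaled_degree",
            "scaled_one_minus_betweenness", "scaled_closeness", "keystoneness"])
    return pd.DataFrame([asdict(t) for t in topology]).set_index("otu_id")
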