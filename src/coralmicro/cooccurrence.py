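"""Spearman co-occurrence networks and their topology.

The network stage: all-pairs Spearman correlations over the abundance-
filtered OTUs of one host dataset, an edge for every strong significant
positive association (rho > 0.6 and P < 0.01 by default), and summary
statistics of the resulting graph — mean degree, mean shortest-path length,
diameter, clustering, and Louvain modularity with the conventional Q > 0.40
"modular structure" call.  A per-OTU permutation null model tests whether
the observed number of co-occurrence edges could arise from independent
abundance profiles.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score

logger = logging.getLogger(__name__)

MODULARITY_THRESHOLD = 0.40


def _rho_p_matrices(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spearman rho and two-sided p matrices for OTU rows (variables) over
    sample columns (observations).

    rho is Pearson correlation of average-tie ranks; p comes from the
    t approximation t = rho*sqrt((n-2)/(1-rho^2)) on n-2 degrees of freedom.
    Constant rows yield NaN entries (callers skip those pairs); a perfect
    |rho| = 1 gets the smallest representable positive p.
    """
    n = values.shape[1]
    ranks = stats.rankdata(values, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(ranks)
        rho = np.clip(rho, -1.0, 1.0)
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    tiny = np.finfo(float).tiny
    p = np.where(np.abs(rho) >= 1.0 - 1e-15, tiny, p)
    np.fill_diagonal(p, 0.0)
    return rho, p


def spearman_all_pairs(frame: pd.DataFrame) -> pd.DataFrame:
    """All unordered OTU pairs with Spearman rho (average-tie ranks), the
    two-sided t-approximation p-value, and the sample count.

    ``frame`` holds retained OTUs as rows and samples as columns.  Pairs
    involving a constant OTU vector have undefined rank correlation; they
    are skipped and logged.
    """
    n_otus, n_samples = frame.shape
    if n_samples < 5:
        raise ValueError("need at least 5 samples for rank correlations")
    if n_otus < 2:
        raise ValueError("need at least 2 OTUs")
    values = frame.to_numpy(dtype=float)
    constant = np.ptp(values, axis=1) == 0
    if constant.any():
        logger.warning("skipping %d constant OTU vector(s): %s",
                       int(constant.sum()),
                       ", ".join(np.asarray(frame.index)[constant][:10]))
    rho, p = _rho_p_matrices(values)
    otu_ids = list(frame.index)
    rows = []
    for i, j in itertools.combinations(range(n_otus), 2):
        if constant[i] or constant[j] or not np.isfinite(rho[i, j]):
            continue
        rows.append((otu_ids[i], otu_ids[j], float(rho[i, j]),
                     float(p[i, j]), n_samples))
    return pd.DataFrame(rows, columns=["otu_a", "otu_b", "rho", "p", "n"])


def build_network(corr: pd.DataFrame, rho_min: float = 0.6,
                  p_max: float = 0.01, host: str | None = None,
                  tax: dict | None = None) -> nx.Graph:
    """Positive co-occurrence network: an edge for every pair with
    rho > rho_min (strict) and p < p_max (strict).

    Nodes are the endpoints of qualifying edges — OTUs that pass the
    abundance filter but co-occur with nothing are not part of the network.
    """
    if not 0 < rho_min <= 1:
        raise ValueError(f"rho_min must be in (0, 1]: {rho_min}")
    if not 0 < p_max <= 1:
        raise ValueError(f"p_max must be in (0, 1]: {p_max}")
    g = nx.Graph(host=host, rho_min=rho_min, p_max=p_max)
    keep = corr[(corr["rho"] > rho_min) & (corr["p"] < p_max)]
    for row in keep.itertuples():
        g.add_edge(row.otu_a, row.otu_b, weight=float(row.rho), p=float(row.p))
    if tax is not None:
        for node in g.nodes:
            rec = tax.get(node)
            if rec is not None:
                g.nodes[node]["phylum"] = rec.rank_label("phylum")
                g.nodes[node]["class"] = rec.rank_label("class")
                g.nodes[node]["genus"] = rec.rank_label("genus")
    return g


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional alternative to the raw-p edge rule)."""
    return stats.false_discovery_control(np.asarray(p, dtype=float), method="bh")


@dataclass
class NetworkTopology:
    n_nodes: int
    n_edges: int
    avg_connectivity: float  # mean degree, exactly 2E/N
    avg_distance: float  # mean shortest-path length over finite pairs, in edges
    diameter: int  # max finite shortest path, in edges
    avg_clustering: float
    modularity: float
    n_communities: int
    is_modular: bool  # Q > 0.40
    communities: list[set] | None = None

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("n_nodes", "n_edges", "avg_connectivity", "avg_distance",
                 "diameter", "avg_clustering", "modularity", "n_communities",
                 "is_modular")}


def modular_structure_flag(q: float) -> bool:
    """Conventional modularity call: a network is modular iff Q > 0.40 strictly."""
    if not np.isfinite(q):
        raise ValueError(f"modularity must be finite: {q}")
    return q > MODULARITY_THRESHOLD


def topology(net: nx.Graph, community_seed: int = 0,
             distance_mode: str = "pooled") -> NetworkTopology:
    """Topology summary of a co-occurrence network.

    On disconnected graphs, mean distance and diameter consider finite
    shortest paths only; ``distance_mode='pooled'`` (default) averages over
    all finite pairs across components, ``'per_component'`` averages the
    per-component means.  Community structure and Q come from seeded Louvain
    optimization on the unweighted graph.
    """
    n = net.number_of_nodes()
    if n < 1:
        raise ValueError("empty graph")
    if distance_mode not in ("pooled", "per_component"):
        raise ValueError(f"unknown distance_mode: {distance_mode!r}")
    e = net.number_of_edges()
    avg_conn = 2.0 * e / n

    diameter = 0
    if distance_mode == "pooled":
        total, pairs = 0, 0
        for source, lengths in nx.all_pairs_shortest_path_length(net):
            for target, dist in lengths.items():
                if target == source:
                    continue
                total += dist
                pairs += 1
                diameter = max(diameter, dist)
        avg_dist = total / pairs if pairs else float("nan")
    else:
        comp_means = []
        for comp in nx.connected_components(net):
            if len(comp) < 2:
                continue
            sub = net.subgraph(comp)
            comp_means.append(nx.average_shortest_path_length(sub))
            diameter = max(diameter, nx.diameter(sub))
        avg_dist = float(np.mean(comp_means)) if comp_means else float("nan")

    avg_clust = nx.average_clustering(net)  # degree<2 nodes contribute 0
    communities = nx.community.louvain_communities(net, weight=None,
                                                   seed=community_seed)
    if e > 0:
        q = nx.community.modularity(net, communities, weight=None)
    else:
        q = 0.0
    return NetworkTopology(
        n_nodes=n, n_edges=e, avg_connectivity=avg_conn, avg_distance=avg_dist,
        diameter=diameter, avg_clustering=float(avg_clust), modularity=float(q),
        n_communities=len(communities), is_modular=modular_structure_flag(q),
        communities=[set(c) for c in communities])


# ---------------------------------------------------------------------------
# Non-randomness null model
# ---------------------------------------------------------------------------

@dataclass
class NullModelResult:
    statistic_name: str
    observed: float
    null_mean: float
    null_sd: float
    p_value: float
    n_reps: int
    seed: int


def _edge_count(values: np.ndarray, rho_min: float, p_max: float) -> int:
    rho, p = _rho_p_matrices(values)
    iu = np.triu_indices(values.shape[0], k=1)
    ok = np.isfinite(rho[iu]) & (rho[iu] > rho_min) & (p[iu] < p_max)
    return int(ok.sum())


def nonrandomness_test(frame: pd.DataFrame, rho_min: float = 0.6,
                       p_max: float = 0.01, n_reps: int = 999,
                       seed: int = 0) -> NullModelResult:
    """Permutation test of non-random co-occurrence.

    Null model: each OTU's abundance vector is independently permuted across
    samples, preserving every marginal distribution while destroying
    cross-OTU association; the network is rebuilt each replicate and the
    qualifying-edge count compared with the observed one.  p uses the
    (b+1)/(m+1) estimator.
    """
    if n_reps < 99:
        raise ValueError("at least 99 null replicates required")
    values = frame.to_numpy(dtype=float)
    observed = _edge_count(values, rho_min, p_max)
    rng = np.random.default_rng(seed)
    null_counts = np.empty(n_reps, dtype=int)
    for k in range(n_reps):
        null_counts[k] = _edge_count(rng.permuted(values, axis=1), rho_min, p_max)
    b = int((null_counts >= observed).sum())
    return NullModelResult(
        statistic_name="qualifying_edge_count",
        observed=float(observed),
        null_mean=float(null_counts.mean()),
        null_sd=float(null_counts.std(ddof=1)) if n_reps > 1 else 0.0,
        p_value=(b + 1) / (n_reps + 1),
        n_reps=n_reps,
        seed=seed)


def guild_recovery_ari(communities: list[set], truth_partition: dict) -> float:
    """Adjusted Rand index between detected network communities and a
    planted guild partition, over planted-guild OTUs present in the network."""
    detected: dict[str, int] = {}
    for ci, comm in enumerate(communities):
        for node in comm:
            detected[node] = ci
    shared = [o for o, gid in truth_partition.items()
              if gid is not None and o in detected]
    if not shared:
        return float("nan")
    return float(adjusted_rand_score([truth_partition[o] for o in shared],
                                     [detected[o] for o in shared]))


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def edge_list_frame(net: nx.Graph) -> pd.DataFrame:
    rows = [(a, b, d["weight"], d["p"])
            for a, b, d in sorted(net.edges(data=True))]
    return pd.DataFrame(rows, columns=["source", "target", "rho", "p"])


def node_frame(net: nx.Graph, communities: list[set] | None = None) -> pd.DataFrame:
    comm_of = {}
    if communities:
        for ci, comm in enumerate(communities):
            for node in comm:
                comm_of[node] = ci
    rows = []
    for node, data in sorted(net.nodes(data=True)):
        rows.append({
            "otu_id": node,
            "degree": net.degree[node],
            "phylum": data.get("phylum", ""),
            "class": data.get("class", ""),
            "genus": data.get("genus", ""),
            "community": comm_of.get(node, -1),
        })
    return pd.DataFrame(rows)


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path, named_key_ids=True)
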