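"""Spearman correlation networks over the 84 signaling nodes.

At each timepoint the 12 signaling parameters x 7 PBMC lineages form the
node set; an undirected edge joins two nodes when the magnitude of their
Spearman rank correlation across subjects is at least the threshold
(default 0.5), weighted by the signed rho.  Node metrics (degree, strength
= sum |rho| over incident edges, betweenness on the unweighted thresholded
graph, eccentricity within each connected component) feed the hub /
bottleneck cross-classification: hubs are the top 20% of nodes by degree,
bottlenecks the top 20% by betweenness, boundary ties included.  Densely
connected functional communities are found by Louvain modularity
maximization on |rho| weights, and cross-timepoint robustness is assessed
by permuting each node's median correlation within timepoint and comparing
observed median-correlation changes against that null.
"""

from __future__ import annotations

import dataclasses
import math

import networkx as nx
import numpy as np
import pandas as pd
from networkx.algorithms.community import louvain_communities, modularity
from scipy.stats import mannwhitneyu, rankdata

from ._rng import derive_rng, derive_seed
from .clustering import hypergeom_pvalue
from .datasets import CohortDataset

__all__ = [
    "spearman_matrix",
    "SignalingNetwork",
    "build_network",
    "node_centralities",
    "classify_roles",
    "detect_communities",
    "category_enrichment",
    "robustness_test",
    "RobustnessReport",
    "topology_over_time",
]


def spearman_matrix(data) -> pd.DataFrame:
    """Spearman correlation matrix of the columns of ``data``.

    Uses average ranks for ties.  Constant columns get missing
    correlations (the node will be isolated downstream).  Requires >= 4
    rows (subjects).
    """
    if isinstance(data, CohortDataset):
        data = data.measurements
    X = pd.DataFrame(data)
    if len(X) < 4:
        raise ValueError(f"need >= 4 subjects, got {len(X)}")
    vals = X.to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 0, vals)
    sd = ranks.std(axis=0, ddof=0)
    constant = sd <= 0
    ranks_c = ranks - ranks.mean(axis=0)
    denom = np.outer(sd, sd) * len(X)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ranks_c.T @ ranks_c) / denom
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, 1.0)
    return pd.DataFrame(rho, index=X.columns, columns=X.columns)


@dataclasses.dataclass
class SignalingNetwork:
    """Thresholded weighted correlation graph plus derived node metrics."""

    graph: nx.Graph
    threshold: float
    timepoint: str = ""
    modularity_q: float | None = None

    @property
    def nodes_table(self) -> pd.DataFrame:
        rows = []
        for v, attrs in self.graph.nodes(data=True):
            rows.append({"node": v, **attrs})
        return pd.DataFrame(rows)

    def to_graphml(self, path) -> None:
        g = self.graph.copy()
        for _, attrs in g.nodes(data=True):
            for k, val in list(attrs.items()):
                if val is None:
                    attrs[k] = ""
        nx.write_graphml(g, path)


def build_network(
    corr: pd.DataFrame,
    threshold: float = 0.5,
    timepoint: str = "",
    node_attrs: pd.DataFrame | None = None,
) -> SignalingNetwork:
    """Threshold a correlation matrix into an undirected weighted graph.

    Edge (i, j) exists iff |rho_ij| >= threshold; the signed rho is stored
    as ``rho`` and |rho| as ``weight``.  ``node_attrs`` (indexed by
    feature_id) may carry cell_type / signaling_param / pathway metadata.
    """
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    M = corr.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1] or not np.allclose(
        M, M.T, equal_nan=True, atol=1e-10
    ):
        raise ValueError("correlation matrix must be square and symmetric")
    nodes = list(corr.index)
    g = nx.Graph(timepoint=timepoint)
    g.add_nodes_from(nodes)
    if node_attrs is not None:
        for v in nodes:
            if v in node_attrs.index:
                for k, val in node_attrs.loc[v].items():
                    g.nodes[v][k] = val
    iu, ju = np.triu_indices(len(nodes), k=1)
    keep = np.abs(M[iu, ju]) >= threshold
    for i, j in zip(iu[keep], ju[keep]):
        rho = float(M[i, j])
        if not math.isfinite(rho):
            continue
        g.add_edge(nodes[i], nodes[j], rho=rho, weight=abs(rho))
    for v in nodes:
        g.nodes[v]["degree"] = g.degree(v)
        g.nodes[v]["strength"] = float(
            sum(d["weight"] for _, _, d in g.edges(v, data=True))
        )
    return SignalingNetwork(g, threshold, timepoint)


def node_centralities(network: SignalingNetwork) -> pd.DataFrame:
    """Betweenness and eccentricity per node, stored on the graph.

    Betweenness counts unordered source-target pairs whose shortest paths
    (on the unweighted thresholded graph) pass through the node, with
    fractional credit when several shortest paths tie.  Eccentricity is
    the maximum geodesic distance within the node's connected component;
    isolated nodes get 0 for both.
    """
    g = network.graph
    bc = nx.betweenness_centrality(g, normalized=False, weight=None)
    ecc: dict = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) == 1:
            ecc[next(iter(comp))] = 0
        else:
            ecc.update(nx.eccentricity(sub))
    for v in g.nodes:
        g.nodes[v]["betweenness"] = float(bc[v])
        g.nodes[v]["eccentricity"] = int(ecc[v])
    return pd.DataFrame(
        {
            "node": list(g.nodes),
            "betweenness": [g.nodes[v]["betweenness"] for v in g.nodes],
            "eccentricity": [g.nodes[v]["eccentricity"] for v in g.nodes],
        }
    )


def _top_fraction(values: dict, fraction: float) -> set:
    """Top ceil(fraction * N) keys by value, boundary ties included.

    When every value is equal the metric is uninformative and no key is
    selected.
    """
    vals = np.array(list(values.values()), dtype=float)
    if vals.size == 0 or np.ptp(vals) == 0:
        return set()
    n_top = math.ceil(fraction * vals.size)
    cutoff = np.sort(vals)[::-1][n_top - 1]
    return {k for k, v in values.items() if v >= cutoff}


def classify_roles(network: SignalingNetwork, fraction: float = 0.2) -> pd.DataFrame:
    """Hub / bottleneck cross-classification of every node.

    Roles: H-B (hub and bottleneck), H-NB, NH-B, NH-NB.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if any("betweenness" not in g.nodes[v] for v in g.nodes):
        node_centralities(network)
    degrees = {v: g.nodes[v]["degree"] for v in g.nodes}
    betw = {v: g.nodes[v]["betweenness"] for v in g.nodes}
    hubs = _top_fraction(degrees, fraction)
    bottlenecks = _top_fraction(betw, fraction)
    for v in g.nodes:
        role = ("H" if v in hubs else "NH") + "-" + ("B" if v in bottlenecks else "NB")
        g.nodes[v]["role"] = role
    return pd.DataFrame(
        {"node": list(g.nodes), "role": [g.nodes[v]["role"] for v in g.nodes]}
    )


def detect_communities(
    network: SignalingNetwork,
    resolution: float = 1.0,
    n_restarts: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Louvain communities on |rho| weights; best modularity over restarts.

    Community ids are relabeled by decreasing size so labels are stable
    per seed.  An edgeless network puts every node in its own community
    with Q = 0.  Returns the node -> community table and sets
    ``network.modularity_q``.
    """
    g = network.graph
    if g.number_of_edges() == 0:
        parts = [{v} for v in g.nodes]
        best_q = 0.0
    else:
        best_q, parts = -np.inf, None
        for r in range(n_restarts):
            p = louvain_communities(
                g,
                weight="weight",
                resolution=resolution,
                seed=derive_seed(seed, "louvain", r),
            )
            q = modularity(g, p, weight="weight", resolution=resolution)
            if q > best_q:
                best_q, parts = q, p
    parts = sorted(parts, key=lambda c: (-len(c), sorted(map(str, c))[0]))
    n = g.number_of_nodes()
    rows = []
    for cid, comm in enumerate(parts):
        for v in comm:
            g.nodes[v]["community"] = cid
    for cid, comm in enumerate(parts):
        rows.append(
            {
                "community": cid,
                "size": len(comm),
                "composition_pct": 100.0 * len(comm) / n,
            }
        )
    network.modularity_q = float(best_q)
    table = pd.DataFrame(
        {
            "node": list(g.nodes),
            "community": [g.nodes[v]["community"] for v in g.nodes],
        }
    )
    table.attrs["composition"] = pd.DataFrame(rows)
    table.attrs["modularity_q"] = float(best_q)
    return table


def category_enrichment(
    network: SignalingNetwork, categories: dict, subset
) -> pd.DataFrame:
    """Hypergeometric enrichment of node categories within a node subset.

    ``categories`` maps every node of the network to a label (signaling
    parameter or pathway); ``subset`` is e.g. the hub set, the bottleneck
    set or one community.
    """
    nodes = set(network.graph.nodes)
    subset = set(subset)
    if not subset:
        raise ValueError("empty node subset")
    if not subset <= nodes:
        raise ValueError(f"subset not within network: {sorted(subset - nodes)}")
    missing = nodes - set(categories)
    if missing:
        raise ValueError(f"categories missing for nodes: {sorted(missing)[:5]}")
    N, n = len(nodes), len(subset)
    rows = []
    for cat in sorted({categories[v] for v in nodes}):
        members = {v for v in nodes if categories[v] == cat}
        K = len(members)
        k = len(members & subset)
        rows.append(
            {
                "category": cat,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p": hypergeom_pvalue(N, K, n, k),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# Cross-timepoint robustness


@dataclasses.dataclass
class RobustnessReport:
    """Observed vs null median-correlation changes per node."""

    frame: pd.DataFrame  # node, t1, t2, m_t1, m_t2, delta_obs, p
    n_perm: int

    def fraction_significant(self, alpha: float = 0.05) -> float:
        return float((self.frame["p"] < alpha).mean())

    def summary(self) -> str:
        return (
            f"Network robustness ({self.n_perm} permutations): "
            f"{100 * self.fraction_significant():.1f}% of node-pair tests "
            "significant at p < 0.05"
        )


def node_median_correlations(corr: pd.DataFrame) -> pd.Series:
    """Median correlation of each node with all other nodes."""
    M = corr.to_numpy(dtype=float).copy()
    np.fill_diagonal(M, np.nan)
    return pd.Series(np.nanmedian(M, axis=1), index=corr.index)


def robustness_test(
    corr_by_timepoint: dict,
    n_perm: int = 10_000,
    seed: int = 0,
    null: str = "node-medians",
    data_by_timepoint: dict | None = None,
) -> RobustnessReport:
    """Permutation test of median-correlation changes between timepoints.

    For every timepoint pair (t1, t2) and node v the observed change is
    Delta_o(v) = |m_t1(v) - m_t2(v)| where m_t(v) is v's median
    correlation at t.  The default null (``null="node-medians"``) permutes
    the node -> median assignment independently within each timepoint;
    p(v) is the proportion of null changes at least as large as
    Delta_o(v).  ``null="subjects"`` instead shuffles each feature's
    values across subjects within timepoint and recomputes the Spearman
    medians per permutation (requires ``data_by_timepoint``: timepoint ->
    subjects x nodes frame); it is far costlier, so scale n_perm down.
    """
    if null == "subjects":
        return _robustness_subject_null(
            corr_by_timepoint, data_by_timepoint, n_perm, seed
        )
    if null != "node-medians":
        raise ValueError(f"unknown null {null!r}")
    tps = list(corr_by_timepoint)
    if len(tps) < 2:
        raise ValueError("need >= 2 timepoints")
    node_sets = [tuple(corr_by_timepoint[t].index) for t in tps]
    if len(set(node_sets)) != 1:
        raise ValueError("node sets differ between timepoints")
    medians = {t: node_median_correlations(corr_by_timepoint[t]) for t in tps}
    nodes = list(corr_by_timepoint[tps[0]].index)
    rng = derive_rng(seed, "robustness")
    rows = []
    for a in range(len(tps)):
        for b in range(a + 1, len(tps)):
            t1, t2 = tps[a], tps[b]
            m1 = medians[t1].to_numpy()
            m2 = medians[t2].to_numpy()
            d_obs = np.abs(m1 - m2)
            count = np.zeros(len(nodes), dtype=int)
            for _ in range(n_perm):
                p1 = rng.permutation(m1)
                p2 = rng.permutation(m2)
                count += np.abs(p1 - p2) >= d_obs - 1e-15
            pvals = count / n_perm
            for i, v in enumerate(nodes):
                rows.append(
                    {
                        "node": v,
                        "t1": t1,
                        "t2": t2,
                        "m_t1": m1[i],
                        "m_t2": m2[i],
                        "delta_obs": d_obs[i],
                        "p": pvals[i],
                    }
                )
    return RobustnessReport(pd.DataFrame(rows), n_perm)


def _robustness_subject_null(
    corr_by_timepoint: dict, data_by_timepoint: dict | None, n_perm: int, seed: int
) -> RobustnessReport:
    """Subject-shuffling null: break inter-feature coupling, keep margins."""
    if data_by_timepoint is None:
        raise ValueError('null="subjects" requires data_by_timepoint')
    tps = list(corr_by_timepoint)
    medians = {t: node_median_correlations(corr_by_timepoint[t]) for t in tps}
    nodes = list(corr_by_timepoint[tps[0]].index)
    rng = derive_rng(seed, "robustness-subjects")
    null_medians = {t: np.empty((n_perm, len(nodes))) for t in tps}
    for t in tps:
        X = data_by_timepoint[t].to_numpy(dtype=float).copy()
        for b in range(n_perm):
            Xp = rng.permuted(X, axis=0)  # independent shuffle per column
            C = spearman_matrix(
                pd.DataFrame(Xp, columns=data_by_timepoint[t].columns)
            )
            null_medians[t][b] = node_median_correlations(C).to_numpy()
    rows = []
    for a in range(len(tps)):
        for b in range(a + 1, len(tps)):
            t1, t2 = tps[a], tps[b]
            m1, m2 = medians[t1].to_numpy(), medians[t2].to_numpy()
            d_obs = np.abs(m1 - m2)
            d_null = np.abs(null_medians[t1] - null_medians[t2])
            pvals = (d_null >= d_obs - 1e-15).mean(axis=0)
            for i, v in enumerate(nodes):
                rows.append(
                    {
                        "node": v,
                        "t1": t1,
                        "t2": t2,
                        "m_t1": m1[i],
                        "m_t2": m2[i],
                        "delta_obs": d_obs[i],
                        "p": pvals[i],
                    }
                )
    return RobustnessReport(pd.DataFrame(rows), n_perm)


def topology_over_time(networks: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-timepoint metric distributions and pairwise rank-sum tests.

    Returns ``(summary, tests)``: medians and IQRs of degree, strength,
    betweenness and eccentricity per timepoint, and Wilcoxon rank-sum
    (Mann-Whitney) p-values between every timepoint pair per metric.
    """
    if len(networks) < 2:
        raise ValueError("need >= 2 timepoints")
    metrics = ["degree", "strength", "betweenness", "eccentricity"]
    dists: dict[str, dict[str, np.ndarray]] = {}
    for tp, net in networks.items():
        if any("betweenness" not in net.graph.nodes[v] for v in net.graph.nodes):
            node_centralities(net)
        dists[tp] = {
            m: np.array([net.graph.nodes[v][m] for v in net.graph.nodes])
            for m in metrics
        }
    sum_rows, test_rows = [], []
    tps = list(networks)
    for tp in tps:
        for m in metrics:
            v = dists[tp][m]
            sum_rows.append(
                {
                    "timepoint": tp,
                    "metric": m,
                    "median": float(np.median(v)) if v.size else 0.0,
                    "iqr": float(np.subtract(*np.percentile(v, [75, 25])))
                    if v.size
                    else 0.0,
                    "n_nodes": v.size,
                }
            )
    for i in range(len(tps)):
        for j in range(i + 1, len(tps)):
            for m in metrics:
                x, y = dists[tps[i]][m], dists[tps[j]][m]
                if x.size < 2 or y.size < 2:
                    continue
                if np.ptp(np.concatenate([x, y])) == 0:
                    stat, p = 0.0, 1.0
                else:
                    stat, p = mannwhitneyu(x, y, alternative="two-sided")
                test_rows.append(
                    {
                        "t1": tps[i],
                        "t2": tps[j],
                        "metric": m,
                        "statistic": float(stat),
                        "p": float(p),
                    }
                )
    return pd.DataFrame(sum_rows), pd.DataFrame(test_rows)
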