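"""Structural statistics of patient-diagnosis bipartite networks.

Covers degree profiles, degree-degree mixing (k vs <knn>), second-order
(distance-2) neighborhoods and their correlations, peer-attribute
homophily, average efficiency, observed/expected chapter lift, and
one-mode projection modularity.

Average efficiency of a node subset S is

    E = 1 / (|S| (|S|-1)) * sum_{i != j in S} 1 / d_ij

with shortest-path distances d_ij measured on the full bipartite graph
and unreachable pairs contributing zero, so E is well defined on
disconnected networks and lies in [0, 1].

All Kendall correlations use the tie-corrected tau-b: degrees are small
integers and ties are ubiquitous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse import csgraph

from .etl import ConditionSplit, chapter_of
from .networks import BipartiteNetwork

__all__ = [
    "MixingProfile",
    "EfficiencyResult",
    "ChapterLiftMatrix",
    "degree_profile",
    "mixing_profile",
    "second_order",
    "second_order_correlations",
    "peer_attribute",
    "efficiency",
    "chapter_lift",
    "modularity",
]


def _side_nodes(network: BipartiteNetwork, side: str) -> list:
    if side == "patients":
        return network.patients
    if side == "diseases":
        return network.diseases
    if side == "all":
        return list(network.graph.nodes)
    raise ValueError(f"side must be 'patients', 'diseases' or 'all', got {side!r}")


def _tau(x, y) -> float:
    """Kendall tau-b; NaN when either margin is degenerate."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(set(x)) < 2 or len(set(y)) < 2:
        return math.nan
    return float(stats.kendalltau(x, y).statistic)


# --------------------------------------------------------------------------
# degrees and mixing


def degree_profile(network: BipartiteNetwork, group_by: str) -> pd.DataFrame:
    """Mean unweighted degree per group with normal-approximation 95% CIs.

    group_by: "side" (patients vs diseases), "chapter" (disease nodes by
    ICD-10 chapter) or "age_band" (patient nodes by decade of age at the
    index diagnosis).  Single-member groups get zero-width CIs.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("network is empty")
    if group_by == "side":
        rows = [(d["kind"] + "s", g.degree(n)) for n, d in g.nodes(data=True)]
    elif group_by == "chapter":
        rows = [
            (d["chapter"], g.degree(n))
            for n, d in g.nodes(data=True)
            if d["kind"] == "disease"
        ]
    elif group_by == "age_band":
        rows = [
            (f"{10 * int(d['age_at_smi'] // 10)}s", g.degree(n))
            for n, d in g.nodes(data=True)
            if d["kind"] == "patient"
        ]
    else:
        raise ValueError(f"unknown group key: {group_by!r}")
    frame = pd.DataFrame(rows, columns=["group", "degree"])
    out = frame.groupby("group")["degree"].agg(["size", "mean", "std"]).reset_index()
    out.columns = ["group", "n", "mean_degree", "sd"]
    se = (out["sd"] / np.sqrt(out["n"])).fillna(0.0)
    out["ci_low"] = out["mean_degree"] - 1.96 * se
    out["ci_high"] = out["mean_degree"] + 1.96 * se
    return out.sort_values("group").reset_index(drop=True)


@dataclass
class MixingProfile:
    """Nearest-neighbor degree profile of one side of the network."""

    side: str
    per_node: pd.DataFrame  # node, k, knn
    per_degree: pd.DataFrame  # k, mean_knn, n
    kendall_tau: float  # tau-b between k(u) and knn(u); NaN if degenerate


def mixing_profile(network: BipartiteNetwork, side: str) -> MixingProfile:
    """<knn> as a function of k: mean neighbor degree per node of ``side``."""
    g = network.graph
    nodes = _side_nodes(network, side)
    if not nodes:
        raise ValueError(f"no nodes on side {side!r}")
    deg = dict(g.degree())
    recs = []
    for u in nodes:
        nbrs = list(g[u])
        if nbrs:
            recs.append((u, deg[u], sum(deg[v] for v in nbrs) / len(nbrs)))
    per_node = pd.DataFrame(recs, columns=["node", "k", "knn"])
    per_degree = (
        per_node.groupby("k")["knn"].agg(["mean", "size"]).reset_index()
    )
    per_degree.columns = ["k", "mean_knn", "n"]
    tau = _tau(per_node["k"], per_node["knn"]) if len(per_node) >= 2 else math.nan
    return MixingProfile(side=side, per_node=per_node, per_degree=per_degree,
                         kendall_tau=tau)


# --------------------------------------------------------------------------
# second-order neighborhoods


def second_order(network: BipartiteNetwork, node) -> set:
    """Nodes at distance exactly 2 (same parity), excluding the node itself."""
    g = network.graph
    if node not in g:
        raise KeyError(f"node {node!r} not in network")
    out: set = set()
    for nbr in g[node]:
        out.update(g[nbr])
    out.discard(node)
    return out


def second_order_correlations(
    network: BipartiteNetwork, side: str
) -> tuple[dict[str, float], pd.DataFrame]:
    """Kendall tau of |N(N(v))| against k(v) and knn(v) on one side."""
    nodes = _side_nodes(network, side)
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes on the side")
    mix = mixing_profile(network, side)
    knn = dict(zip(mix.per_node["node"], mix.per_node["knn"]))
    g = network.graph
    recs = [
        (u, g.degree(u), knn.get(u, math.nan), len(second_order(network, u)))
        for u in nodes
    ]
    table = pd.DataFrame(recs, columns=["node", "k", "knn", "nn2"])
    taus = {
        "tau_k_nn2": _tau(table["k"], table["nn2"]),
        "tau_knn_nn2": _tau(table["knn"].fillna(0.0), table["nn2"]),
    }
    return taus, table


def peer_attribute(
    network: BipartiteNetwork, attribute: str = "age_at_smi"
) -> tuple[pd.DataFrame, float]:
    """Mean attribute of each patient's second-order (peer) patients.

    Returns the per-patient table (patients with no peers excluded) and
    Kendall tau between a patient's own attribute and the peer mean.
    Sparse-matrix route: peers of u are the nonzeros of row u of B B^T.
    """
    g = network.graph
    patients = network.patients
    if not patients:
        raise ValueError("network has no patient nodes")
    for p in patients:
        if attribute not in g.nodes[p]:
            raise KeyError(f"attribute {attribute!r} missing on patient {p!r}")
    diseases = network.diseases
    if not diseases:
        return pd.DataFrame(columns=["patient_id", "own", "peer_mean", "n_peers"]), math.nan
    b = nx_biadjacency(g, patients, diseases)
    shared = (b @ b.T).tocsr()
    shared.setdiag(0)
    shared.eliminate_zeros()
    adj = shared.copy()
    adj.data[:] = 1.0
    attr = np.array([g.nodes[p][attribute] for p in patients], dtype=float)
    n_peers = np.asarray(adj.sum(axis=1)).ravel()
    sums = adj @ attr
    mask = n_peers > 0
    table = pd.DataFrame(
        {
            "patient_id": np.asarray(patients, dtype=object)[mask],
            "own": attr[mask],
            "peer_mean": sums[mask] / n_peers[mask],
            "n_peers": n_peers[mask].astype(int),
        }
    )
    tau = _tau(table["own"], table["peer_mean"]) if len(table) >= 2 else math.nan
    return table, tau


def nx_biadjacency(g: nx.Graph, rows: list, cols: list) -> sparse.csr_matrix:
    """Boolean biadjacency matrix of a bipartite graph (rows x cols)."""
    ri = {n: i for i, n in enumerate(rows)}
    ci = {n: i for i, n in enumerate(cols)}
    r, c = [], []
    for u, v in g.edges():
        if u in ri and v in ci:
            r.append(ri[u]); c.append(ci[v])
        elif v in ri and u in ci:
            r.append(ri[v]); c.append(ci[u])
    data = np.ones(len(r))
    return sparse.csr_matrix((data, (r, c)), shape=(len(rows), len(cols)))


# --------------------------------------------------------------------------
# efficiency


@dataclass
class EfficiencyResult:
    value: float
    node_subset: str
    label: str = ""


def efficiency(network: BipartiteNetwork, node_subset: str = "all") -> EfficiencyResult:
    """Average efficiency over ordered pairs of the chosen node subset.

    Distances are shortest paths on the full bipartite graph even when
    the subset is one parity; unreachable pairs contribute zero.
    """
    g = network.graph
    subset = _side_nodes(network, node_subset)
    if len(subset) < 2:
        raise ValueError("node subset must contain at least 2 nodes")
    nodelist = list(g.nodes)
    index = {n: i for i, n in enumerate(nodelist)}
    idx = np.array([index[n] for n in subset])
    adj = nx.to_scipy_sparse_array(g, nodelist=nodelist, weight=None, format="csr")
    dist = csgraph.shortest_path(adj, method="D", unweighted=True, indices=idx)
    sub = dist[:, idx]
    with np.errstate(divide="ignore"):
        inv = 1.0 / sub
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    s = len(subset)
    return EfficiencyResult(
        value=float(inv.sum() / (s * (s - 1))), node_subset=node_subset,
        label=network.label,
    )


# --------------------------------------------------------------------------
# chapter lift and modularity


@dataclass
class ChapterLiftMatrix:
    """Observed/expected ratio linking pre-index to post-index chapters."""

    lift: pd.DataFrame  # rows: pre chapter, cols: post chapter
    support: pd.DataFrame  # joint patient counts per cell
    n_patients: int


def chapter_lift(splits: list[ConditionSplit]) -> ChapterLiftMatrix:
    """lift(A, B) = P(pre in A and post in B) / (P(pre in A) P(post in B)).

    Membership is patient-level presence/absence of >=1 diagnosis in the
    chapter; cells with a zero marginal are NaN.
    """
    if not splits:
        raise ValueError("need at least one patient split")
    n = len(splits)
    pre_ch = [frozenset(chapter_of(c) for c in s.pre_existing) for s in splits]
    post_ch = [frozenset(chapter_of(c) for c in s.post_set) for s in splits]
    chapters = sorted(set().union(*pre_ch, *post_ch))
    p_pre = {a: sum(a in cs for cs in pre_ch) / n for a in chapters}
    p_post = {b: sum(b in cs for cs in post_ch) / n for b in chapters}
    lift = pd.DataFrame(index=chapters, columns=chapters, dtype=float)
    support = pd.DataFrame(0, index=chapters, columns=chapters, dtype=int)
    for a in chapters:
        for b in chapters:
            joint = sum((a in p) and (b in q) for p, q in zip(pre_ch, post_ch))
            support.loc[a, b] = joint
            denom = p_pre[a] * p_post[b]
            lift.loc[a, b] = (joint / n) / denom if denom > 0 else math.nan
    return ChapterLiftMatrix(lift=lift, support=support, n_patients=n)


def modularity(projection: nx.Graph, partition: dict) -> float:
    """Weighted Newman modularity of a one-mode projection.

    ``partition`` maps every node to a community label (typically a
    patient attribute such as gender or ethnicity).
    """
    missing = [n for n in projection.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing[:5]}")
    groups: dict = {}
    for node, comm in partition.items():
        if node in projection:
            groups.setdefault(comm, set()).add(node)
    return float(
        nx.community.modularity(projection, groups.values(), weight="weight")
    )
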