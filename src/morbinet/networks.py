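"""Aggregated temporal bipartite patient-diagnosis networks.

A window of the diagnosis event stream aggregates into a weighted
two-mode graph: patient nodes (with gender, ethnicity, index-SMI code
and age at index diagnosis as attributes) on one side, 3-character
disease categories on the other, an edge whenever the patient was
diagnosed with the disease inside the window, weighted by the number of
such diagnoses.  A patient's own index code never forms an edge, and a
patient whose only diagnoses are the index code is absent altogether.

Window boundaries are half-open [t, t + dt) in signed years-to-index,
except the final window of a sliding sequence, which is closed so the
sequence partitions the observed span without double counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from networkx.algorithms import bipartite as nx_bipartite

from .etl import DAYS_PER_YEAR, chapter_of

__all__ = [
    "BipartiteNetwork",
    "SnapshotSequence",
    "NetworkSummary",
    "build_network",
    "build_pre_post",
    "build_snapshots",
    "summarize",
    "project",
]


@dataclass
class BipartiteNetwork:
    """A weighted two-mode graph plus the window it aggregates."""

    graph: nx.Graph
    window: tuple[float | None, float | None]
    label: str = ""

    @property
    def patients(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "patient"]

    @property
    def diseases(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "disease"]

    @property
    def midpoint(self) -> float:
        lo, hi = self.window
        if lo is None or hi is None:
            return math.nan
        return (lo + hi) / 2.0

    def edge_table(self) -> pd.DataFrame:
        rows = [
            (u if d["kind"] == "patient" else v,
             v if d["kind"] == "patient" else u,
             attrs["weight"], attrs["first_age"], self.label)
            for u, v, attrs in self.graph.edges(data=True)
            for d in (self.graph.nodes[u],)
        ]
        return pd.DataFrame(
            rows, columns=["patient_id", "code3", "weight", "first_age", "window"]
        )


@dataclass
class SnapshotSequence:
    """Ordered (window, network) pairs, sliding or cumulative."""

    snapshots: list[BipartiteNetwork]
    mode: str
    delta_t: float
    step: float

    def __iter__(self):
        return iter(self.snapshots)

    def __len__(self):
        return len(self.snapshots)


@dataclass
class NetworkSummary:
    n_nodes: int
    n_patients: int
    n_diseases: int
    n_edges: int
    mean_degree: float
    mean_patient_degree: float
    mean_disease_degree: float
    density: float
    n_components: int
    gcr: float  # % of nodes in the largest component; NaN when empty
    label: str = ""


def _window_mask(years: pd.Series, lo, hi, closed_right: bool) -> pd.Series:
    mask = pd.Series(True, index=years.index)
    if lo is not None:
        mask &= years >= lo
    if hi is not None:
        mask &= (years <= hi) if closed_right else (years < hi)
    return mask


def build_network(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    window: tuple[float | None, float | None] = (None, None),
    label: str = "",
    closed_right: bool = False,
) -> BipartiteNetwork:
    """Aggregate events inside ``window`` (years-to-index) into a network.

    Edge weight counts the diagnoses of the (patient, disease) pair in
    the window; the edge attribute ``first_age`` is the patient's age in
    whole years at the first such diagnosis.  Events carrying the
    patient's own index SMI code are excluded.  An empty window yields an
    empty network.
    """
    meta = patients.set_index("patient_id")
    lo, hi = window
    ev = events[_window_mask(events["years_to_smi"], lo, hi, closed_right)]
    ev = ev[ev["code3"] != ev["patient_id"].map(meta["first_smi_code"])]

    g = nx.Graph()
    if not ev.empty:
        agg = ev.groupby(["patient_id", "code3"]).agg(
            weight=("code3", "size"), first_ts=("timestamp", "min")
        )
        for (pid, code), row in agg.iterrows():
            if pid not in g:
                m = meta.loc[pid]
                age_smi = (m["first_smi_date"] - m["dob"]).days / DAYS_PER_YEAR
                g.add_node(
                    pid, kind="patient", bipartite=0, gender=m["gender"],
                    ethnicity=m["ethnicity"], first_smi_code=m["first_smi_code"],
                    age_at_smi=age_smi,
                )
            if code not in g:
                g.add_node(code, kind="disease", bipartite=1,
                           chapter=chapter_of(code))
            first_age = math.floor(
                (row["first_ts"] - meta.loc[pid, "dob"]).days / DAYS_PER_YEAR
            )
            g.add_edge(pid, code, weight=int(row["weight"]), first_age=first_age)
    return BipartiteNetwork(graph=g, window=window, label=label)


def build_pre_post(
    events: pd.DataFrame, patients: pd.DataFrame
) -> tuple[BipartiteNetwork, BipartiteNetwork]:
    """Networks over (-inf, 0) and [0, +inf) years-to-index."""
    pre = build_network(events, patients, window=(None, 0.0), label="PRE")
    post = build_network(events, patients, window=(0.0, None), label="POST")
    return pre, post


def build_snapshots(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    delta_t: float = 5.0,
    step: float = 1.0,
    mode: str = "sliding",
) -> SnapshotSequence:
    """Sliding [t, t+dt) or cumulative (-inf, t] window sequence.

    Sliding windows start at floor(min years) and advance by ``step``
    until the window end reaches the observed maximum; the final window
    is closed on the right.  Cumulative windows aggregate everything up
    to each yearly boundary.
    """
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    if mode not in ("sliding", "cumulative"):
        raise ValueError(f"unknown snapshot mode: {mode!r}")
    years = events["years_to_smi"]
    t_min = math.floor(years.min())
    t_max = math.ceil(years.max())
    snaps = []
    if mode == "sliding":
        if t_min + delta_t >= t_max:
            snaps.append(
                build_network(events, patients, (t_min, t_max),
                              label=f"[{t_min},{t_max}]", closed_right=True)
            )
        else:
            t = float(t_min)
            while t + delta_t <= t_max:
                last = t + delta_t + step > t_max
                snaps.append(
                    build_network(
                        events, patients, (t, t + delta_t),
                        label=f"[{t:g},{t + delta_t:g}]", closed_right=last,
                    )
                )
                t += step
    else:
        t = float(t_min + 1)
        while t <= t_max:
            snaps.append(
                build_network(events, patients, (None, t),
                              label=f"(-inf,{t:g}]", closed_right=True)
            )
            t += step
    return SnapshotSequence(snapshots=snaps, mode=mode, delta_t=delta_t, step=step)


def summarize(network: BipartiteNetwork) -> NetworkSummary:
    """Table-style summary: node/edge counts, mean degrees, density, components."""
    g = network.graph
    n_p, n_d = len(network.patients), len(network.diseases)
    n_nodes, n_edges = g.number_of_nodes(), g.number_of_edges()
    if n_nodes == 0:
        return NetworkSummary(0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0, math.nan,
                              network.label)
    degs = dict(g.degree())
    mean_k = 2.0 * n_edges / n_nodes
    mean_kp = (sum(degs[p] for p in network.patients) / n_p) if n_p else 0.0
    mean_kd = (sum(degs[d] for d in network.diseases) / n_d) if n_d else 0.0
    density = n_edges / (n_p * n_d) if n_p and n_d else 0.0
    comps = list(nx.connected_components(g))
    gcr = 100.0 * max(len(c) for c in comps) / n_nodes
    return NetworkSummary(
        n_nodes, n_p, n_d, n_edges, mean_k, mean_kp, mean_kd, density,
        len(comps), gcr, network.label,
    )


def project(network: BipartiteNetwork, side: str) -> nx.Graph:
    """One-mode projection; edge weight = number of shared neighbors."""
    if side == "patients":
        nodes = network.patients
    elif side == "diseases":
        nodes = network.diseases
    else:
        raise ValueError(f"side must be 'patients' or 'diseases', got {side!r}")
    if network.graph.number_of_nodes() == 0:
        return nx.Graph()
    proj = nx_bipartite.weighted_projected_graph(network.graph, nodes)
    proj.remove_edges_from([(u, v) for u, v, w in proj.edges(data="weight") if w == 0])
    return proj
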