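"""Static and temporal bipartite graphlets.

A static bipartite graphlet is a small connected sub-graph with
parity-labeled nodes (patients vs diseases); for 2-4 nodes there are
exactly 7 classes.  Node orbits are computed on topology alone,
ignoring parity, so e.g. the 4-cycle has a single orbit.

A temporal graphlet is a strictly time-ordered sequence of m temporal
edges within a window dt whose induced static sub-graph is connected.
The three 2-edge classes are the workhorses of the analysis:

    D1  the same (patient, disease) pair twice      -- recurrence
    D2  one patient, two diseases (patient wedge)   -- progression-like
    D3  one disease, two patients (disease wedge)   -- selection-like

Counting uses a single time-ordered sweep with per-node counters over
the active window, so cost is O(events x window occupancy); a plain
all-pairs brute-force twin serves as its oracle.  Events sharing a
timestamp (e.g. codes within one admission episode) never form a pair:
the temporal ordering t1 < t2 is strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations, product

import numpy as np
import pandas as pd

__all__ = [
    "StaticGraphlet",
    "TemporalGraphlet",
    "GraphletCounts",
    "static_catalogue",
    "temporal_catalogue",
    "count_2edge",
    "count_2edge_bruteforce",
]

DAYS_PER_YEAR = 365.25


# --------------------------------------------------------------------------
# catalogues


@dataclass(frozen=True)
class StaticGraphlet:
    """One parity-labeled isomorphism class of connected bipartite graphs.

    ``edges`` is the canonical form: sorted (patient index, disease
    index) pairs, minimal over parity-preserving relabelings.  ``orbits``
    partitions node labels ("p0", "d1", ...) by topological position,
    ignoring parity.
    """

    id: str
    n_nodes: int
    n_patients: int
    n_diseases: int
    edges: tuple[tuple[int, int], ...]
    orbits: tuple[frozenset[str], ...]


@dataclass(frozen=True)
class TemporalGraphlet:
    """A strictly ordered edge sequence class, canonical by first appearance."""

    id: str
    m: int
    edges: tuple[tuple[int, int], ...]  # (patient index, disease index) per step
    n_nodes: int
    n_patients: int
    n_diseases: int
    static_id: str


def _canonical_static(
    edges: set[tuple[int, int]], n_p: int, n_d: int
) -> tuple[tuple[int, int], ...]:
    best = None
    for pp in permutations(range(n_p)):
        for dp in permutations(range(n_d)):
            form = tuple(sorted((pp[i], dp[j]) for i, j in edges))
            if best is None or form < best:
                best = form
    return best


def _connected(edges: set[tuple[int, int]], n_p: int, n_d: int) -> bool:
    nodes = {("p", i) for i in range(n_p)} | {("d", j) for j in range(n_d)}
    adj: dict = {n: set() for n in nodes}
    for i, j in edges:
        adj[("p", i)].add(("d", j))
        adj[("d", j)].add(("p", i))
    if any(not a for a in adj.values()):
        return False
    seen = set()
    stack = [next(iter(nodes))]
    while stack:
        n = stack.pop()
        if n in seen:
            continue
        seen.add(n)
        stack.extend(adj[n] - seen)
    return len(seen) == len(nodes)


def _orbits(edges: set[tuple[int, int]], n_p: int, n_d: int) -> tuple[frozenset[str], ...]:
    """Automorphism orbits on topology alone (parity ignored)."""
    labels = [f"p{i}" for i in range(n_p)] + [f"d{j}" for j in range(n_d)]
    n = len(labels)
    adjacency = {(n_p + j, i) for i, j in edges} | {(i, n_p + j) for i, j in edges}
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for perm in permutations(range(n)):
        if all(((perm[a], perm[b]) in adjacency) == ((a, b) in adjacency)
               for a in range(n) for b in range(n)):
            for a in range(n):
                ra, rb = find(a), find(perm[a])
                if ra != rb:
                    parent[ra] = rb
    groups: dict = {}
    for a in range(n):
        groups.setdefault(find(a), set()).add(labels[a])
    return tuple(sorted((frozenset(g) for g in groups.values()),
                        key=lambda s: sorted(s)))


def static_catalogue(max_nodes: int = 4) -> list[StaticGraphlet]:
    """Exhaustive catalogue of connected bipartite graphlets with 2..max nodes."""
    if max_nodes not in (2, 3, 4):
        raise ValueError("max_nodes must be 2, 3 or 4")
    seen: dict = {}
    for n in range(2, max_nodes + 1):
        for n_p in range(1, n):
            n_d = n - n_p
            grid = list(product(range(n_p), range(n_d)))
            for bits in range(1, 2 ** len(grid)):
                edges = {grid[k] for k in range(len(grid)) if bits >> k & 1}
                if not _connected(edges, n_p, n_d):
                    continue
                canon = _canonical_static(edges, n_p, n_d)
                key = (n_p, n_d, canon)
                if key not in seen:
                    seen[key] = (n, len(edges), n_p, n_d, canon,
                                 _orbits(edges, n_p, n_d))
    ordered = sorted(seen.values(), key=lambda t: (t[0], t[1], t[2], t[4]))
    return [
        StaticGraphlet(
            id=f"G{rank}", n_nodes=n, n_patients=n_p, n_diseases=n_d,
            edges=canon, orbits=orbits,
        )
        for rank, (n, _, n_p, n_d, canon, orbits) in enumerate(ordered)
    ]


def _temporal_sequences(max_edges: int) -> list[tuple[tuple[int, int], ...]]:
    """All edge sequences in first-appearance normal form, connected overall."""
    out = []

    def extend(seq: tuple, n_p: int, n_d: int) -> None:
        if seq:
            edges = set(seq)
            if _connected(edges, n_p, n_d):
                out.append(seq)
        if len(seq) == max_edges:
            return
        for i in range(n_p + 1):
            for j in range(n_d + 1):
                extend(seq + ((i, j),), max(n_p, i + 1), max(n_d, j + 1))

    extend(tuple(), 0, 0)
    return sorted(out, key=lambda s: (len(s), s))


def temporal_catalogue(max_edges: int = 3) -> list[TemporalGraphlet]:
    """Exhaustive catalogue of temporal bipartite graphlets with <= m edges.

    Classes are canonical up to parity-preserving relabeling that fixes
    the (strict) edge order; ids D0, D1, ... follow (m, normal form)
    order, which places the three 2-edge classes at D1 (repeated pair),
    D2 (patient wedge) and D3 (disease wedge).
    """
    if not 1 <= max_edges <= 3:
        raise ValueError("max_edges must be between 1 and 3")
    statics = static_catalogue(4)
    canon_to_id = {(s.n_patients, s.n_diseases, s.edges): s.id for s in statics}
    out = []
    for rank, seq in enumerate(_temporal_sequences(max_edges)):
        n_p = max(i for i, _ in seq) + 1
        n_d = max(j for _, j in seq) + 1
        canon = _canonical_static(set(seq), n_p, n_d)
        out.append(
            TemporalGraphlet(
                id=f"D{rank}", m=len(seq), edges=seq, n_nodes=n_p + n_d,
                n_patients=n_p, n_diseases=n_d,
                static_id=canon_to_id[(n_p, n_d, canon)],
            )
        )
    return out


# --------------------------------------------------------------------------
# 2-edge counting


@dataclass
class GraphletCounts:
    """Counts of the three 2-edge temporal graphlet classes in a window."""

    delta_t: float  # window length, years
    scope: str  # ALL | PRE | POST
    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float]:
        t = self.total
        return {k: (v / t if t else math.nan) for k, v in self.counts.items()}


def _scope_filter(events: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope == "ALL":
        return events
    if scope == "PRE":
        return events[events["years_to_smi"] < 0]
    if scope == "POST":
        return events[events["years_to_smi"] >= 0]
    raise ValueError(f"scope must be ALL, PRE or POST, got {scope!r}")


def _prepare(events: pd.DataFrame, scope: str):
    ev = _scope_filter(events, scope)
    t = ev["timestamp"].to_numpy().astype("datetime64[D]").astype(np.int64)
    if np.any(np.diff(t) < 0):
        raise ValueError("events must be sorted by timestamp")
    p = pd.factorize(ev["patient_id"])[0]
    d = pd.factorize(ev["code3"])[0]
    return t, p, d


def count_2edge(
    events: pd.DataFrame, delta_t: float, scope: str = "ALL"
) -> GraphletCounts:
    """Count ordered event pairs (t1 < t2, t2 - t1 <= dt) sharing a node.

    Sweep over the time-sorted stream with counters of window occupancy
    per patient, per disease and per (patient, disease) pair; ties in
    timestamp are inserted as a block after being counted against, so
    simultaneous events never pair.  ``delta_t`` is in years (365.25-day
    years internally); the scope restricts to pre- or post-index events.
    """
    if delta_t < 0:
        raise ValueError("delta_t must be nonnegative")
    t, p, d = _prepare(events, scope)
    window = delta_t * DAYS_PER_YEAR
    counts = {"D1": 0, "D2": 0, "D3": 0}
    n = len(t)
    cnt_p: dict[int, int] = {}
    cnt_d: dict[int, int] = {}
    cnt_pair: dict[tuple[int, int], int] = {}
    head = 0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        # expire events older than the window relative to this block
        while head < i and t[i] - t[head] > window:
            ph, dh = p[head], d[head]
            cnt_p[ph] -= 1
            cnt_d[dh] -= 1
            cnt_pair[(ph, dh)] -= 1
            head += 1
        for k in range(i, j):
            pk, dk = p[k], d[k]
            same_pair = cnt_pair.get((pk, dk), 0)
            counts["D1"] += same_pair
            counts["D2"] += cnt_p.get(pk, 0) - same_pair
            counts["D3"] += cnt_d.get(dk, 0) - same_pair
        for k in range(i, j):
            pk, dk = p[k], d[k]
            cnt_p[pk] = cnt_p.get(pk, 0) + 1
            cnt_d[dk] = cnt_d.get(dk, 0) + 1
            cnt_pair[(pk, dk)] = cnt_pair.get((pk, dk), 0) + 1
        i = j
    return GraphletCounts(delta_t=delta_t, scope=scope, counts=counts)


def count_2edge_bruteforce(
    events: pd.DataFrame, delta_t: float, scope: str = "ALL"
) -> GraphletCounts:
    """Oracle twin of count_2edge: explicit loop over all ordered pairs."""
    if delta_t < 0:
        raise ValueError("delta_t must be nonnegative")
    t, p, d = _prepare(events, scope)
    window = delta_t * DAYS_PER_YEAR
    counts = {"D1": 0, "D2": 0, "D3": 0}
    n = len(t)
    for i in range(n):
        for j in range(i + 1, n):
            dt = t[j] - t[i]
            if dt <= 0:
                continue
            if dt > window:
                break
            same_p = p[i] == p[j]
            same_d = d[i] == d[j]
            if same_p and same_d:
                counts["D1"] += 1
            elif same_p:
                counts["D2"] += 1
            elif same_d:
                counts["D3"] += 1
    return GraphletCounts(delta_t=delta_t, scope=scope, counts=counts)
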