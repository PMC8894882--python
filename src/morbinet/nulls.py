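"""Degree-preserving null model for bipartite networks.

Random counterparts of an observed patient-diagnosis network are drawn
by repeated double-edge swaps: given edges A-X and B-Y (A, B patients;
X, Y diseases), replace them with A-Y and B-X unless that would
duplicate an existing edge.  Both degree sequences are preserved
exactly; edge weights are reset to 1, so any statistic compared against
this ensemble must be weight-free.

Significance of an observed statistic phi_o is a z-score against the
null ensemble, z = (phi_o - <phi_r>) / sigma(phi_r), with a two-tailed
p-value from the standard normal; the empirical percentile of phi_o in
the ensemble is carried along for diagnostics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import numpy as np
from scipy import stats

from .networks import BipartiteNetwork

__all__ = ["NullTestResult", "rewire", "null_test"]

logger = logging.getLogger(__name__)


def rewire(
    network: BipartiteNetwork,
    n_swaps: int | None = None,
    rng: np.random.Generator | None = None,
) -> BipartiteNetwork:
    """Return a degree-preserving randomization of ``network``.

    Performs ``n_swaps`` accepted double-edge swaps (default 10x the
    edge count); candidate swaps that would create a duplicate edge or
    involve a shared endpoint are rejected and retried.  On networks
    admitting no valid swap (e.g. complete bipartite) an identical copy
    is returned with a logged warning.
    """
    g = network.graph
    if g.number_of_edges() < 2:
        raise ValueError("rewiring needs at least 2 edges")
    rng = rng if rng is not None else np.random.default_rng()
    # integer-encode the edge list: the swap chain is the hot loop
    patients = network.patients
    diseases = network.diseases
    p_index = {u: i for i, u in enumerate(patients)}
    d_index = {v: j for j, v in enumerate(diseases)}
    n_d = len(diseases)
    pa: list[int] = []
    da: list[int] = []
    for u, v in g.edges():
        if g.nodes[u]["kind"] != "patient":
            u, v = v, u
        pa.append(p_index[u])
        da.append(d_index[v])
    m = len(pa)
    if n_swaps is None:
        n_swaps = 10 * m
    edge_set = {p * n_d + d for p, d in zip(pa, da)}
    contains = edge_set.__contains__
    discard = edge_set.discard
    add = edge_set.add
    accepted = 0
    attempts = 0
    max_attempts = max(100 * n_swaps, 1000)
    block = rng.integers(0, m, size=2 * max(n_swaps, 256)).tolist()
    bi = 0
    while accepted < n_swaps and attempts < max_attempts:
        if bi >= len(block):
            block = rng.integers(0, m, size=len(block)).tolist()
            bi = 0
        i = block[bi]
        j = block[bi + 1]
        bi += 2
        attempts += 1
        a, x = pa[i], da[i]
        b, y = pa[j], da[j]
        if a == b or x == y or contains(a * n_d + y) or contains(b * n_d + x):
            continue
        discard(a * n_d + x)
        discard(b * n_d + y)
        add(a * n_d + y)
        add(b * n_d + x)
        da[i] = y
        da[j] = x
        accepted += 1
    if accepted < n_swaps:
        logger.warning(
            "rewire stopped after %d/%d accepted swaps (%d attempts); "
            "network may admit no further valid swap", accepted, n_swaps, attempts,
        )
    out = nx.Graph()
    out.add_nodes_from(g.nodes(data=True))
    out.add_edges_from(
        (patients[p], diseases[d], {"weight": 1}) for p, d in zip(pa, da)
    )
    return BipartiteNetwork(graph=out, window=network.window, label=network.label)


@dataclass
class NullTestResult:
    """Observed statistic against the degree-preserving null ensemble."""

    name: str
    observed: float
    null_mean: float
    null_sd: float
    z: float  # NaN when the null is degenerate (sd == 0)
    p_two_tailed: float
    n_replicates: int
    seed: int | None
    empirical_percentile: float
    null_values: np.ndarray = field(repr=False, default=None)


def null_test(
    network: BipartiteNetwork,
    statistic: Callable[[BipartiteNetwork], float],
    n_replicates: int = 1000,
    n_swaps: int | None = None,
    seed: int | None = None,
    name: str = "statistic",
) -> NullTestResult:
    """z-score an arbitrary scalar network statistic against the null."""
    rng = np.random.default_rng(seed)
    observed = float(statistic(network))
    null_values = np.array(
        [float(statistic(rewire(network, n_swaps, rng))) for _ in range(n_replicates)]
    )
    mean = float(null_values.mean())
    sd = float(null_values.std(ddof=1)) if n_replicates > 1 else 0.0
    if sd > 0:
        z = (observed - mean) / sd
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        z, p = math.nan, math.nan
    percentile = float(100.0 * (null_values < observed).mean())
    return NullTestResult(
        name=name, observed=observed, null_mean=mean, null_sd=sd, z=z,
        p_two_tailed=p, n_replicates=n_replicates, seed=seed,
        empirical_percentile=percentile, null_values=null_values,
    )
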