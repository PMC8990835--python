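"""Whole-graph topology statistics used as robustness indicators.

Four statistics summarize a disease network's topology:

* **AD** — average degree, ``sum(deg(v)) / n``.
* **ASPL** — average shortest path length over ordered reachable pairs.
* **DC** — Freeman degree centralization,
  ``sum(deg(v*) - deg(v)) / ((n-1)(n-2))`` where ``v*`` attains the
  maximal degree.  1 on a star, 0 on any vertex-transitive graph.
* **CC** — closeness centralization,
  ``sum(clo(v#) - clo(v)) / ((n-1)(n-2)/(2n-3))`` where ``v#`` attains
  the maximal closeness.  Also 1 on a star and 0 on vertex-transitive
  graphs.

Node-deletion attacks routinely fragment a network, so the conventions
for disconnected graphs are explicit:

* ASPL averages over ordered *reachable* pairs only; a graph with no
  edges has no reachable pair and ASPL is undefined (NaN, never 0).
* Closeness uses the Wasserman-Faust component-scaled form
  ``clo(v) = ((n_C - 1)/(n - 1)) * ((n_C - 1) / sum_{t in C} d(v, t))``
  for ``v`` in component ``C``; an isolated node has closeness 0.  On a
  connected graph this reduces to the classic ``(n-1)/sum d(v, t)``.
* Centralizations need ``n >= 3`` (the normalizer ``(n-1)(n-2)`` must
  be positive); smaller graphs yield 0 with a logged warning so that an
  attack that shrinks a subnetwork below 3 nodes still produces a full
  profile.

Undefined values are carried as ``float('nan')`` and propagate through
downstream relative changes and z-scores; they are never coerced to 0.

All distances are unweighted (every interaction has length 1).  The
production distance routine is igraph's C all-pairs BFS; every
statistic is then a closed-form reduction of the one distance matrix,
so a profile is computed from a single pass.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TopologyProfile",
    "average_degree",
    "average_shortest_path_length",
    "degree_centralization",
    "closeness_centralization",
    "topology_profile",
]

#: Conventions recorded in profile metadata / run manifests.
CONVENTIONS = (
    "aspl=mean-over-reachable-ordered-pairs;"
    "closeness=wasserman-faust;"
    "centralization(n<3)=0;"
    "undefined=NaN"
)


@dataclass(frozen=True)
class TopologyProfile:
    """The four whole-graph statistics plus bookkeeping counts.

    ``aspl`` is NaN when no ordered pair is reachable (edgeless graph).
    """

    ad: float
    aspl: float
    dc: float
    cc: float
    n_nodes: int
    n_edges: int
    n_components: int
    conventions: str = CONVENTIONS

    def as_dict(self) -> dict[str, float | int | str]:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_components": self.n_components,
            "ad": self.ad,
            "aspl": self.aspl,
            "dc": self.dc,
            "cc": self.cc,
            "conventions": self.conventions,
        }


def _require_nonempty(net: nx.Graph) -> None:
    if net.number_of_nodes() == 0:
        raise ValueError("statistic undefined on an empty network")


def _distances_from_edges(n: int, edges: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path distances via igraph's C
    BFS; +inf for unreachable pairs.  ``edges`` is an (m, 2) integer
    array over nodes ``0..n-1``."""
    if len(edges) == 0:
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    g = ig.Graph(n=n, edges=edges.tolist(), directed=False)
    return np.asarray(g.distances(), dtype=float)


def _edge_array(net: nx.Graph) -> tuple[int, np.ndarray]:
    """Map a labeled graph to (n, integer edge array) with node order
    following ``net.nodes``."""
    index = {v: i for i, v in enumerate(net.nodes)}
    edges = np.array(
        [(index[a], index[b]) for a, b in net.edges()], dtype=np.int64
    ).reshape(-1, 2)
    return len(index), edges


def _distance_matrix(net: nx.Graph) -> np.ndarray:
    n, edges = _edge_array(net)
    return _distances_from_edges(n, edges)


def _degrees(net: nx.Graph) -> np.ndarray:
    return np.array([d for _, d in net.degree()], dtype=float)


def _degrees_from_edges(n: int, edges: np.ndarray) -> np.ndarray:
    deg = np.zeros(n)
    if len(edges):
        np.add.at(deg, edges[:, 0], 1.0)
        np.add.at(deg, edges[:, 1], 1.0)
    return deg


def average_degree(net: nx.Graph) -> float:
    """Average degree ``sum(deg(v)) / n`` (equals ``2m/n``)."""
    _require_nonempty(net)
    return 2.0 * net.number_of_edges() / net.number_of_nodes()


def _aspl_from_distances(dist: np.ndarray) -> float:
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(dist) & off
    k = int(finite.sum())
    if k == 0:
        return math.nan
    return float(dist[finite].sum() / k)


def average_shortest_path_length(net: nx.Graph) -> float:
    """Mean shortest-path length over ordered reachable pairs.

    On a connected graph this is the textbook
    ``sum d(s,t) / (n(n-1))``; on a fragmented graph unreachable pairs
    are simply excluded from the average.  Returns NaN when no pair is
    reachable (no edges at all).
    """
    _require_nonempty(net)
    return _aspl_from_distances(_distance_matrix(net))


def _dc_from_degrees(deg: np.ndarray) -> float:
    n = deg.size
    if n < 3:
        logger.warning("degree centralization undefined for n=%d < 3; returning 0", n)
        return 0.0
    return float((deg.max() - deg).sum() / ((n - 1) * (n - 2)))


def degree_centralization(net: nx.Graph) -> float:
    """Freeman degree centralization of the whole graph.

    ``sum_v [deg(v*) - deg(v)] / ((n-1)(n-2))`` with ``v*`` the
    maximal-degree node.  The formula depends only on the maximal
    degree value, so ties among maximal nodes are irrelevant.
    """
    _require_nonempty(net)
    return _dc_from_degrees(_degrees(net))


def _closeness_from_distances(dist: np.ndarray) -> np.ndarray:
    """Wasserman-Faust closeness for every node, from the distance
    matrix.  Isolated nodes get 0."""
    n = dist.shape[0]
    if n == 1:
        return np.zeros(1)
    finite = np.isfinite(dist)
    n_comp = finite.sum(axis=1).astype(float)  # component size incl. self
    totals = np.where(finite, dist, 0.0).sum(axis=1)
    clo = np.zeros(n)
    reachable = totals > 0
    nc1 = n_comp - 1.0
    clo[reachable] = (nc1[reachable] / (n - 1)) * (nc1[reachable] / totals[reachable])
    return clo


def _cc_from_closeness(clo: np.ndarray) -> float:
    n = clo.size
    if n < 3:
        logger.warning("closeness centralization undefined for n=%d < 3; returning 0", n)
        return 0.0
    return float((clo.max() - clo).sum() * (2 * n - 3) / ((n - 1) * (n - 2)))


def closeness_centralization(net: nx.Graph) -> float:
    """Closeness centralization of the whole graph.

    ``sum_v [clo(v#) - clo(v)] / ((n-1)(n-2)/(2n-3))`` with ``v#`` the
    maximal-closeness node and ``clo`` the (component-scaled) closeness.
    """
    _require_nonempty(net)
    return _cc_from_closeness(_closeness_from_distances(_distance_matrix(net)))


def profile_from_edges(n: int, edges: np.ndarray) -> TopologyProfile:
    """Profile of the graph given as (node count, integer edge array).

    This is the computational core behind :func:`topology_profile`;
    the permutation null uses it directly so that thousands of random
    replicates skip labeled-graph construction.
    """
    if n == 0:
        raise ValueError("statistic undefined on an empty network")
    dist = _distances_from_edges(n, edges)
    deg = _degrees_from_edges(n, edges)
    # each node contributes 1/|its component|; the sum counts components
    comp_sizes = np.isfinite(dist).sum(axis=1).astype(float)
    n_components = int(round((1.0 / comp_sizes).sum()))
    return TopologyProfile(
        ad=float(deg.sum() / n),
        aspl=_aspl_from_distances(dist),
        dc=_dc_from_degrees(deg),
        cc=_cc_from_closeness(_closeness_from_distances(dist)),
        n_nodes=n,
        n_edges=int(len(edges)),
        n_components=n_components,
    )


def topology_profile(net: nx.Graph) -> TopologyProfile:
    """Compute all four statistics plus node/edge/component counts from
    one distance-matrix pass."""
    _require_nonempty(net)
    n, edges = _edge_array(net)
    return profile_from_edges(n, edges)
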