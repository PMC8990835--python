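"""Independent brute-force oracles for the topology statistics.

Deliberately naive: Floyd-Warshall distances over dict-of-dict tables
and direct evaluation of the printed formulas, sharing no code with
the production implementation.
"""

from __future__ import annotations

import math

import networkx as nx

INF = math.inf


def fw_distances(g: nx.Graph) -> dict:
    """All-pairs shortest paths by textbook Floyd-Warshall."""
    nodes = list(g.nodes)
    dist = {u: {v: (0 if u == v else INF) for v in nodes} for u in nodes}
    for a, b in g.edges():
        dist[a][b] = 1
        dist[b][a] = 1
    for k in nodes:
        for i in nodes:
            dik = dist[i][k]
            if dik is INF:
                continue
            for j in nodes:
                alt = dik + dist[k][j]
                if alt < dist[i][j]:
                    dist[i][j] = alt
    return dist


def oracle_average_degree(g: nx.Graph) -> float:
    return sum(d for _, d in g.degree()) / g.number_of_nodes()


def oracle_aspl(g: nx.Graph) -> float:
    dist = fw_distances(g)
    lengths = [
        dist[s][t]
        for s in g.nodes
        for t in g.nodes
        if s != t and dist[s][t] < INF
    ]
    if not lengths:
        return math.nan
    return sum(lengths) / len(lengths)


def oracle_dc(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 3:
        return 0.0
    degs = [d for _, d in g.degree()]
    mx = max(degs)
    return sum(mx - d for d in degs) / ((n - 1) * (n - 2))


def oracle_closeness(g: nx.Graph) -> dict:
    """Wasserman-Faust component-scaled closeness, from first
    principles."""
    n = g.number_of_nodes()
    dist = fw_distances(g)
    clo = {}
    for v in g.nodes:
        reach = [t for t in g.nodes if t != v and dist[v][t] < INF]
        if not reach:
            clo[v] = 0.0
            continue
        n_c = len(reach) + 1
        total = sum(dist[v][t] for t in reach)
        clo[v] = ((n_c - 1) / (n - 1)) * ((n_c - 1) / total)
    return clo


def oracle_cc(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 3:
        return 0.0
    clo = oracle_closeness(g)
    mx = max(clo.values())
    return sum(mx - c for c in clo.values()) / ((n - 1) * (n - 2) / (2 * n - 3))
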