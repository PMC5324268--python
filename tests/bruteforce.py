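"""Exhaustive all-paths centrality oracle for small graphs.

Independent of the production implementation: distances by Floyd-Warshall,
shortest paths enumerated explicitly by depth-first search, metrics summed
directly from the path lists.  Exponential, intended for graphs of ~12 nodes.
"""

from __future__ import annotations

import itertools

import networkx as nx

INF = float("inf")


def _distances(g: nx.Graph) -> dict:
    nodes = list(g.nodes)
    d = {(u, v): (0 if u == v else (1 if g.has_edge(u, v) else INF))
         for u in nodes for v in nodes}
    for k in nodes:
        for i in nodes:
            for j in nodes:
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def _all_shortest_paths(g: nx.Graph, s, t, d) -> list[list]:
    if d[s, t] == INF:
        return []
    if s == t:
        return [[s]]
    paths = []
    for u in g.neighbors(s):
        if d[u, t] == d[s, t] - 1:
            for rest in _all_shortest_paths(g, u, t, d):
                paths.append([s] + rest)
    return paths


def brute_profile(g: nx.Graph) -> dict:
    """All six metrics by direct enumeration; same conventions as production."""
    nodes = list(g.nodes)
    d = _distances(g)

    b_raw = {n: 0.0 for n in nodes}
    eb = {tuple(sorted(e, key=str)): 0.0 for e in g.edges}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(g, s, t, d)
        if not paths:
            continue
        sigma = len(paths)
        for p in paths:
            for n in p[1:-1]:
                b_raw[n] += 1.0 / sigma
            for u, v in zip(p, p[1:]):
                eb[tuple(sorted((u, v), key=str))] += 1.0 / sigma

    comp_of = {}
    for comp in nx.connected_components(g):
        for n in comp:
            comp_of[n] = comp

    b_norm = {}
    for n in nodes:
        size = len(comp_of[n])
        denom = (size - 1) * (size - 2) / 2.0
        b_norm[n] = b_raw[n] / denom if denom > 0 else 0.0

    closeness, ecc = {}, {}
    for n in nodes:
        dists = [d[n, m] for m in nodes if m != n and d[n, m] < INF]
        closeness[n] = len(dists) / sum(dists) if dists and sum(dists) > 0 else 0.0
        ecc[n] = int(max(dists)) if dists else 0

    clustering = {}
    for n in nodes:
        nbrs = list(g.neighbors(n))
        k = len(nbrs)
        if k < 2:
            clustering[n] = 0.0
        else:
            links = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
            clustering[n] = 2.0 * links / (k * (k - 1))

    return {
        "b_ct_raw": b_raw,
        "b_ct": b_norm,
        "eb_ct": eb,
        "degree": {n: g.degree(n) for n in nodes},
        "cc_ct": clustering,
        "c_ct": closeness,
        "e_ct": ecc,
    }
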