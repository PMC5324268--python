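"""Centrality metrics of residue interaction graphs.

Five node metrics and one edge metric on an undirected, unweighted graph:
betweenness centrality B_ct, degree D, clustering coefficient CC_ct,
closeness C_ct, eccentricity E_ct, and edge betweenness EB_ct.  Shortest
paths are hop counts; ties contribute fractionally through path counts
(Brandes accumulation via networkx), never by arbitrary tie-breaking.

Normalization conventions (they matter on disconnected graphs, which real
residue networks can be):

* B_ct is the raw pair-sum divided by (N'-1)(N'-2)/2 where N' is the size of
  the node's connected component, giving values in [0, 1]; this matches the
  NetworkAnalyzer convention and makes the reported magnitudes comparable
  across components.  Raw values are retained alongside.
* C_ct is the inverse of the mean shortest-path distance to the nodes
  *reachable* from n (component-local); isolated nodes get 0.
* E_ct is the maximum finite shortest-path distance (0 for isolated nodes).
* CC_ct for degree <= 1 is defined as 0 (the triangle fraction is 0/0 there).
* EB_ct is reported raw (unnormalized pair-sum), one value per edge.

B_ct and C_ct are additionally reported on a display scale (×100 by
default), the scale on which Δ statistics are quoted downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable

import networkx as nx
import pandas as pd

__all__ = [
    "CentralityProfile",
    "betweenness",
    "edge_betweenness",
    "degree",
    "clustering",
    "closeness",
    "eccentricity",
    "profile",
    "REPORT_SCALE",
]

#: default display scale for B_ct and C_ct
REPORT_SCALE = 100.0


def betweenness(g: nx.Graph) -> dict[Hashable, float]:
    """Pair-normalized betweenness centrality in [0, 1] (per component)."""
    raw = nx.betweenness_centrality(g, normalized=False)
    out = {}
    for comp in nx.connected_components(g):
        n = len(comp)
        denom = (n - 1) * (n - 2) / 2.0
        for node in comp:
            out[node] = raw[node] / denom if denom > 0 else 0.0
    return {n: out[n] for n in g.nodes}  # stable: graph insertion order


def betweenness_raw(g: nx.Graph) -> dict[Hashable, float]:
    """Unnormalized pair-sum betweenness (each unordered pair counted once)."""
    return nx.betweenness_centrality(g, normalized=False)


def edge_betweenness(g: nx.Graph) -> dict[tuple, float]:
    """Raw edge betweenness: shortest-path load per edge, endpoint pairs included."""
    return nx.edge_betweenness_centrality(g, normalized=False)


def degree(g: nx.Graph) -> dict[Hashable, int]:
    return {n: int(d) for n, d in g.degree()}


def clustering(g: nx.Graph) -> dict[Hashable, float]:
    """Triangle fraction 2e_n / k_n(k_n - 1); zero for degree <= 1."""
    return {n: float(v) for n, v in nx.clustering(g).items()}


def closeness(g: nx.Graph) -> dict[Hashable, float]:
    """Inverse mean distance to reachable nodes; 0 for isolated nodes."""
    # wf_improved=False gives (n'-1)/sum(d) within the component = 1/mean(d)
    return nx.closeness_centrality(g, wf_improved=False)


def eccentricity(g: nx.Graph) -> dict[Hashable, int]:
    """Maximum finite shortest-path distance from each node (0 if isolated)."""
    out = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) == 1:
            out.update({n: 0 for n in comp})
        else:
            out.update({n: int(e) for n, e in nx.eccentricity(sub).items()})
    return {n: out[n] for n in g.nodes}


@dataclass
class CentralityProfile:
    """All metrics of one graph, with the declared reporting scale."""

    b_ct: dict[Hashable, float]
    b_ct_raw: dict[Hashable, float]
    degree: dict[Hashable, int]
    cc_ct: dict[Hashable, float]
    c_ct: dict[Hashable, float]
    e_ct: dict[Hashable, int]
    eb_ct: dict[tuple, float] = field(default_factory=dict)
    report_scale: float = REPORT_SCALE

    def b_ct_scaled(self, node: Hashable) -> float:
        return self.b_ct[node] * self.report_scale

    def c_ct_scaled(self, node: Hashable) -> float:
        return self.c_ct[node] * self.report_scale

    def node_table(self) -> pd.DataFrame:
        """Per-node metric table (one row per node, stable node order)."""
        rows = [
            {
                "node": n,
                "b_ct_raw": self.b_ct_raw[n],
                "b_ct": self.b_ct[n],
                "b_ct_scaled": self.b_ct[n] * self.report_scale,
                "degree": self.degree[n],
                "cc_ct": self.cc_ct[n],
                "c_ct": self.c_ct[n],
                "c_ct_scaled": self.c_ct[n] * self.report_scale,
                "e_ct": self.e_ct[n],
            }
            for n in self.b_ct
        ]
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [{"edge": f"{u}--{v}", "eb_ct": w} for (u, v), w in self.eb_ct.items()]
        return pd.DataFrame(rows, columns=["edge", "eb_ct"])


def profile(g: nx.Graph, report_scale: float = REPORT_SCALE) -> CentralityProfile:
    """Compute the full centrality profile of a graph (deterministic)."""
    return CentralityProfile(
        b_ct=betweenness(g),
        b_ct_raw=betweenness_raw(g),
        degree=degree(g),
        cc_ct=clustering(g),
        c_ct=closeness(g),
        e_ct=eccentricity(g),
        eb_ct=edge_betweenness(g),
        report_scale=report_scale,
    )
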