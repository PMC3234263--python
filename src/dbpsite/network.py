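"""Residue contact network and centrality scores.

A protein chain is recast as an undirected graph whose vertices are the
alpha carbons of its residues; an edge joins two vertices whose Calpha
distance is at most 8 A.  Betweenness centrality of a vertex v is the sum
over unordered vertex pairs (s, t), s != v != t, of the fraction of
shortest s-t paths passing through v, normalized by the pair count
(n - 1)(n - 2) / 2 so that chains of different length are comparable.
Unreachable pairs contribute zero; degree is normalized by (n - 1) and
closeness uses the within-component convention (zero for isolated
vertices).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from .structure import Residue

__all__ = [
    "CONTACT_CUTOFF",
    "ContactGraph",
    "build_contact_graph",
    "betweenness_centrality",
    "degree_centrality",
    "closeness_centrality",
    "edge_list_table",
]

CONTACT_CUTOFF = 8.0

ResidueKey = tuple[str, int, str]


@dataclass
class ContactGraph:
    graph: nx.Graph
    order: list[ResidueKey] = field(default_factory=list)
    degenerate: bool = False  # fewer than 3 vertices: BC normalizer undefined

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()


def build_contact_graph(
    residues: list[Residue], cutoff: float = CONTACT_CUTOFF
) -> ContactGraph:
    """Calpha contact graph of one chain at the given distance cutoff.

    Residues lacking a Calpha are excluded with a warning.  Edges are
    inclusive of the cutoff.
    """
    keys: list[ResidueKey] = []
    coords = []
    for res in residues:
        ca = res.ca_coord
        if ca is None:
            warnings.warn(f"residue {res.label()} lacks CA; excluded from graph")
            continue
        keys.append(res.key)
        coords.append(ca)
    graph = nx.Graph()
    graph.add_nodes_from(keys)
    if coords:
        arr = np.asarray(coords)
        tree = cKDTree(arr)
        for i, j in sorted(tree.query_pairs(cutoff)):
            graph.add_edge(keys[i], keys[j], distance=float(np.linalg.norm(arr[i] - arr[j])))
    degenerate = graph.number_of_nodes() < 3
    if degenerate:
        warnings.warn("contact graph has fewer than 3 vertices; BC normalization degenerate")
    return ContactGraph(graph=graph, order=keys, degenerate=degenerate)


def betweenness_centrality(contact: ContactGraph) -> dict[ResidueKey, float]:
    """Normalized betweenness per residue (Brandes accumulation).

    Each unordered pair is counted once and the per-vertex sum is divided
    by (n - 1)(n - 2) / 2; graphs with fewer than 3 vertices return all
    zeros.
    """
    if contact.degenerate:
        return {k: 0.0 for k in contact.order}
    return dict(nx.betweenness_centrality(contact.graph, normalized=True))


def degree_centrality(contact: ContactGraph) -> dict[ResidueKey, float]:
    """Degree normalized by (n - 1); zero for singleton graphs."""
    if contact.n <= 1:
        return {k: 0.0 for k in contact.order}
    return dict(nx.degree_centrality(contact.graph))


def closeness_centrality(contact: ContactGraph) -> dict[ResidueKey, float]:
    """Closeness = (reachable count) / (sum of shortest-path lengths).

    Computed within the vertex's connected component (no cross-component
    rescaling); isolated vertices score zero.
    """
    return dict(nx.closeness_centrality(contact.graph, wf_improved=False))


def edge_list_table(contact: ContactGraph):
    """Edge list as a DataFrame (res_i, res_j, distance) for inspection."""
    import pandas as pd

    rows = [
        {"res_i": "{}{}{}".format(*u), "res_j": "{}{}{}".format(*v),
         "distance": d}
        for u, v, d in contact.graph.edges(data="distance")
    ]
    return pd.DataFrame(rows, columns=["res_i", "res_j", "distance"])
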