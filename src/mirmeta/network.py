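"""Interaction-network summaries: degree-based hub selection and connected
components for a simple undirected gene network."""
from __future__ import annotations

import networkx as nx
import pandas as pd

from .datatypes import ValidationError


def build_network(edges, nodes=None) -> nx.Graph:
    """Simple undirected graph from (u, v) pairs; self-loops dropped and
    duplicate edges collapsed."""
    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(str(n) for n in nodes)
    for u, v in edges:
        u, v = str(u), str(v)
        if u != v:
            g.add_edge(u, v)
    return g


def degree_hubs(net: nx.Graph, min_degree: int = 5) -> pd.DataFrame:
    """Nodes with degree >= min_degree (unique neighbors), sorted by degree
    descending then name."""
    if min_degree < 0:
        raise ValidationError("min_degree must be >= 0")
    rows = [
        {"gene": n, "degree": d} for n, d in net.degree() if d >= min_degree
    ]
    return (
        pd.DataFrame(rows, columns=["gene", "degree"])
        .sort_values(["degree", "gene"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )


def components(net: nx.Graph) -> list[set[str]]:
    """Connected components, largest first (ties by smallest member name)."""
    comps = [set(c) for c in nx.connected_components(net)]
    return sorted(comps, key=lambda c: (-len(c), min(c)))
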