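"""Conserved-subnetwork extraction and transcription-factor connectivity.

Two independently inferred networks (e.g. in vitro and in vivo) are
intersected edge-for-edge; the connected components of the intersection are
the conserved subnetworks. TF hub tables count per-TF degree in each
network and flag hubs and system-biased TFs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .clr import CLRNetwork

__all__ = [
    "ConservedSubnetworks",
    "intersect_networks",
    "connected_components",
    "tf_degree_table",
    "degree_ratio_flags",
]


@dataclass
class Component:
    nodes: list[str]
    edges: list[tuple[str, str]]
    tfs: list[str] = field(default_factory=list)
    direction_consistent: bool | None = None


@dataclass
class ConservedSubnetworks:
    """Edges present in both input networks, organized into components."""

    edges: set[frozenset]
    components: list[Component]

    @property
    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def connected_components(edges) -> list[list[str]]:
    """Components of an undirected edge set, ordered by size (desc) then
    by lexicographically smallest member; nodes sorted within each."""
    g = nx.Graph()
    for e in edges:
        a, b = tuple(e)
        g.add_edge(a, b)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


def intersect_networks(
    a: CLRNetwork,
    b: CLRNetwork,
    tf_ids=None,
    directions_a: dict | None = None,
    directions_b: dict | None = None,
) -> ConservedSubnetworks:
    """Unordered-pair intersection of two undirected networks.

    Optionally annotates each component with its member TFs and, given
    per-gene regulation directions from the two systems' DE results, a flag
    marking components whose members all agree in direction within and
    across systems.
    """
    conserved = a.edge_set() & b.edge_set()
    tf_ids = set(tf_ids or ())
    comps = []
    for nodes in connected_components(conserved):
        node_set = set(nodes)
        comp_edges = sorted(
            tuple(sorted(e)) for e in conserved if e <= node_set
        )
        flag = None
        if directions_a is not None and directions_b is not None:
            dirs = {directions_a.get(n) for n in nodes} | {
                directions_b.get(n) for n in nodes
            }
            flag = len(dirs) == 1 and None not in dirs
        comps.append(
            Component(
                nodes=nodes,
                edges=comp_edges,
                tfs=sorted(node_set & tf_ids),
                direction_consistent=flag,
            )
        )
    return ConservedSubnetworks(edges=conserved, components=comps)


def tf_degree_table(
    net: CLRNetwork, tf_ids, min_connections: int = 15
) -> pd.DataFrame:
    """Per-TF degree with a hub highlight flag (strictly more than the cutoff).

    TFs absent from the network are reported with degree 0.
    """
    degree: dict[str, int] = {tf: 0 for tf in tf_ids}
    for a, b in zip(net.edges["gene_a"], net.edges["gene_b"]):
        if a in degree:
            degree[a] += 1
        if b in degree:
            degree[b] += 1
    table = pd.DataFrame(
        {
            "tf": sorted(degree),
            "degree": [degree[t] for t in sorted(degree)],
        }
    )
    table["hub"] = table["degree"] > min_connections
    return table


def degree_ratio_flags(
    degrees_a: dict, degrees_b: dict, ratio: float = 2.0
) -> pd.DataFrame:
    """Flag TFs whose degree differs by >= ``ratio``-fold between networks.

    Zero-degree convention: positive-vs-zero is flagged; zero-vs-zero is not.
    """
    tfs = sorted(set(degrees_a) | set(degrees_b))
    rows = []
    for tf in tfs:
        da = int(degrees_a.get(tf, 0))
        db = int(degrees_b.get(tf, 0))
        a_high = da >= ratio * db and da > 0
        b_high = db >= ratio * da and db > 0
        rows.append(
            {
                "tf": tf,
                "degree_a": da,
                "degree_b": db,
                "biased_to": "a" if a_high else ("b" if b_high else "none"),
            }
        )
    return pd.DataFrame(rows)
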