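"""PPI graph construction, cleaning, and edge-level topology.

The interaction graph is an undirected simple graph: self-interactions are
dropped and redundant interaction records collapse onto one edge. Small
disconnected components (1-3 proteins interacting only among themselves)
carry no information for network-propagated scores and are filtered out.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

from diffslc.io import InteractionRecord

__all__ = [
    "EdgeWeights",
    "edge_key",
    "build_network",
    "filter_small_components",
    "count_edge_triangles",
    "edge_clustering_coefficient",
    "all_edge_weights",
    "write_edge_list",
]

log = logging.getLogger(__name__)


def edge_key(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered-pair key: endpoints in lexicographic order."""
    return (u, v) if u <= v else (v, u)


@dataclass
class EdgeWeights:
    """Per-edge ECC and coexpression values, keyed on canonical pairs."""

    ecc: dict[tuple[str, str], float] = field(default_factory=dict)
    coexpr: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mapping in (self.ecc, self.coexpr):
            for u, v in mapping:
                if u > v:
                    raise ValueError(f"edge key ({u}, {v}) not in canonical order")


def build_network(records: Iterable[InteractionRecord]) -> nx.Graph:
    """Build the undirected simple interaction graph from MITAB records.

    Self-interactions are removed and duplicate pairs (in either order)
    collapse to a single edge. An empty record list yields an empty graph.
    """
    net = nx.Graph()
    n_self = 0
    for rec in records:
        if rec.interactor_a == rec.interactor_b:
            n_self += 1
            continue
        net.add_edge(rec.interactor_a, rec.interactor_b)
    if n_self:
        log.info("removed %d self-interaction records", n_self)
    return net


def filter_small_components(net: nx.Graph, max_size: int = 3) -> nx.Graph:
    """Drop every connected component of ``max_size`` or fewer nodes.

    Isolated nodes count as size-1 components. Returns a new graph; the
    operation is idempotent.
    """
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    keep: set[str] = set()
    for component in nx.connected_components(net):
        if len(component) > max_size:
            keep.update(component)
    return net.subgraph(keep).copy()


def count_edge_triangles(net: nx.Graph, edge: tuple[str, str]) -> int:
    """Number of triangles through an edge: |N(u) ∩ N(v)|."""
    u, v = edge
    if not net.has_edge(u, v):
        raise KeyError(f"edge {edge} not in network")
    return len(set(net[u]) & set(net[v]))


def edge_clustering_coefficient(
    net: nx.Graph, edge: tuple[str, str], denominator: str = "degree"
) -> float:
    """Edge clustering coefficient: (z + 1) / min(k_u - 1, k_v - 1).

    ``z`` is the triangle count through the edge and ``k`` the endpoint
    degree, so the denominator is the maximum number of triangles the edge
    could participate in. With ``denominator="triangles"``, k_u, k_v are
    instead the endpoints' own triangle counts (an alternative reading of
    the formula's k). Pendant edges, where the denominator vanishes, return
    0: such an edge can belong to no triangle.
    """
    u, v = edge
    if not net.has_edge(u, v):
        raise KeyError(f"edge {edge} not in network")
    z = count_edge_triangles(net, edge)
    if denominator == "degree":
        ku, kv = net.degree(u), net.degree(v)
    elif denominator == "triangles":
        tri = nx.triangles(net, [u, v])
        ku, kv = tri[u], tri[v]
    else:
        raise ValueError(f"unknown denominator mode {denominator!r}")
    denom = min(ku - 1, kv - 1)
    if denom <= 0:
        return 0.0
    return (z + 1) / denom


def all_edge_weights(
    net: nx.Graph,
    coexpr: Mapping[tuple[str, str], float] | None = None,
    denominator: str = "degree",
    missing_coexpr: float = 0.0,
) -> EdgeWeights:
    """Assemble complete per-edge weights: ECC plus coexpression.

    ECC is computed for every edge. Coexpression values are taken from
    ``coexpr`` (keys in either endpoint order); edges absent from the map get
    ``missing_coexpr`` (default 0, so they contribute no coexpression bias
    while their ECC term still counts).
    """
    weights = EdgeWeights()
    lookup: dict[tuple[str, str], float] = {}
    if coexpr:
        for (u, v), value in coexpr.items():
            lookup[edge_key(u, v)] = value
    n_missing = 0
    for u, v in net.edges():
        key = edge_key(u, v)
        weights.ecc[key] = edge_clustering_coefficient(net, (u, v), denominator)
        if key in lookup:
            weights.coexpr[key] = lookup[key]
        else:
            weights.coexpr[key] = missing_coexpr
            n_missing += 1
    if coexpr is not None and n_missing:
        log.info("%d/%d edges lacked a coexpression value; default %.3g used",
                 n_missing, net.number_of_edges(), missing_coexpr)
    return weights


def write_edge_list(net: nx.Graph, weights: EdgeWeights, path) -> None:
    """Export edges with their ECC and coexpression weights as TSV."""
    with open(path, "w") as handle:
        handle.write("node_a\tnode_b\tecc\tcoexpr\n")
        for u, v in sorted(edge_key(a, b) for a, b in net.edges()):
            key = (u, v)
            handle.write(f"{u}\t{v}\t{weights.ecc[key]:.15g}\t{weights.coexpr[key]:.15g}\n")
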