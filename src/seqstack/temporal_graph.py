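"""Layered temporal networks over a fixed node universe.

A temporal network is an ordered sequence of simple undirected graphs
``G = {G_0, ..., G_L}`` that all share the same node set ``{0, ..., n-1}``.
Nodes never arrive or depart: a node with no incident edges in a layer is
simply isolated in that layer.  Layers are unweighted; duplicate edge
records collapse to a single edge.

The on-disk format is a 3-column integer edge list (``layer  u  v``),
whitespace- or tab-delimited, with ``#`` comments.  Timestamps must already
be binned into contiguous layer indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "TemporalNetwork",
    "read_temporal_edgelist",
    "write_temporal_edgelist",
    "intersection_graph",
]


@dataclass
class TemporalNetwork:
    """An ordered sequence of simple undirected graphs on nodes ``0..n-1``.

    Parameters
    ----------
    n
        Size of the node universe shared by every layer.
    layers
        One :class:`networkx.Graph` per time step, index 0 first.
    """

    n: int
    layers: list[nx.Graph] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"node count must be positive, got {self.n}")
        for t, g in enumerate(self.layers):
            self.layers[t] = _canonicalize_layer(g, self.n, t)

    @property
    def layer_count(self) -> int:
        """Number of layers, L + 1."""
        return len(self.layers)

    @property
    def L(self) -> int:
        """Index of the last layer."""
        return len(self.layers) - 1

    def layer(self, t: int) -> nx.Graph:
        if not 0 <= t < self.layer_count:
            raise IndexError(f"layer {t} out of range 0..{self.L}")
        return self.layers[t]

    def edge_sets(self) -> list[set[tuple[int, int]]]:
        """Edge set of each layer with endpoints ordered ``u < v``."""
        return [
            {(min(u, v), max(u, v)) for u, v in g.edges()} for g in self.layers
        ]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TemporalNetwork):
            return NotImplemented
        return self.n == other.n and self.edge_sets() == other.edge_sets()


def _canonicalize_layer(g: nx.Graph, n: int, t: int) -> nx.Graph:
    """Return a simple undirected copy of ``g`` over the full node universe."""
    clean = nx.Graph()
    clean.add_nodes_from(range(n))
    for u, v in g.edges():
        if u == v:
            logger.warning("dropping self-loop (%d,%d) in layer %d", u, v, t)
            continue
        if not (0 <= u < n and 0 <= v < n):
            raise ValueError(
                f"edge ({u},{v}) in layer {t} outside node universe 0..{n - 1}"
            )
        clean.add_edge(u, v)
    return clean


class EdgelistParseError(ValueError):
    """Raised for records that cannot be parsed as ``layer u v`` integers."""


def read_temporal_edgelist(
    source: IO[str] | str | Iterable[str], n: int | None = None
) -> TemporalNetwork:
    """Read a layered edge list into a :class:`TemporalNetwork`.

    Parameters
    ----------
    source
        Path, open text stream, or iterable of lines.  Each non-comment,
        non-blank line holds at least three whitespace-separated
        non-negative integers ``layer u v``; extra fields are ignored.
    n
        Node-universe size.  Defaults to ``1 + max(node id)``.

    Notes
    -----
    Layer indices need not be sorted; missing intermediate indices produce
    empty layers.  Self-loop records are dropped with a warning; duplicate
    records (in either orientation) collapse to one edge.
    """
    if isinstance(source, str):
        with open(source, "r", encoding="utf-8") as fh:
            return read_temporal_edgelist(fh, n=n)

    records: list[tuple[int, int, int]] = []
    max_node = -1
    max_layer = -1
    for lineno, raw in enumerate(source, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise EdgelistParseError(
                f"line {lineno}: expected 3 fields 'layer u v', got {len(fields)}"
            )
        try:
            t, u, v = (int(fields[0]), int(fields[1]), int(fields[2]))
        except ValueError as exc:
            raise EdgelistParseError(
                f"line {lineno}: non-integer field in {fields[:3]!r}"
            ) from exc
        if t < 0 or u < 0 or v < 0:
            raise ValueError(f"line {lineno}: negative layer or node id")
        records.append((t, u, v))
        max_node = max(max_node, u, v)
        max_layer = max(max_layer, t)

    if n is None:
        if max_node < 0:
            raise ValueError("empty edge list and no node count given")
        n = max_node + 1
    elif max_node >= n:
        raise ValueError(f"node id {max_node} exceeds declared universe n={n}")

    n_layers = max(max_layer + 1, 1)
    graphs = [nx.Graph() for _ in range(n_layers)]
    for t, u, v in records:
        graphs[t].add_edge(u, v) if u != v else graphs[t].add_node(u)
        if u == v:
            logger.warning("dropping self-loop record (%d,%d,%d)", t, u, v)
    return TemporalNetwork(n=n, layers=graphs)


def write_temporal_edgelist(net: TemporalNetwork, sink: IO[str] | str) -> int:
    """Write ``net`` as a sorted ``layer u v`` TSV; returns the record count.

    Records are sorted by (layer, u, v) with ``u < v`` so that output is
    byte-stable, and ``read(write(net)) == net``.
    """
    if isinstance(sink, str):
        with open(sink, "w", encoding="utf-8") as fh:
            return write_temporal_edgelist(net, fh)

    count = 0
    for t, edges in enumerate(net.edge_sets()):
        for u, v in sorted(edges):
            sink.write(f"{t}\t{u}\t{v}\n")
            count += 1
    return count


def intersection_graph(net: TemporalNetwork, t_start: int, q: int) -> nx.Graph:
    """AND-aggregate ``q`` consecutive layers starting at ``t_start``.

    The result contains edge (i, j) iff (i, j) is present in every layer
    ``t_start .. t_start + q - 1``.  This is the aggregation underlying the
    temporal common-neighbors baseline: persistent neighbors are exactly
    the neighbors in the intersection graph.
    """
    if q < 1:
        raise ValueError(f"window length q must be >= 1, got {q}")
    if t_start < 0 or t_start + q > net.layer_count:
        raise IndexError(
            f"window [{t_start}, {t_start + q}) out of range for "
            f"{net.layer_count} layers"
        )
    sets = net.edge_sets()[t_start : t_start + q]
    common = set.intersection(*sets)
    g = nx.Graph()
    g.add_nodes_from(range(net.n))
    g.add_edges_from(common)
    return g
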