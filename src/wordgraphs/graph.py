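"""Directed word multigraphs and their four attributes.

Each unique word of a token sequence is a node; each consecutive word pair
contributes one directed edge instance (identical pairs accumulate
multiplicity, immediate repetitions become self-loops). Four attributes
summarise a graph:

* ``N``  — node count, lexical diversity;
* ``RE`` — repeated edges, short-range recurrence: the sum of edge instances
  over ordered node pairs connected more than once;
* ``LSC`` — node count of the largest strongly connected component,
  long-range recurrence ("speech connectedness");
* ``ASP`` — average shortest directed path over reachable ordered pairs,
  a measure of graph size.

LSC and ASP depend on topology only; RE uses multiplicities.
"""

from __future__ import annotations

import warnings
from collections import Counter, deque
from dataclasses import dataclass, field
from typing import Iterator, Literal, NamedTuple, Sequence

import networkx as nx

__all__ = [
    "WordGraph",
    "GraphAttributes",
    "build_graph",
    "attr_N",
    "attr_RE",
    "attr_LSC",
    "attr_ASP",
    "attributes",
]

ReMode = Literal["sum", "excess"]
AspMode = Literal["directed", "undirected"]


class GraphAttributes(NamedTuple):
    """The attribute quadruple of one word graph."""

    N: int
    RE: int
    LSC: int
    ASP: float


@dataclass(frozen=True)
class WordGraph:
    """A directed multigraph over unique words.

    ``edges`` maps ordered (source, target) pairs to multiplicity >= 1; the
    sum of multiplicities equals ``token_length - 1``. Self-loops permitted.
    """

    nodes: frozenset[str]
    edges: dict[tuple[str, str], int]
    token_length: int
    # successor sets, multiplicity-free; derived once, reused by LSC/ASP
    _adj: dict[str, set[str]] = field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self._adj is None:
            adj: dict[str, set[str]] = {n: set() for n in self.nodes}
            for (u, v) in self.edges:
                adj[u].add(v)
            object.__setattr__(self, "_adj", adj)

    @property
    def total_multiplicity(self) -> int:
        return sum(self.edges.values())

    def successors(self, node: str) -> set[str]:
        return self._adj[node]

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for (u, v), m in self.edges.items():
            for _ in range(m):
                g.add_edge(u, v)
        return g

    def to_dot(self) -> str:
        """Minimal DOT serialization for visual inspection."""
        lines = ["digraph wordgraph {"]
        for n in sorted(self.nodes):
            lines.append(f'  "{n}";')
        for (u, v), m in sorted(self.edges.items()):
            label = f' [label="{m}"]' if m > 1 else ""
            lines.append(f'  "{u}" -> "{v}"{label};')
        lines.append("}")
        return "\n".join(lines)

    def write_graphml(self, path) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (u, v), m in self.edges.items():
            g.add_edge(u, v, multiplicity=m)
        nx.write_graphml(g, path)


def build_graph(tokens: Sequence[str]) -> WordGraph:
    """Build the word graph of a token sequence.

    Every consecutive pair (w_i, w_{i+1}) becomes one directed edge instance
    with direction preserved; a single token yields one node and no edges.
    """
    if not tokens:
        raise ValueError("cannot build a word graph from an empty sequence")
    edges = Counter(zip(tokens, tokens[1:]))
    return WordGraph(
        nodes=frozenset(tokens),
        edges=dict(edges),
        token_length=len(tokens),
    )


def attr_N(graph: WordGraph) -> int:
    """Lexical diversity: number of distinct words (nodes)."""
    return len(graph.nodes)


def attr_RE(graph: WordGraph, mode: ReMode = "sum") -> int:
    """Short-range recurrence: repeated edges.

    ``mode="sum"`` (default) counts every edge instance on ordered node
    pairs connected more than once (a pair of multiplicity m >= 2
    contributes m); this reading attains 29 for a 30-token window of one
    repeated word. ``mode="excess"`` counts only the surplus instances
    (m - 1 per pair), capping at 28 for such a window.
    """
    if mode == "sum":
        return sum(m for m in graph.edges.values() if m >= 2)
    if mode == "excess":
        return sum(m - 1 for m in graph.edges.values())
    raise ValueError(f"unknown RE mode: {mode!r}")


def attr_LSC(graph: WordGraph) -> int:
    """Long-range recurrence: size of the largest strongly connected component.

    Multiplicities are irrelevant; an isolated node is an SCC of size 1, so
    the result is always >= 1.
    """
    g = nx.DiGraph(graph._adj)
    return max(len(c) for c in nx.strongly_connected_components(g))


def _bfs_lengths(adj: dict[str, set[str]], source: str) -> Iterator[int]:
    """Yield shortest path lengths from source to every other reachable node."""
    dist = {source: 0}
    q = deque((source,))
    while q:
        u = q.popleft()
        du = dist[u]
        for v in adj[u]:
            if v not in dist:
                dist[v] = du + 1
                q.append(v)
    for node, d in dist.items():
        if node != source:
            yield d


def attr_ASP(graph: WordGraph, mode: AspMode = "directed") -> float:
    """Graph size: average shortest path length in edge steps.

    The mean runs over ordered node pairs (u, v), u != v, for which a
    directed path exists; unreachable pairs are excluded. Word graphs are
    often not strongly connected, so this keeps ASP finite. With
    ``mode="undirected"`` edge direction is ignored first. A graph with no
    reachable ordered pair (single node, or no edges) has ASP 0 by
    convention, with a warning when nodes > 1.
    """
    adj = graph._adj
    if mode == "undirected":
        und: dict[str, set[str]] = {n: set() for n in graph.nodes}
        for (u, v) in graph.edges:
            if u != v:
                und[u].add(v)
                und[v].add(u)
        adj = und
    elif mode != "directed":
        raise ValueError(f"unknown ASP mode: {mode!r}")

    total = 0
    count = 0
    for source in adj:
        for d in _bfs_lengths(adj, source):
            total += d
            count += 1
    if count == 0:
        if len(graph.nodes) > 1:
            warnings.warn("no reachable ordered pair; ASP defined as 0",
                          stacklevel=2)
        return 0.0
    return total / count


def attributes(
    graph: WordGraph,
    re_mode: ReMode = "sum",
    asp_mode: AspMode = "directed",
) -> GraphAttributes:
    """Compute the (N, RE, LSC, ASP) quadruple of one graph."""
    return GraphAttributes(
        N=attr_N(graph),
        RE=attr_RE(graph, mode=re_mode),
        LSC=attr_LSC(graph),
        ASP=attr_ASP(graph, mode=asp_mode),
    )
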