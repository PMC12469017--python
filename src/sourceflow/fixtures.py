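"""Reference networks and seeded synthetic-graph generators.

The two worked networks used throughout the tests and examples:

* ``path3`` — the 3-node path 0–1–2 with unit infection rates, the
  smallest network on which the classical first-k ML and JML source
  estimators are provably degenerate;
* the butterfly network on nodes 1..6 (arcs 1→3, 2→3, 1→5, 2→6, 3→4,
  4→5, 4→6, unit capacity), the canonical example where network coding
  from sources {1, 2} achieves multicast rate 2 to sinks {5, 6}; its
  undirected version admits rate 2 by routing from the single source {3}.

Synthetic generators (Barabási–Albert, Watts–Strogatz, Erdős–Rényi) are
seeded, cleaned for connectivity, and oriented from lower- to
higher-indexed nodes with unit capacities.
"""

from __future__ import annotations

import networkx as nx

from .linking import DirectedGraphLinking, UndirectedGraphLinking
from .si import GraphRateModel

__all__ = [
    "BUTTERFLY_EDGES",
    "path3",
    "butterfly_directed",
    "butterfly_undirected",
    "path_graph",
    "ba_graph",
    "ws_graph",
    "er_graph",
    "build_fixture",
]

BUTTERFLY_EDGES = ((1, 3), (2, 3), (1, 5), (2, 6), (3, 4), (4, 5), (4, 6))


def path3(rate: float = 1.0) -> GraphRateModel:
    """Undirected 3-node path 0–1–2 with per-edge infection rate."""
    return GraphRateModel.from_edges([(0, 1, rate), (1, 2, rate)], directed=False)


def butterfly_directed(capacity: float = 1.0) -> DirectedGraphLinking:
    return DirectedGraphLinking.from_edges(
        [(u, w, capacity) for u, w in BUTTERFLY_EDGES], nodes=range(1, 7)
    )


def butterfly_undirected(capacity: float = 1.0) -> UndirectedGraphLinking:
    return UndirectedGraphLinking.from_edges(
        [(u, w, capacity) for u, w in BUTTERFLY_EDGES], nodes=range(1, 7)
    )


def _orient_low_high(G: nx.Graph, capacity: float) -> DirectedGraphLinking:
    edges = [(min(u, v), max(u, v), capacity) for u, v in G.edges()]
    return DirectedGraphLinking.from_edges(edges, nodes=sorted(G.nodes()))


def path_graph(n: int, capacity: float = 1.0, directed: bool = True):
    G = nx.path_graph(n)
    if directed:
        return _orient_low_high(G, capacity)
    return UndirectedGraphLinking.from_edges(
        [(u, v, capacity) for u, v in G.edges()], nodes=range(n)
    )


def ba_graph(n: int, m: int = 2, seed: int = 0, capacity: float = 1.0):
    """Barabási–Albert preferential attachment, oriented low→high index.

    BA graphs are connected by construction.
    """
    G = nx.barabasi_albert_graph(n, m, seed=seed)
    return _orient_low_high(G, capacity)


def ws_graph(n: int, k: int = 4, p: float = 0.1, seed: int = 0, capacity: float = 1.0):
    """Connected Watts–Strogatz small world, oriented low→high index."""
    G = nx.connected_watts_strogatz_graph(n, k, p, seed=seed)
    return _orient_low_high(G, capacity)


def er_graph(n: int, p: float = 0.2, seed: int = 0, capacity: float = 1.0):
    """Erdős–Rényi G(n, p), resampled (seed incremented) until connected."""
    for attempt in range(1000):
        G = nx.erdos_renyi_graph(n, p, seed=seed + attempt)
        if nx.is_connected(G):
            return _orient_low_high(G, capacity)
    raise RuntimeError(f"could not draw a connected G({n}, {p}) in 1000 attempts")


_GENERATORS = {
    "path3": path3,
    "butterfly_directed": butterfly_directed,
    "butterfly_undirected": butterfly_undirected,
    "path": path_graph,
    "ba": ba_graph,
    "ws": ws_graph,
    "er": er_graph,
}


def build_fixture(name: str, **params):
    """Build a named fixture; unknown names raise with the valid choices."""
    try:
        gen = _GENERATORS[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {sorted(_GENERATORS)}"
        ) from None
    return gen(**params)
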