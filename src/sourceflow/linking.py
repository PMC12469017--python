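"""Network link models: linking functions, cut functions, contraction.

A *linking function* ``lambda(B, C)`` measures the capacity from a node
set ``B`` to a node set ``C``.  It is normalized (zero when either
argument is empty), monotone in both arguments, and bisubmodular — the
two-argument generalization of submodularity.  The weighted-digraph
specialization is modular: ``lambda(B, C) = sum of arc capacities from B
to C``.  The induced *incut* function ``f(C) = lambda(V \\ C, C)`` is
normalized submodular, which is what makes min-cut / max-flow machinery
applicable.

Undirected networks are handled by per-edge orientation variables: each
edge capacity is assigned to (or, in the relaxed reading, split between)
its two directions, and capacities optimize over that choice (see
:mod:`sourceflow.capacity`).
"""

from __future__ import annotations

import itertools
import logging
from typing import Callable, Iterable, Mapping

import networkx as nx
import numpy as np

from .si import GroundSet, Node

logger = logging.getLogger(__name__)

__all__ = [
    "LinkingOracle",
    "CallableLinking",
    "TableLinking",
    "DirectedGraphLinking",
    "UndirectedGraphLinking",
    "cut_value",
    "incut",
    "check_monotone",
    "check_bisubmodular",
    "check_incut_submodular",
    "contract",
]


class LinkingOracle:
    """Abstract linking function on a ground set.

    Bisubmodularity is a checkable contract (:func:`check_bisubmodular`),
    not an enforced one — verifying it exactly is exponential.
    """

    ground: GroundSet

    def link(self, B: Iterable[Node], C: Iterable[Node]) -> float:
        raise NotImplementedError

    def cut(self, B: Iterable[Node]) -> float:
        """``lambda(B, V \\ B)`` — the out-cut of ``B``."""
        B = self.ground.validate(B)
        return self.link(B, self.ground.complement(B))


class CallableLinking(LinkingOracle):
    """Opaque linking oracle wrapping a user-supplied callable.

    This is the interface for non-graph linking functions (e.g. ones
    derived from channel entropies); only evaluation is supported.
    """

    def __init__(self, ground: GroundSet, fn: Callable[[frozenset, frozenset], float]):
        self.ground = ground
        self._fn = fn

    def link(self, B, C):
        B = self.ground.validate(B)
        C = self.ground.validate(C)
        if not B or not C:
            return 0.0
        return float(self._fn(B, C))


class TableLinking(LinkingOracle):
    """Explicit table on all ``(B, C)`` pairs — tiny ground sets only."""

    def __init__(self, ground: GroundSet, table: Mapping[tuple, float]):
        self.ground = ground
        self._table = {
            (ground.sort(ground.validate(B)), ground.sort(ground.validate(C))): float(v)
            for (B, C), v in table.items()
        }

    def link(self, B, C):
        B = self.ground.validate(B)
        C = self.ground.validate(C)
        if not B or not C:
            return 0.0
        key = (self.ground.sort(B), self.ground.sort(C))
        if key not in self._table:
            raise KeyError(f"no table entry for linking({set(B)}, {set(C)})")
        return self._table[key]


class DirectedGraphLinking(LinkingOracle):
    """Modular linking of a weighted digraph: sums of arc capacities.

    Self-loops contribute nothing to any cut and are dropped at
    construction with a logged warning; parallel arcs are summed.
    """

    def __init__(self, ground: GroundSet, arcs: Mapping[tuple[Node, Node], float]):
        self.ground = ground
        self.arcs: dict[tuple[Node, Node], float] = {}
        for (u, w), cap in arcs.items():
            if cap < 0:
                raise ValueError(f"negative capacity on arc {u!r}->{w!r}")
            if u == w:
                logger.warning("dropping self-loop at %r", u)
                continue
            ground.index(u), ground.index(w)
            if cap == 0:
                continue
            self.arcs[(u, w)] = self.arcs.get((u, w), 0.0) + float(cap)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[Node, Node, float]],
        nodes: Iterable[Node] | None = None,
    ) -> "DirectedGraphLinking":
        edges = list(edges)
        if nodes is None:
            seen: dict[Node, None] = {}
            for u, v, _ in edges:
                seen.setdefault(u)
                seen.setdefault(v)
            nodes = sorted(seen, key=lambda u: (u.__class__.__name__, u))
        arcs: dict[tuple[Node, Node], float] = {}
        for u, v, c in edges:
            arcs[(u, v)] = arcs.get((u, v), 0.0) + c
        return cls(GroundSet(nodes), arcs)

    def link(self, B, C):
        B = self.ground.validate(B)
        C = self.ground.validate(C)
        return sum(cap for (u, w), cap in self.arcs.items() if u in B and w in C)

    def cut(self, B):
        B = self.ground.validate(B)
        return sum(cap for (u, w), cap in self.arcs.items() if u in B and w not in B)

    def to_networkx(self) -> nx.DiGraph:
        G = nx.DiGraph()
        G.add_nodes_from(self.ground)
        for (u, w), cap in self.arcs.items():
            G.add_edge(u, w, capacity=cap)
        return G


class UndirectedGraphLinking:
    """Weighted undirected graph whose edges may be oriented fractionally.

    Each edge ``{u, w}`` of capacity ``c`` can be split into nonnegative
    directed parts ``c_uw + c_wu = c``; the directed cut induced by a
    feasible split is what the undirected capacities optimize over.
    """

    def __init__(self, ground: GroundSet, edges: Mapping[frozenset, float]):
        self.ground = ground
        self.edges: dict[frozenset, float] = {}
        for e, cap in edges.items():
            e = frozenset(e)
            if cap < 0:
                raise ValueError(f"negative capacity on edge {set(e)}")
            if len(e) != 2:
                logger.warning("dropping self-loop/degenerate edge %s", set(e))
                continue
            for u in e:
                ground.index(u)
            if cap == 0:
                continue
            self.edges[e] = self.edges.get(e, 0.0) + float(cap)

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[Node, Node, float]],
        nodes: Iterable[Node] | None = None,
    ) -> "UndirectedGraphLinking":
        edges = list(edges)
        if nodes is None:
            seen: dict[Node, None] = {}
            for u, v, _ in edges:
                seen.setdefault(u)
                seen.setdefault(v)
            nodes = sorted(seen, key=lambda u: (u.__class__.__name__, u))
        acc: dict[frozenset, float] = {}
        for u, v, c in edges:
            e = frozenset((u, v))
            acc[e] = acc.get(e, 0.0) + c
        return cls(GroundSet(nodes), acc)

    def oriented_arcs(self) -> list[tuple[Node, Node]]:
        """Both orientations of every edge, in deterministic ground order."""
        arcs = []
        for e in sorted(self.edges, key=lambda e: self.ground.sort(e)):
            u, w = self.ground.sort(e)
            arcs.append((u, w))
            arcs.append((w, u))
        return arcs

    def crossing_capacity(self, B: Iterable[Node]) -> float:
        """Total capacity of edges with exactly one endpoint in ``B``."""
        B = self.ground.validate(B)
        return sum(cap for e, cap in self.edges.items() if len(e & B) == 1)

    def orient(self, splits: Mapping[tuple[Node, Node], float]) -> DirectedGraphLinking:
        """Directed model induced by a feasible capacity split."""
        for e, cap in self.edges.items():
            u, w = self.ground.sort(e)
            tot = splits.get((u, w), 0.0) + splits.get((w, u), 0.0)
            if abs(tot - cap) > 1e-6:
                raise ValueError(f"split does not conserve capacity on edge {set(e)}")
        return DirectedGraphLinking(self.ground, dict(splits))


def cut_value(model: LinkingOracle, B: Iterable[Node]) -> float:
    """Out-cut ``lambda(B, V \\ B)``; zero for the empty set and for V."""
    return model.cut(B)


def incut(model: LinkingOracle, C: Iterable[Node]) -> float:
    """Incut ``f(C) = lambda(V \\ C, C)`` — normalized submodular."""
    C = model.ground.validate(C)
    return model.link(model.ground.complement(C), C)


def _random_subset(nodes, rng) -> frozenset:
    mask = rng.random(len(nodes)) < 0.5
    return frozenset(u for u, m in zip(nodes, mask) if m)


def check_monotone(
    model: LinkingOracle, *, exhaustive_limit: int = 4, n_samples: int = 2000, seed: int = 0
) -> list[str]:
    """Check normalization and monotonicity of ``lambda`` in both arguments.

    Exhaustive over all nested pairs for tiny ground sets (9^|V| queries),
    sampled otherwise.
    """
    ground = model.ground
    nodes = list(ground)
    violations: list[str] = []
    if model.link(frozenset(), frozenset(nodes)) != 0:
        violations.append("lambda(emptyset, V) != 0")
    if model.link(frozenset(nodes), frozenset()) != 0:
        violations.append("lambda(V, emptyset) != 0")

    def _pair(Bs, B, Cs, C):
        if model.link(Bs, Cs) > model.link(B, C) + 1e-12:
            violations.append(
                f"monotonicity: lambda({set(Bs)}, {set(Cs)}) > lambda({set(B)}, {set(C)})"
            )

    if len(nodes) <= exhaustive_limit:
        subsets = [frozenset(c) for k in range(len(nodes) + 1)
                   for c in itertools.combinations(nodes, k)]
        for B in subsets:
            for Bs in map(frozenset, itertools.chain.from_iterable(
                    itertools.combinations(sorted(B, key=ground.index), k)
                    for k in range(len(B) + 1))):
                for C in subsets:
                    for Cs in map(frozenset, itertools.chain.from_iterable(
                            itertools.combinations(sorted(C, key=ground.index), k)
                            for k in range(len(C) + 1))):
                        _pair(Bs, B, Cs, C)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_samples):
            B = _random_subset(nodes, rng)
            C = _random_subset(nodes, rng)
            Bs = _random_subset(sorted(B, key=ground.index), rng)
            Cs = _random_subset(sorted(C, key=ground.index), rng)
            _pair(Bs, B, Cs, C)
    return violations


def check_bisubmodular(
    model: LinkingOracle, *, exhaustive_limit: int = 3, n_samples: int = 10000, seed: int = 0
) -> list[str]:
    """Check the bisubmodular inequality
    ``lambda(B1,C1) + lambda(B2,C2) >= lambda(B1&B2, C1|C2) + lambda(B1|B2, C1&C2)``.

    Exhaustive over all quadruples only for very small ground sets
    (16^|V| cases), otherwise a seeded random sample.
    """
    ground = model.ground
    nodes = list(ground)
    violations: list[str] = []

    def _quad(B1, C1, B2, C2):
        lhs = model.link(B1, C1) + model.link(B2, C2)
        rhs = model.link(B1 & B2, C1 | C2) + model.link(B1 | B2, C1 & C2)
        if lhs < rhs - 1e-9:
            violations.append(
                f"bisubmodularity violated at B1={set(B1)}, C1={set(C1)}, "
                f"B2={set(B2)}, C2={set(C2)}: {lhs} < {rhs}"
            )

    if len(nodes) <= exhaustive_limit:
        subsets = [frozenset(c) for k in range(len(nodes) + 1)
                   for c in itertools.combinations(nodes, k)]
        for B1 in subsets:
            for C1 in subsets:
                for B2 in subsets:
                    for C2 in subsets:
                        _quad(B1, C1, B2, C2)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_samples):
            _quad(*(_random_subset(nodes, rng) for _ in range(4)))
    return violations


def check_incut_submodular(
    model: LinkingOracle, *, exhaustive_limit: int = 8, n_samples: int = 5000, seed: int = 0
) -> list[str]:
    """Check ``f(C1) + f(C2) >= f(C1&C2) + f(C1|C2)`` for the incut ``f``."""
    ground = model.ground
    nodes = list(ground)
    violations: list[str] = []

    def _pair(C1, C2):
        lhs = incut(model, C1) + incut(model, C2)
        rhs = incut(model, C1 & C2) + incut(model, C1 | C2)
        if lhs < rhs - 1e-9:
            violations.append(
                f"incut submodularity violated at C1={set(C1)}, C2={set(C2)}"
            )

    if len(nodes) <= exhaustive_limit:
        subsets = [frozenset(c) for k in range(len(nodes) + 1)
                   for c in itertools.combinations(nodes, k)]
        for C1 in subsets:
            for C2 in subsets:
                _pair(C1, C2)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_samples):
            _pair(_random_subset(nodes, rng), _random_subset(nodes, rng))
    return violations


def supernode_label(ground: GroundSet, S: Iterable[Node]) -> str:
    """Canonical label for a contracted node set."""
    return "S:" + ",".join(str(u) for u in ground.sort(ground.validate(S)))


def contract(
    model: DirectedGraphLinking, S: Iterable[Node]
) -> tuple[DirectedGraphLinking, dict[Node, Node]]:
    """Merge ``S`` into one supernode, summing parallel arcs and dropping
    internal ones.  Cut values of sets respecting the merge are preserved
    exactly.  Returns the contracted model and the old-to-new label map.
    """
    S = model.ground.validate(S)
    if not S:
        raise ValueError("cannot contract an empty set")
    label = supernode_label(model.ground, S)
    label_map: dict[Node, Node] = {
        u: (label if u in S else u) for u in model.ground
    }
    first = next(u for u in model.ground if u in S)
    new_nodes = [label_map[u] for u in model.ground
                 if u not in S or u == first]
    arcs: dict[tuple[Node, Node], float] = {}
    for (u, w), cap in model.arcs.items():
        nu, nw = label_map[u], label_map[w]
        if nu == nw:
            continue
        arcs[(nu, nw)] = arcs.get((nu, nw), 0.0) + cap
    return DirectedGraphLinking(GroundSet(new_nodes), arcs), label_map
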