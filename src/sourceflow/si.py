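"""Generalized susceptible–infectious (SI) contagion model.

The state of the epidemic is the set ``B`` of currently infected nodes.
Each susceptible node ``u`` is infected after an exponential waiting time
with a set-dependent hazard ``lambda_u(B)``; hazards are normalized
(``lambda_u(emptyset) = 0``) and non-decreasing in ``B``.  The classical
per-edge-clock SI process on a weighted graph is the special case where
``lambda_u(B)`` is the sum of the rates of edges joining ``B`` to ``u``
(:class:`GraphRateModel`); arbitrary monotone hazards on small ground sets
are supported through :class:`TableRateModel`.

Because all waiting times are exponential, the process is a continuous-time
Markov chain on infected sets, and forward simulation is the standard
Gillespie scheme: draw a holding time ``Exp(Lambda(B))`` with
``Lambda(B) = sum_{v not in B} lambda_v(B)``, then pick the next infected
node ``w`` with probability ``lambda_w(B) / Lambda(B)``.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

Node = Hashable

__all__ = [
    "GroundSet",
    "InfectionRateModel",
    "GraphRateModel",
    "TableRateModel",
    "InfectionTrajectory",
    "total_hazard",
    "next_infection_distribution",
    "simulate",
    "check_rate_model",
]


class GroundSet:
    """A finite ordered node set; the order fixes all tie-breaking."""

    def __init__(self, nodes: Iterable[Node]):
        self.nodes: tuple[Node, ...] = tuple(nodes)
        self._index = {u: i for i, u in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise ValueError("node labels must be unique")

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(self.nodes)

    def __contains__(self, u: Node) -> bool:
        return u in self._index

    def __eq__(self, other) -> bool:
        return isinstance(other, GroundSet) and self.nodes == other.nodes

    def __repr__(self) -> str:
        return f"GroundSet({list(self.nodes)!r})"

    def index(self, u: Node) -> int:
        try:
            return self._index[u]
        except KeyError:
            raise KeyError(f"unknown node label {u!r}") from None

    def sort(self, B: Iterable[Node]) -> tuple[Node, ...]:
        """Return ``B`` as a tuple sorted by the ground order."""
        return tuple(sorted(B, key=self.index))

    def validate(self, B: Iterable[Node]) -> frozenset:
        B = frozenset(B)
        for u in B:
            if u not in self._index:
                raise KeyError(f"unknown node label {u!r}")
        return B

    def complement(self, B: Iterable[Node]) -> tuple[Node, ...]:
        B = frozenset(B)
        return tuple(u for u in self.nodes if u not in B)

    def subsets(self):
        """All subsets in (size, ground-order-lexicographic) order."""
        for k in range(len(self.nodes) + 1):
            for combo in itertools.combinations(self.nodes, k):
                yield frozenset(combo)


class InfectionRateModel:
    """Base class: a ground set plus a hazard map ``(u, B) -> rate``."""

    ground: GroundSet

    def hazard(self, u: Node, B: Iterable[Node]) -> float:
        """Infection rate of susceptible ``u`` given infected set ``B``.

        Raises if ``u`` is in ``B`` — the hazard of an already infected
        node is never meaningful and querying it is a caller bug.
        """
        raise NotImplementedError

    def _check_query(self, u: Node, B: frozenset) -> None:
        if u not in self.ground:
            raise KeyError(f"unknown node label {u!r}")
        if u in B:
            raise ValueError(f"hazard of {u!r} queried with {u!r} already infected")


class GraphRateModel(InfectionRateModel):
    """Per-edge exponential clocks: ``lambda_u(B) = sum_{w in B, {w,u} edge} rate_wu``.

    Stored internally as directed arcs; an undirected edge contributes one
    arc in each direction.  Zero-rate arcs are pruned.
    """

    def __init__(self, ground: GroundSet, arcs: Mapping[tuple[Node, Node], float]):
        self.ground = ground
        self._in: dict[Node, list[tuple[Node, float]]] = {u: [] for u in ground}
        self.arcs: dict[tuple[Node, Node], float] = {}
        for (w, u), rate in arcs.items():
            if rate < 0:
                raise ValueError(f"negative rate on arc {w!r}->{u!r}")
            if w == u or rate == 0:
                continue
            ground.index(w), ground.index(u)
            self.arcs[(w, u)] = self.arcs.get((w, u), 0.0) + float(rate)
        for (w, u), rate in self.arcs.items():
            self._in[u].append((w, rate))

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[Node, Node, float]],
        directed: bool = False,
        nodes: Iterable[Node] | None = None,
    ) -> "GraphRateModel":
        edges = list(edges)
        if nodes is None:
            seen: dict[Node, None] = {}
            for u, v, _ in edges:
                seen.setdefault(u)
                seen.setdefault(v)
            nodes = sorted(seen, key=lambda u: (u.__class__.__name__, u))
        ground = GroundSet(nodes)
        arcs: dict[tuple[Node, Node], float] = {}
        for u, v, r in edges:
            arcs[(u, v)] = arcs.get((u, v), 0.0) + r
            if not directed:
                arcs[(v, u)] = arcs.get((v, u), 0.0) + r
        return cls(ground, arcs)

    def hazard(self, u: Node, B: Iterable[Node]) -> float:
        B = frozenset(B)
        self._check_query(u, B)
        return sum(rate for w, rate in self._in[u] if w in B)


class TableRateModel(InfectionRateModel):
    """Explicit hazard table on all ``(u, B)`` pairs (small ground sets).

    Keys are stored canonically as ``(u, sorted label tuple)``.  A missing
    entry is an error, never an implicit zero.
    """

    def __init__(self, ground: GroundSet, table: Mapping[tuple[Node, Iterable[Node]], float]):
        self.ground = ground
        self._table: dict[tuple[Node, tuple[Node, ...]], float] = {}
        for (u, B), rate in table.items():
            if rate < 0:
                raise ValueError(f"negative hazard for ({u!r}, {B!r})")
            self._table[(u, ground.sort(ground.validate(B)))] = float(rate)

    @classmethod
    def from_function(cls, ground: GroundSet, fn) -> "TableRateModel":
        """Tabulate ``fn(u, B)`` over every u and every B not containing u."""
        table = {}
        for B in ground.subsets():
            for u in ground:
                if u not in B:
                    table[(u, tuple(ground.sort(B)))] = fn(u, B)
        return cls(ground, table)

    def hazard(self, u: Node, B: Iterable[Node]) -> float:
        B = self.ground.validate(B)
        self._check_query(u, B)
        key = (u, self.ground.sort(B))
        if key not in self._table:
            raise KeyError(f"no table entry for hazard({u!r}, {set(B) or '{}'!r})")
        return self._table[key]


@dataclasses.dataclass(frozen=True)
class InfectionTrajectory:
    """An ordered record of one simulated outbreak."""

    source: frozenset
    sequence: tuple[Node, ...]  # newly infected nodes, in order
    times: tuple[float, ...]  # matching infection timestamps
    absorbed: bool  # no susceptible node had positive hazard at the end

    @property
    def infected(self) -> frozenset:
        return self.source | frozenset(self.sequence)

    def to_dict(self) -> dict:
        return {
            "source": sorted(map(str, self.source)),
            "events": [
                {"node": str(u), "time": t} for u, t in zip(self.sequence, self.times)
            ],
            "absorbed": self.absorbed,
        }


def total_hazard(model: InfectionRateModel, B: Iterable[Node]) -> float:
    """Total outflow rate ``Lambda(B) = sum_{v not in B} lambda_v(B)``."""
    B = model.ground.validate(B)
    return sum(model.hazard(v, B) for v in model.ground if v not in B)


def next_infection_distribution(
    model: InfectionRateModel, B: Iterable[Node]
) -> dict[Node, float]:
    """Law of the next infected node: competing exponentials.

    Node ``w`` is next with probability ``lambda_w(B) / Lambda(B)``.
    """
    B = model.ground.validate(B)
    hazards = {v: model.hazard(v, B) for v in model.ground if v not in B}
    lam = sum(hazards.values())
    if lam <= 0:
        raise ValueError("absorbing set — no further infection possible")
    return {v: h / lam for v, h in hazards.items()}


def simulate(
    model: InfectionRateModel,
    W: Iterable[Node],
    *,
    k_max: int | None = None,
    t_max: float | None = None,
    seed: int | np.random.Generator,
) -> InfectionTrajectory:
    """Gillespie simulation of the SI process started from source set ``W``.

    Stops after ``k_max`` new infections, past time ``t_max``, or at
    absorption (no susceptible node has positive hazard).  Exponential
    waiting times make the embedded jump chain exactly
    :func:`next_infection_distribution`, so ties never need breaking.
    """
    if k_max is None and t_max is None:
        raise ValueError("supply k_max and/or t_max")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    B = set(model.ground.validate(W))
    if not B:
        raise ValueError("source set must be nonempty")
    sequence: list[Node] = []
    times: list[float] = []
    t = 0.0
    while True:
        if k_max is not None and len(sequence) >= k_max:
            return InfectionTrajectory(frozenset(W), tuple(sequence), tuple(times), False)
        sus = [v for v in model.ground if v not in B]
        hazards = np.array([model.hazard(v, B) for v in sus])
        lam = hazards.sum()
        if not sus or lam <= 0:
            return InfectionTrajectory(frozenset(W), tuple(sequence), tuple(times), True)
        t += rng.exponential(1.0 / lam)
        if t_max is not None and t > t_max:
            return InfectionTrajectory(frozenset(W), tuple(sequence), tuple(times), False)
        w = sus[rng.choice(len(sus), p=hazards / lam)]
        B.add(w)
        sequence.append(w)
        times.append(t)


def check_rate_model(
    model: InfectionRateModel,
    *,
    exhaustive_limit: int = 12,
    n_samples: int = 1000,
    seed: int = 0,
) -> list[str]:
    """Validity check: normalization ``lambda_u({}) = 0`` and monotonicity
    ``lambda_u(B') <= lambda_u(B)`` for ``B' subseteq B``.

    Exhaustive over all ``(u, B' subseteq B)`` pairs when the ground set has
    at most ``exhaustive_limit`` nodes, else a seeded random sample of
    nested pairs.  Returns a list of human-readable violation strings.
    """
    ground = model.ground
    violations: list[str] = []
    for u in ground:
        if model.hazard(u, frozenset()) != 0:
            violations.append(f"lambda_{u!r}(emptyset) != 0")

    def _check_pair(u, Bsmall, Bbig):
        if model.hazard(u, Bsmall) > model.hazard(u, Bbig) + 1e-12:
            violations.append(
                f"monotonicity: lambda_{u!r}({set(Bsmall) or '{}'}) > "
                f"lambda_{u!r}({set(Bbig)})"
            )

    if len(ground) <= exhaustive_limit:
        for u in ground:
            others = [v for v in ground if v != u]
            for Bbig in map(frozenset, _powerset(others)):
                for Bsmall in map(frozenset, _powerset(sorted(Bbig, key=ground.index))):
                    _check_pair(u, Bsmall, Bbig)
    else:
        rng = np.random.default_rng(seed)
        nodes = list(ground)
        for _ in range(n_samples):
            u = nodes[rng.integers(len(nodes))]
            others = [v for v in nodes if v != u]
            mask = rng.random(len(others)) < 0.5
            Bbig = frozenset(v for v, m in zip(others, mask) if m)
            sub = rng.random(len(Bbig)) < 0.5
            Bsmall = frozenset(v for v, m in zip(sorted(Bbig, key=ground.index), sub) if m)
            _check_pair(u, Bsmall, Bbig)
    return violations


def _powerset(items: Sequence) -> Iterable[tuple]:
    items = list(items)
    return itertools.chain.from_iterable(
        itertools.combinations(items, k) for k in range(len(items) + 1)
    )
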