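"""Rate-constrained and size-constrained source selection.

Given sinks ``A`` and a capacity oracle ``rho(S, A)`` (any of the
multicast variants), two problems are solved:

* *rate-constrained*: find an inclusion-minimal source set whose capacity
  meets a threshold ``r`` — backward elimination gives one such set with
  at most ``|V| + 1`` capacity evaluations; exhaustive enumeration gives
  all of them on small ground sets;
* *size-constrained*: maximize the capacity over source sets of size at
  most ``k`` — greedy forward search and its lazy (CELF-style) variant,
  with the classic ``1 - 1/e`` guarantee when the capacity is submodular
  in ``S`` (the colluding unicast variant is).

A candidate whose capacity is the infinite sentinel (a source set that
already contains sinks, making the colluding-cut query degenerate) is
evaluated but never selected; such queries certify nothing about spread.
"""

from __future__ import annotations

import dataclasses
import heapq
import itertools
import math
from typing import Callable, Iterable

from .capacity import KINDS, rho
from .si import Node

__all__ = [
    "SelectionResult",
    "CapacityOracle",
    "backward_elimination",
    "minimal_feasible_sources",
    "greedy_forward",
    "lazy_greedy",
    "brute_force_optimum",
]

_TOL = 1e-9


class CapacityOracle:
    """Counting wrapper around the capacity function ``S -> rho(S, A)``."""

    def __init__(self, model, A: Iterable[Node], kind: str = "ms",
                 orientation: str = "directed"):
        if kind not in KINDS:
            raise ValueError(f"unknown capacity kind {kind!r}")
        self.model = model
        self.ground = model.ground
        self.A = model.ground.validate(A)
        self.kind = kind
        self.orientation = orientation
        self.calls = 0

    def __call__(self, S: Iterable[Node]) -> float:
        self.calls += 1
        return self.peek(S)

    def peek(self, S: Iterable[Node]) -> float:
        """Evaluate without counting (used for final certification)."""
        return rho(self.model, S, self.A, self.kind, self.orientation).value


@dataclasses.dataclass(frozen=True)
class SelectionResult:
    selected: frozenset
    rate: float
    trace: tuple[dict, ...]
    oracle_calls: int
    algorithm: str

    def to_dict(self) -> dict:
        return {
            "selected": sorted(map(str, self.selected)),
            "rate": "inf" if math.isinf(self.rate) else self.rate,
            "oracle_calls": self.oracle_calls,
            "algorithm": self.algorithm,
            "trace": [
                {k: (sorted(map(str, v)) if isinstance(v, (set, frozenset)) else v)
                 for k, v in step.items()}
                for step in self.trace
            ],
        }


def _oracle(model, A, kind, orientation) -> CapacityOracle:
    return CapacityOracle(model, A, kind, orientation)


def backward_elimination(
    model,
    A: Iterable[Node],
    r: float,
    kind: str = "ms",
    orientation: str = "directed",
    *,
    tol: float = _TOL,
) -> SelectionResult | None:
    """Find one inclusion-minimal source set of capacity at least ``r``.

    Start from the full node set; scan nodes in ascending ground order and
    drop each node whose removal keeps the set feasible.  Returns ``None``
    iff even the full node set is infeasible.  Monotonicity of the
    capacity makes the surviving set inclusion-minimal.  The result can
    depend on the scan order; :func:`minimal_feasible_sources` is the
    order-free ground truth.
    """
    if r <= 0:
        raise ValueError("rate threshold must be positive")
    cap = _oracle(model, A, kind, orientation)
    V = list(model.ground)
    if cap(V) < r - tol:
        return None
    S = set(V)
    trace = []
    for u in V:
        trial = cap(S - {u})
        if trial >= r - tol:
            S.remove(u)
            trace.append({"removed": u, "rate": trial})
    selected = frozenset(S)
    return SelectionResult(selected, cap.peek(selected), tuple(trace),
                           cap.calls, "backward-elimination")


def minimal_feasible_sources(
    model,
    A: Iterable[Node],
    r: float,
    kind: str = "ms",
    orientation: str = "directed",
    *,
    tol: float = _TOL,
) -> list[frozenset]:
    """All inclusion-minimal source sets with capacity at least ``r``.

    Exhaustive over the subset lattice (guarded at 12 nodes); supersets of
    an already-found minimal set are pruned, which is sound because the
    capacity is monotone in the source set.  Output in lexicographic order
    of the sorted label tuples.
    """
    ground = model.ground
    if len(ground) > 12:
        raise ValueError("ground set too large for exhaustive enumeration (max 12)")
    cap = _oracle(model, A, kind, orientation)
    minimal: list[frozenset] = []
    for size in range(1, len(ground) + 1):
        for combo in itertools.combinations(ground.nodes, size):
            S = frozenset(combo)
            if any(m <= S for m in minimal):
                continue
            if cap(S) >= r - tol:
                minimal.append(S)
    return sorted(minimal, key=lambda S: ground.sort(S))


def _select_best(candidates: list[tuple[Node, float]]) -> tuple[Node, float] | None:
    """Strict argmax over (node, value); earlier (smaller-label) candidates
    win ties; infinite values are never selected."""
    best = None
    for w, val in candidates:
        if math.isinf(val):
            continue
        if best is None or val > best[1]:
            best = (w, val)
    return best


def greedy_forward(
    model,
    A: Iterable[Node],
    k: int,
    kind: str = "ms",
    orientation: str = "directed",
) -> SelectionResult:
    """Greedy forward search: ``k`` rounds, each adding the node with the
    largest marginal capacity gain (smallest label on ties).

    Evaluates every remaining node each round — exactly
    ``k·|V| − k(k−1)/2`` capacity calls — and returns a lower bound on the
    size-``k`` optimum; at least ``(1 − 1/e)`` of it when the capacity is
    submodular in the source set.
    """
    ground = model.ground
    if not 1 <= k <= len(ground):
        raise ValueError("budget k must be between 1 and |V|")
    cap = _oracle(model, A, kind, orientation)
    S: set = set()
    rate = 0.0
    trace = []
    for _ in range(k):
        candidates = [(w, cap(S | {w})) for w in ground if w not in S]
        best = _select_best(candidates)
        if best is None:
            break
        w, val = best
        trace.append({"added": w, "gain": val - rate, "rate": val})
        S.add(w)
        rate = val
    selected = frozenset(S)
    return SelectionResult(selected, cap.peek(selected) if S else 0.0,
                           tuple(trace), cap.calls, "greedy")


def lazy_greedy(
    model,
    A: Iterable[Node],
    k: int,
    kind: str = "ms",
    orientation: str = "directed",
) -> SelectionResult:
    """Lazy (CELF-style) greedy: cached marginal gains in a priority queue.

    The queue is seeded with the singleton capacities.  A popped entry
    whose cached gain is stale is re-evaluated and pushed back; an entry
    still fresh for the current source set is selected immediately.  With
    a monotone submodular capacity this selects exactly the greedy set
    under the same smallest-label tie rule, with never more oracle calls
    (each node is re-evaluated at most once per round, and only if it
    reaches the top of the queue).
    """
    ground = model.ground
    if not 1 <= k <= len(ground):
        raise ValueError("budget k must be between 1 and |V|")
    cap = _oracle(model, A, kind, orientation)
    S: set = set()
    rate = 0.0
    trace = []
    # heap entries: (-gain, ground index, node, |S| when gain was computed)
    heap = []
    for w in ground:
        val = cap({w})
        heap.append((-val, ground.index(w), w, 0))
    heapq.heapify(heap)
    while len(S) < k and heap:
        neg_gain, idx, w, stamp = heapq.heappop(heap)
        if w in S:
            continue
        gain = -neg_gain
        if math.isinf(gain):
            continue  # degenerate query — never selectable, drop for good
        if stamp == len(S):
            S.add(w)
            rate += gain
            trace.append({"added": w, "gain": gain, "rate": rate})
            continue
        val = cap(S | {w})
        if math.isinf(val):
            continue
        heapq.heappush(heap, (-(val - rate), idx, w, len(S)))
    selected = frozenset(S)
    return SelectionResult(selected, cap.peek(selected) if S else 0.0,
                           tuple(trace), cap.calls, "lazy-greedy")


def brute_force_optimum(
    model,
    A: Iterable[Node],
    k: int,
    kind: str = "ms",
    orientation: str = "directed",
) -> tuple[float, frozenset]:
    """Exhaustive size-constrained optimum ``max_{|S| <= k} rho(S, A)``.

    Ties go to the lexicographically smallest set (smallest size first);
    degenerate infinite-capacity sets are skipped.  Guarded at 12 nodes.
    """
    ground = model.ground
    if len(ground) > 12:
        raise ValueError("ground set too large for brute force (max 12)")
    if k < 0:
        raise ValueError("budget must be nonnegative")
    cap = _oracle(model, A, kind, orientation)
    best_rate, best_set = 0.0, frozenset()
    for size in range(1, min(k, len(ground)) + 1):
        for combo in itertools.combinations(ground.nodes, size):
            S = frozenset(combo)
            val = cap(S)
            if math.isinf(val):
                continue
            if val > best_rate + _TOL:
                best_rate, best_set = val, S
    return best_rate, best_set
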