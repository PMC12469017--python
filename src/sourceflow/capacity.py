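"""Multicast capacities from a source set to a sink set.

Four directed variants, distinguished by whether sources and/or sinks may
collude:

* ``ms`` — multi-source multicast: the LP
  ``max r(S)  s.t.  r >= 0,  r(B) <= lambda(B, V\\B)  for every B not
  containing all of A``;
* ``ss`` — single (colluding) source: ``min cut(B)`` over ``S ⊆ B`` with
  ``B`` missing some sink, computable as a min over sinks of a max-flow
  after contracting ``S``;
* ``ma`` — colluding sinks: the ``ms`` LP with constraints restricted to
  ``B ⊆ V \\ A``;
* ``uc`` — both collude: a single s–t max-flow after contracting ``S``
  and ``A`` (infinite when they intersect).

Undirected variants add per-edge orientation variables: each edge
capacity is split fractionally between its two directions and the split
is optimized jointly (inside the same LP for ``ms``/``ma``; as a max–min
LP for ``ss``/``uc``).

Infinite capacity (empty constraint/cut family) is reported as the
explicit sentinel ``math.inf``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import networkx as nx
import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .linking import (
    DirectedGraphLinking,
    LinkingOracle,
    UndirectedGraphLinking,
    contract,
)
from .si import Node

__all__ = ["CapacityResult", "rho_ms", "rho_ma", "rho_ss", "rho_uc",
           "rho_undirected", "rho", "KINDS"]

KINDS = ("ms", "ss", "ma", "uc")

_ENUM_GUARD = 16  # 2^|V| constraint / subset enumeration limit
_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class CapacityResult:
    """A capacity value with a certifying witness.

    ``witness`` is the optimal rate vector (ms/ma), the minimizing cut set
    (ss/uc), or the orientation split as well for undirected queries.
    ``oracle_calls`` counts cut evaluations / max-flow solves performed.
    """

    value: float
    kind: str
    orientation: str
    witness: dict | None
    oracle_calls: int

    @property
    def finite(self) -> bool:
        return math.isfinite(self.value)

    def to_dict(self) -> dict:
        w = None
        if self.witness is not None:
            w = {}
            for key, val in self.witness.items():
                if isinstance(val, dict):
                    w[key] = {str(k): v for k, v in val.items()}
                elif isinstance(val, (set, frozenset)):
                    w[key] = sorted(map(str, val))
                else:
                    w[key] = val
        return {
            "value": "inf" if math.isinf(self.value) else self.value,
            "kind": self.kind,
            "orientation": self.orientation,
            "witness": w,
            "oracle_calls": self.oracle_calls,
        }


def _masks(n: int):
    return range(1 << n)


def _mask_of(ground, B) -> int:
    m = 0
    for u in B:
        m |= 1 << ground.index(u)
    return m


def _set_of(ground, mask: int) -> frozenset:
    return frozenset(u for i, u in enumerate(ground.nodes) if mask >> i & 1)


def _guard(model):
    n = len(model.ground)
    if n > _ENUM_GUARD:
        raise ValueError(
            f"|V| = {n} exceeds the subset-enumeration guard ({_ENUM_GUARD})"
        )
    return n


def _all_cuts(model) -> np.ndarray:
    """Out-cut of every subset, indexed by bitmask (one lambda evaluation
    per subset for oracle models; an arc sweep for graphs)."""
    n = len(model.ground)
    cuts = np.zeros(1 << n)
    if isinstance(model, DirectedGraphLinking):
        ground = model.ground
        for (u, w), cap in model.arcs.items():
            iu, iw = ground.index(u), ground.index(w)
            for mask in _masks(n):
                if mask >> iu & 1 and not mask >> iw & 1:
                    cuts[mask] += cap
    else:
        for mask in _masks(n):
            cuts[mask] = model.cut(_set_of(model.ground, mask))
    return cuts


def _rate_lp(model, S, A, restrict_to_complement: bool, kind: str) -> CapacityResult:
    """Shared LP for ms (all B missing a sink) and ma (B inside V \\ A)."""
    n = _guard(model)
    ground = model.ground
    S = ground.validate(S)
    A = ground.validate(A)
    if not A:
        return CapacityResult(math.inf, kind, "directed", None, 0)
    if not S:
        return CapacityResult(0.0, kind, "directed", {"rates": {}}, 0)
    maskA = _mask_of(ground, A)
    cuts = _all_cuts(model)
    rows, rhs, calls = [], [], 0
    for mask in _masks(n):
        if mask == 0:
            continue
        if restrict_to_complement:
            if mask & maskA:
                continue
        elif mask & maskA == maskA:
            continue
        row = np.zeros(n)
        for i in range(n):
            if mask >> i & 1:
                row[i] = 1.0
        rows.append(row)
        rhs.append(cuts[mask])
        calls += 1
    c = np.zeros(n)
    for u in S:
        c[ground.index(u)] = -1.0
    if not rows:
        # no constraint binds any source rate: capacity is unbounded
        return CapacityResult(math.inf, kind, "directed", None, calls)
    res = linprog(c, A_ub=np.array(rows), b_ub=np.array(rhs),
                  bounds=(0, None), method="highs")
    if res.status == 3:  # unbounded
        return CapacityResult(math.inf, kind, "directed", None, calls)
    if not res.success:
        raise RuntimeError(f"capacity LP failed: {res.message}")
    rates = {u: float(res.x[ground.index(u)]) for u in ground.nodes}
    return CapacityResult(float(-res.fun), kind, "directed",
                          {"rates": rates}, calls)


def rho_ms(model, S: Iterable[Node], A: Iterable[Node]) -> CapacityResult:
    """Multi-source multicast rate (independent per-node rates)."""
    return _rate_lp(model, S, A, restrict_to_complement=False, kind="ms")


def rho_ma(model, S: Iterable[Node], A: Iterable[Node]) -> CapacityResult:
    """Multiple-access rate (sinks collude to decode)."""
    return _rate_lp(model, S, A, restrict_to_complement=True, kind="ma")


def _min_cut_exhaustive(model, S, A, kind, inside_complement: bool) -> CapacityResult:
    n = _guard(model)
    ground = model.ground
    maskS = _mask_of(ground, S)
    maskA = _mask_of(ground, A)
    best, best_mask, calls = math.inf, None, 0
    cuts = _all_cuts(model)
    for mask in _masks(n):
        if mask & maskS != maskS:
            continue
        if inside_complement:
            if mask & maskA:
                continue
        elif mask & maskA == maskA:
            continue
        calls += 1
        if cuts[mask] < best:
            best, best_mask = cuts[mask], mask
    witness = None if best_mask is None else {"cut": _set_of(ground, best_mask)}
    return CapacityResult(float(best), kind, "directed", witness, calls)


def _maxflow_min_cut(G: nx.DiGraph, s, t) -> tuple[float, set]:
    value, (reach, _) = nx.minimum_cut(G, s, t)
    return value, set(reach)


def rho_ss(
    model, S: Iterable[Node], A: Iterable[Node], *, method: str = "auto"
) -> CapacityResult:
    """Single-source multicast rate: ``min_{S ⊆ B, B missing a sink} cut(B)``.

    For graph models the min runs over sinks ``j ∈ A \\ S`` of the s–j
    max-flow after contracting ``S`` (sinks already inside ``S`` are
    trivially served and skipped); infinite when ``A ⊆ S``.  For general
    oracles the min is exhaustive over qualifying subsets.
    """
    ground = model.ground
    S = ground.validate(S)
    A = ground.validate(A)
    if not A:
        return CapacityResult(math.inf, "ss", "directed", None, 0)
    if not S:
        return CapacityResult(0.0, "ss", "directed", {"cut": frozenset()}, 0)
    if A <= S:
        return CapacityResult(math.inf, "ss", "directed", None, 0)
    if method == "exhaustive" or not isinstance(model, DirectedGraphLinking):
        return _min_cut_exhaustive(model, S, A, "ss", inside_complement=False)
    contracted, label_map = contract(model, S)
    s_label = label_map[next(iter(S))]
    G = contracted.to_networkx()
    best, best_cut, calls = math.inf, None, 0
    for j in ground.sort(A - S):
        value, reach = _maxflow_min_cut(G, s_label, j)
        calls += 1
        if value < best:
            best = value
            best_cut = frozenset(
                u for u in ground
                if (label_map[u] in reach)
            )
    return CapacityResult(float(best), "ss", "directed",
                          {"cut": best_cut}, calls)


def rho_uc(
    model, S: Iterable[Node], A: Iterable[Node], *, method: str = "auto"
) -> CapacityResult:
    """Unicast rate with colluding sources and sinks: one s–t max-flow
    after contracting both sides; infinite when ``S`` meets ``A``."""
    ground = model.ground
    S = ground.validate(S)
    A = ground.validate(A)
    if not A:
        return CapacityResult(math.inf, "uc", "directed", None, 0)
    if not S:
        return CapacityResult(0.0, "uc", "directed", {"cut": frozenset()}, 0)
    if S & A:
        return CapacityResult(math.inf, "uc", "directed", None, 0)
    if method == "exhaustive" or not isinstance(model, DirectedGraphLinking):
        return _min_cut_exhaustive(model, S, A, "uc", inside_complement=True)
    step1, map1 = contract(model, S)
    step2, map2 = contract(step1, A)
    s_label = map1[next(iter(S))]
    t_label = map2[next(iter(A))]
    G = step2.to_networkx()
    value, reach = _maxflow_min_cut(G, s_label, t_label)
    cut = frozenset(u for u in ground if map2[map1[u]] in reach)
    return CapacityResult(float(value), "uc", "directed", {"cut": cut}, 1)


def rho_undirected(
    model: UndirectedGraphLinking,
    S: Iterable[Node],
    A: Iterable[Node],
    kind: str,
    *,
    method: str = "orientation",
) -> CapacityResult:
    """Undirected capacities: optimize the direction of every link.

    ``method="orientation"`` (default) assigns each edge a single
    direction — a binary orientation variable per edge, solved jointly
    with the rate vector (``ms``/``ma``) or the worst qualifying cut
    (``ss``/``uc``) as one mixed-integer LP.  This reproduces the worked
    butterfly values (rate 2 by routing from source {3}; rate 1 from
    source {1}).

    ``method="fractional"`` relaxes the orientation to a nonnegative
    capacity split per edge (a point of the orientation base polytope);
    it upper-bounds the integral value and can exceed it (1.5 versus 1
    from source {1} on the unit butterfly).
    """
    if kind not in KINDS:
        raise ValueError(f"unknown capacity kind {kind!r}")
    if method not in ("orientation", "fractional"):
        raise ValueError(f"unknown undirected method {method!r}")
    if not isinstance(model, UndirectedGraphLinking):
        raise TypeError("rho_undirected requires an undirected graph model")
    n = _guard(model)
    ground = model.ground
    S = ground.validate(S)
    A = ground.validate(A)
    if not A:
        return CapacityResult(math.inf, kind, "undirected", None, 0)
    if not S:
        return CapacityResult(0.0, kind, "undirected", None, 0)
    if kind == "ss" and A <= S:
        return CapacityResult(math.inf, kind, "undirected", None, 0)
    if kind == "uc" and S & A:
        return CapacityResult(math.inf, kind, "undirected", None, 0)
    maskS = _mask_of(ground, S)
    maskA = _mask_of(ground, A)
    edges = sorted(model.edges.items(), key=lambda kv: ground.sort(kv[0]))
    rate_based = kind in ("ms", "ma")

    def qualifying(mask: int) -> bool:
        if mask == 0:
            return False
        if kind == "ms":
            return mask & maskA != maskA
        if kind == "ma":
            return not mask & maskA
        if kind == "ss":
            return mask & maskS == maskS and mask & maskA != maskA
        return mask & maskS == maskS and not mask & maskA  # uc

    if method == "fractional":
        return _undirected_fractional(model, S, kind, edges, qualifying, rate_based)

    # Integral orientation: z_e = 1 orients edge (lo, hi) as lo -> hi.
    # Variables: [r_1..r_n | z_edges] (ms/ma) or [t | z_edges] (ss/uc).
    head = n if rate_based else 1
    nvar = head + len(edges)
    rows, lbs, ubs, calls = [], [], [], 0
    for mask in _masks(n):
        if not qualifying(mask):
            continue
        row = np.zeros(nvar)
        ub = 0.0
        if rate_based:
            for i in range(n):
                if mask >> i & 1:
                    row[i] = 1.0
        else:
            row[0] = 1.0
        for j, (e, cap) in enumerate(edges):
            lo, hi = ground.sort(e)
            ilo, ihi = ground.index(lo), ground.index(hi)
            lo_in, hi_in = mask >> ilo & 1, mask >> ihi & 1
            if lo_in == hi_in:
                continue
            if lo_in:  # out-capacity cap*z_e
                row[head + j] -= cap
            else:  # out-capacity cap*(1 - z_e)
                row[head + j] += cap
                ub += cap
        rows.append(row)
        ubs.append(ub)
        lbs.append(-np.inf)
        calls += 1
    if not rows:
        return CapacityResult(math.inf, kind, "undirected", None, calls)
    c = np.zeros(nvar)
    if rate_based:
        for u in S:
            c[ground.index(u)] = -1.0
    else:
        c[0] = -1.0
    integrality = np.concatenate([np.zeros(head), np.ones(len(edges))])
    bounds = Bounds(
        lb=np.concatenate([np.zeros(head), np.zeros(len(edges))]),
        ub=np.concatenate([np.full(head, np.inf), np.ones(len(edges))]),
    )
    res = milp(c, constraints=LinearConstraint(np.array(rows), lbs, ubs),
               integrality=integrality, bounds=bounds)
    if res.status == 3:
        return CapacityResult(math.inf, kind, "undirected", None, calls)
    if not res.success:
        raise RuntimeError(f"undirected orientation MILP failed: {res.message}")
    splits: dict[tuple[Node, Node], float] = {}
    for j, (e, cap) in enumerate(edges):
        lo, hi = ground.sort(e)
        z = float(res.x[head + j])
        splits[(lo, hi)] = cap * z
        splits[(hi, lo)] = cap * (1.0 - z)
    witness: dict = {"splits": splits}
    if rate_based:
        witness["rates"] = {u: float(res.x[ground.index(u)]) for u in ground}
    return CapacityResult(float(-res.fun), kind, "undirected", witness, calls)


def _undirected_fractional(model, S, kind, edges, qualifying, rate_based):
    """Fractional capacity-split relaxation (LP over the base polytope)."""
    ground = model.ground
    n = len(ground)
    arcs = model.oriented_arcs()
    arc_index = {a: i for i, a in enumerate(arcs)}
    head = n if rate_based else 1
    nvar = head + len(arcs)
    rows, rhs, calls = [], [], 0
    for mask in _masks(n):
        if not qualifying(mask):
            continue
        row = np.zeros(nvar)
        if rate_based:
            for i in range(n):
                if mask >> i & 1:
                    row[i] = 1.0
        else:
            row[0] = 1.0
        for (u, w) in arcs:
            if mask >> ground.index(u) & 1 and not mask >> ground.index(w) & 1:
                row[head + arc_index[(u, w)]] -= 1.0
        rows.append(row)
        rhs.append(0.0)
        calls += 1
    if not rows:
        return CapacityResult(math.inf, kind, "undirected", None, calls)
    # conservation: the two directed parts of each edge sum to its capacity
    eq_rows, eq_rhs = [], []
    for e, cap in edges:
        u, w = ground.sort(e)
        row = np.zeros(nvar)
        row[head + arc_index[(u, w)]] = 1.0
        row[head + arc_index[(w, u)]] = 1.0
        eq_rows.append(row)
        eq_rhs.append(cap)
    c = np.zeros(nvar)
    if rate_based:
        for u in S:
            c[ground.index(u)] = -1.0
    else:
        c[0] = -1.0
    res = linprog(c, A_ub=np.array(rows), b_ub=np.array(rhs),
                  A_eq=np.array(eq_rows), b_eq=np.array(eq_rhs),
                  bounds=(0, None), method="highs")
    if res.status == 3:
        return CapacityResult(math.inf, kind, "undirected", None, calls)
    if not res.success:
        raise RuntimeError(f"undirected capacity LP failed: {res.message}")
    splits = {a: float(res.x[head + i]) for a, i in arc_index.items()}
    witness: dict = {"splits": splits}
    if rate_based:
        witness["rates"] = {u: float(res.x[ground.index(u)]) for u in ground}
    return CapacityResult(float(-res.fun), kind, "undirected", witness, calls)


def rho(
    model,
    S: Iterable[Node],
    A: Iterable[Node],
    kind: str = "ms",
    orientation: str = "directed",
    **kwargs,
) -> CapacityResult:
    """Dispatch to the requested capacity variant.

    Enforces the boundary conventions: empty source gives rate 0, empty
    sink set gives the infinite sentinel.
    """
    if kind not in KINDS:
        raise ValueError(f"unknown capacity kind {kind!r}")
    if orientation == "undirected":
        return rho_undirected(model, S, A, kind, **kwargs)
    if orientation != "directed":
        raise ValueError(f"unknown orientation {orientation!r}")
    fn = {"ms": rho_ms, "ma": rho_ma, "ss": rho_ss, "uc": rho_uc}[kind]
    return fn(model, S, A, **kwargs)
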