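import heapq

import numpy as np
import pytest

import sourceflow as sf
from sourceflow.si import GroundSet, TableRateModel


@pytest.fixture
def path3():
    return sf.path3()


@pytest.fixture
def butterfly():
    return sf.butterfly_directed()


@pytest.fixture
def butterfly_u():
    return sf.butterfly_undirected()


@pytest.fixture
def star4():
    """Star with center 'c' and leaves a, b, d; unit rates."""
    return sf.GraphRateModel.from_edges(
        [("c", "a", 1.0), ("c", "b", 1.0), ("c", "d", 1.0)], directed=False
    )


def random_table_model(rng, n_min=3, n_max=5) -> TableRateModel:
    """Random monotone (non-graph) hazard table: a concave power of a
    random weighted in-neighborhood sum — monotone but not modular."""
    n = int(rng.integers(n_min, n_max + 1))
    ground = GroundSet(range(n))
    w = rng.random((n, n)) * (rng.random((n, n)) < 0.7)
    np.fill_diagonal(w, 0.0)
    gamma = 0.5 + 0.5 * rng.random()

    def fn(u, B):
        s = sum(w[v][u] for v in B)
        return float(s**gamma) if s > 0 else 0.0

    return TableRateModel.from_function(ground, fn)


def random_digraph(rng, n_max=8, p=0.4):
    """Random unit-capacity digraph on [n] with at least one arc."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        edges = [
            (u, v, 1.0)
            for u in range(n)
            for v in range(n)
            if u != v and rng.random() < p
        ]
        if edges:
            return sf.DirectedGraphLinking.from_edges(edges, nodes=range(n))


def per_edge_clock_simulate(edges, W, rng):
    """Independent oracle for the classical SI reading: one exponential
    clock per directed edge, infection times by first-passage (Dijkstra
    with random edge weights).  Returns the infection sequence."""
    adj: dict = {}
    for u, v, rate in edges:
        adj.setdefault(u, []).append((v, rate))
        adj.setdefault(v, []).append((u, rate))
    T = {u: 0.0 for u in W}
    heap = [(0.0, u) for u in sorted(W, key=str)]
    heapq.heapify(heap)
    done = set()
    sequence = []
    while heap:
        t, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        if u not in W:
            sequence.append(u)
        for v, rate in adj.get(u, []):
            if v in done:
                continue
            cand = t + rng.exponential(1.0 / rate)
            if v not in T or cand < T[v]:
                T[v] = cand
                heapq.heappush(heap, (cand, v))
    return tuple(sequence)
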