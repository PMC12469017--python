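"""Multicast capacities: worked butterfly values, sandwich bounds, witnesses."""

import itertools
import math

import numpy as np
import pytest

import sourceflow as sf
from sourceflow.capacity import rho, rho_ma, rho_ms, rho_ss, rho_uc, rho_undirected

from conftest import random_digraph


class TestDirectedButterfly:
    """Worked values: coding from {1,2} achieves 2; singletons achieve 1."""

    @pytest.mark.parametrize(
        "S, expected",
        [({1, 2}, 2.0), ({1}, 1.0), ({2}, 1.0), ({3}, 1.0), ({4}, 1.0),
         ({5}, 0.0), ({6}, 0.0), ({5, 6}, 0.0), ({1, 3}, 1.0)],
    )
    def test_ms(self, butterfly, S, expected):
        assert rho_ms(butterfly, S, {5, 6}).value == pytest.approx(expected, abs=1e-9)

    def test_ss(self, butterfly):
        assert rho_ss(butterfly, {1, 2}, {5, 6}).value == pytest.approx(2.0)
        assert rho_ss(butterfly, {3}, {5, 6}).value == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "S, A, expected",
        [({1}, {5}, 2.0), ({4}, {6}, 1.0), ({1, 2}, {5, 6}, 3.0)],
    )
    def test_uc(self, butterfly, S, A, expected):
        assert rho_uc(butterfly, S, A).value == pytest.approx(expected)

    def test_ma(self, butterfly):
        # colluding sinks relax the per-sink cuts: 3 = cut({1,2,3})
        assert rho_ma(butterfly, {1, 2}, {5, 6}).value == pytest.approx(3.0)


class TestSentinels:
    def test_sinks_inside_source_ss(self, butterfly):
        assert math.isinf(rho_ss(butterfly, {5, 6}, {5, 6}).value)

    def test_overlap_uc(self, butterfly):
        assert math.isinf(rho_uc(butterfly, {5}, {5, 6}).value)

    def test_empty_sink_is_unbounded(self, butterfly):
        for kind in ("ms", "ss", "ma", "uc"):
            assert math.isinf(rho(butterfly, {1}, set(), kind).value)

    def test_empty_source_is_zero(self, butterfly):
        for kind in ("ms", "ss", "ma", "uc"):
            assert rho(butterfly, set(), {5, 6}, kind).value == 0.0

    def test_single_node_source_equals_sink(self):
        # the constraint family B ⊆ V \ A is empty, so nothing bounds the
        # rate of a node that is itself the sink
        model = sf.DirectedGraphLinking.from_edges([], nodes=[0])
        assert math.isinf(rho_ma(model, {0}, {0}).value)

    def test_unknown_kind(self, butterfly):
        with pytest.raises(ValueError):
            rho(butterfly, {1}, {5}, "xx")


class TestFastPathEqualsExhaustive:
    def test_butterfly_all_pairs(self, butterfly):
        nodes = list(butterfly.ground)
        for s, a in itertools.permutations(nodes, 2):
            fast = rho_ss(butterfly, {s}, {a}).value
            slow = rho_ss(butterfly, {s}, {a}, method="exhaustive").value
            assert fast == pytest.approx(slow, abs=1e-9)
            fast = rho_uc(butterfly, {s}, {a}).value
            slow = rho_uc(butterfly, {s}, {a}, method="exhaustive").value
            assert fast == pytest.approx(slow, abs=1e-9)

    def test_random_digraphs(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            model = random_digraph(rng, n_max=8)
            nodes = list(model.ground)
            S = {nodes[int(rng.integers(len(nodes)))]}
            A = {nodes[int(rng.integers(len(nodes)))],
                 nodes[int(rng.integers(len(nodes)))]}
            fast = rho_ss(model, S, A).value
            slow = rho_ss(model, S, A, method="exhaustive").value
            assert fast == pytest.approx(slow, abs=1e-9)


class TestWitnesses:
    def test_ms_rate_vector_certifies_value(self, butterfly):
        res = rho_ms(butterfly, {1, 2}, {5, 6})
        rates = res.witness["rates"]
        assert sum(rates[u] for u in (1, 2)) == pytest.approx(res.value, abs=1e-9)
        nodes = list(butterfly.ground)
        for k in range(1, 7):
            for B in itertools.combinations(nodes, k):
                if {5, 6} <= set(B):
                    continue
                assert sum(rates[u] for u in B) <= sf.cut_value(
                    butterfly, set(B)
                ) + 1e-9

    def test_ss_cut_certifies_value(self, butterfly):
        res = rho_ss(butterfly, {1, 2}, {5, 6})
        cut = res.witness["cut"]
        assert {1, 2} <= cut and not {5, 6} <= cut
        assert sf.cut_value(butterfly, cut) == pytest.approx(res.value)

    def test_integer_values_on_unit_networks(self, butterfly):
        for S in ({1}, {2}, {3}, {4}, {1, 2}):
            v = rho_ms(butterfly, S, {5, 6}).value
            assert abs(v - round(v)) < 1e-9


class TestSandwichAndMonotonicity:
    def test_sandwich_on_random_queries(self):
        """ss and ma both lie in [ms, uc] whenever all four are finite."""
        rng = np.random.default_rng(123)
        tested = 0
        while tested < 20:
            model = random_digraph(rng, n_max=7)
            nodes = list(model.ground)
            S = {u for u in nodes if rng.random() < 0.3}
            A = {u for u in nodes if rng.random() < 0.3}
            if not S or not A or S & A:
                continue
            ms = rho_ms(model, S, A).value
            ss = rho_ss(model, S, A).value
            ma = rho_ma(model, S, A).value
            uc = rho_uc(model, S, A).value
            assert ms - 1e-9 <= ss <= uc + 1e-9
            assert ms - 1e-9 <= ma <= uc + 1e-9
            tested += 1

    def test_monotone_in_source_set(self, butterfly):
        rng = np.random.default_rng(3)
        nodes = list(butterfly.ground)
        for _ in range(20):
            S = {u for u in nodes if rng.random() < 0.4}
            extra = {u for u in nodes if rng.random() < 0.3}
            A = {5, 6}
            small = rho_ms(butterfly, S, A).value
            big = rho_ms(butterfly, S | extra, A).value
            assert small <= big + 1e-9


class TestUndirectedButterfly:
    """Worked undirected values: routing from {3} achieves 2; {1} and {2}
    are limited to 1 by their two-edge bottleneck."""

    @pytest.mark.parametrize(
        "S, expected",
        [({3}, 2.0), ({1}, 1.0), ({2}, 1.0), ({4}, 2.0), ({5}, 2.0),
         ({6}, 2.0), ({1, 2}, 2.0)],
    )
    def test_ms_orientation(self, butterfly_u, S, expected):
        got = rho_undirected(butterfly_u, S, {5, 6}, "ms")
        assert got.value == pytest.approx(expected, abs=1e-9)

    def test_fractional_relaxation_upper_bounds(self, butterfly_u):
        for S in ({1}, {2}, {3}, {1, 2}):
            integral = rho_undirected(butterfly_u, S, {5, 6}, "ms").value
            frac = rho_undirected(butterfly_u, S, {5, 6}, "ms",
                                  method="fractional").value
            assert frac >= integral - 1e-9
        # the relaxation is strict from source {1}: 1.5 versus 1
        assert rho_undirected(butterfly_u, {1}, {5, 6}, "ms",
                              method="fractional").value == pytest.approx(1.5)

    def test_orientation_witness_is_feasible_split(self, butterfly_u):
        res = rho_undirected(butterfly_u, {3}, {5, 6}, "ms")
        directed = butterfly_u.orient(res.witness["splits"])
        rates = res.witness["rates"]
        nodes = list(butterfly_u.ground)
        for k in range(1, 7):
            for B in itertools.combinations(nodes, k):
                if {5, 6} <= set(B):
                    continue
                assert sum(rates[u] for u in B) <= sf.cut_value(
                    directed, set(B)
                ) + 1e-9

    def test_undirected_sandwich(self, butterfly_u):
        for S in ({3}, {1}, {1, 2}):
            vals = {k: rho_undirected(butterfly_u, S, {5, 6}, k).value
                    for k in ("ms", "ss", "ma", "uc")}
            finite = {k: v for k, v in vals.items() if math.isfinite(v)}
            for k in ("ss", "ma"):
                if k in finite and "uc" in finite:
                    assert vals["ms"] - 1e-9 <= vals[k] <= vals["uc"] + 1e-9

    def test_dispatcher_undirected(self, butterfly_u):
        assert rho(butterfly_u, {3}, {5, 6}, "ms", "undirected").value == 2.0
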