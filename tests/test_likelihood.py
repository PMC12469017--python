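"""Snapshot likelihoods, the CTMC oracle, and the three source estimators."""

import itertools
import math

import numpy as np
import pytest
from scipy.integrate import quad

import sourceflow as sf

from conftest import random_table_model


class TestPermittedSequences:
    def test_path_center_source(self, path3):
        assert sf.permitted_sequences(path3, {1}, {0, 1, 2}) == ((0, 2), (2, 0))

    def test_snapshot_equals_source(self, path3):
        assert sf.permitted_sequences(path3, {0, 1}, {0, 1}) == ((),)

    def test_unreachable_snapshot_has_no_sequences(self, path3):
        assert sf.permitted_sequences(path3, {0}, {0, 2}) == ()

    def test_every_step_has_positive_hazard(self, path3):
        for seq in sf.permitted_sequences(path3, {0}, {0, 1, 2}):
            B = {0}
            for u in seq:
                assert path3.hazard(u, B) > 0
                B.add(u)


class TestHoldingDensity:
    def test_density_at_zero_equals_rate(self, path3):
        assert sf.holding_density(path3, {1}, 0, 0.0) == pytest.approx(1.0)

    def test_total_mass_is_jump_probability(self, path3):
        mass, _ = quad(lambda t: sf.holding_density(path3, {1}, 0, t), 0, np.inf)
        assert mass == pytest.approx(0.5, abs=1e-9)

    def test_closed_form(self, path3):
        assert sf.holding_density(path3, {0, 1}, 2, 1.0) == pytest.approx(
            math.exp(-1), abs=1e-12
        )

    def test_impermissible_step_rejected(self, path3):
        with pytest.raises(ValueError, match="impermissible"):
            sf.holding_density(path3, {0}, 2, 1.0)


class TestSequenceLikelihood:
    def test_certain_absorption_at_infinity(self, path3):
        assert sf.sequence_likelihood(path3, {0}, (1, 2), math.inf) == 1.0

    def test_hypoexponential_cdf(self, path3):
        # chain of two unit-rate stages: 1 - e^{-t} - t e^{-t}
        got = sf.sequence_likelihood(path3, {0}, (1, 2), 1.0)
        assert got == pytest.approx(1 - 2 * math.exp(-1), abs=1e-12)

    def test_branching_chain(self, path3):
        # from the center: jump prob 1/2 times hypoexp(2,1) passage
        got = sf.sequence_likelihood(path3, {1}, (0, 2), 1.0)
        assert got == pytest.approx(0.5 * (1 - math.exp(-1)) ** 2, abs=1e-12)

    def test_wrong_cover_rejected(self, path3):
        with pytest.raises(ValueError):
            sf.sequence_likelihood(path3, {0}, (1,), 1.0, S={0, 1, 2})


class TestSnapshotLikelihood:
    def test_center_source_full_snapshot(self, path3):
        got = sf.snapshot_likelihood(path3, {1}, {0, 1, 2}, 1.0)
        assert got == pytest.approx((1 - math.exp(-1)) ** 2, abs=1e-12)

    def test_end_source_full_snapshot(self, path3):
        got = sf.snapshot_likelihood(path3, {0}, {0, 1, 2}, 1.0)
        assert got == pytest.approx(1 - 2 * math.exp(-1), abs=1e-12)

    def test_partial_snapshot_with_escape(self, path3):
        # infected {0,1} at t: survival of node 2 matters
        got = sf.snapshot_likelihood(path3, {1}, {0, 1}, 1.0)
        assert got == pytest.approx(math.exp(-1) - math.exp(-2), abs=1e-12)

    def test_everything_infected_is_certain(self, path3):
        for t in (0.0, 0.5, 7.0):
            assert sf.snapshot_likelihood(path3, {0, 1, 2}, {0, 1, 2}, t) == 1.0


class TestCtmcOracle:
    @pytest.mark.parametrize("t", [0.1, 1.0, 10.0])
    def test_agrees_on_path(self, path3, t):
        nodes = [0, 1, 2]
        for k in range(1, 4):
            for S in map(frozenset, itertools.combinations(nodes, k)):
                for W in map(frozenset, sf.si._powerset(sorted(S))):
                    if not W:
                        continue
                    a = sf.snapshot_likelihood(path3, W, S, t)
                    b = sf.ctmc_likelihood(path3, W, S, t)
                    assert a == pytest.approx(b, abs=1e-9)

    def test_agrees_on_random_models(self):
        """Dual-route check: sequence-sum recursion vs subset-lattice CTMC
        on 50 random non-modular hazard tables."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 50:
            model = random_table_model(rng)
            nodes = list(model.ground)
            S = frozenset(
                u for u in nodes if rng.random() < 0.7
            ) or frozenset(nodes[:1])
            members = sorted(S)
            W = frozenset(u for u in members if rng.random() < 0.5)
            if not W:
                W = frozenset(members[:1])
            t = float(rng.choice([0.1, 1.0, 5.0]))
            a = sf.snapshot_likelihood(model, W, S, t)
            b = sf.ctmc_likelihood(model, W, S, t)
            assert a == pytest.approx(b, abs=1e-9)
            checked += 1

    def test_boundaries(self, path3):
        assert sf.ctmc_likelihood(path3, {0, 1, 2}, {0, 1, 2}, 3.0) == 1.0
        assert sf.ctmc_likelihood(path3, {1}, {0, 1, 2}, 0.0) == 0.0


class TestNormalization:
    def test_snapshot_law_sums_to_one(self):
        """For fixed W and t the snapshot likelihood is a distribution
        over supersets of W."""
        rng = np.random.default_rng(5)
        model = random_table_model(rng, n_min=4, n_max=4)
        nodes = list(model.ground)
        W = frozenset(nodes[:1])
        for t in (0.3, 1.0):
            total = sum(
                sf.snapshot_likelihood(model, W, W | frozenset(extra), t)
                for extra in sf.si._powerset(nodes[1:])
            )
            assert total == pytest.approx(1.0, abs=1e-8)

    def test_jump_chain_sums_to_one_per_size(self, path3):
        W = frozenset({1})
        free = [0, 2]
        for k in range(0, 3):
            total = sum(
                sf.ml_first_k(path3, W | frozenset(extra), W)
                for extra in itertools.combinations(free, k)
            )
            assert total == pytest.approx(1.0, abs=1e-12)


class TestClassicalEstimators:
    def test_ml_first_k_is_degenerate_on_the_path(self, path3):
        S = {0, 1, 2}
        assert [sf.ml_first_k(path3, S, {s}) for s in (0, 1, 2)] == [1.0, 1.0, 1.0]

    def test_ml_first_k_partial(self, path3):
        assert sf.ml_first_k(path3, {0, 1}, {1}) == pytest.approx(0.5)

    def test_jml_is_degenerate_on_the_path(self, path3):
        for s in (0, 1, 2):
            value, t_at = sf.jml(path3, {0, 1, 2}, {s})
            assert value == pytest.approx(1.0, abs=1e-9)
            assert math.isinf(t_at)

    def test_jml_matches_dense_grid_brute_force(self, path3):
        value, t_at = sf.jml(path3, {0, 1}, {1})
        # independent closed form: P[infected set is {0,1} at t] = e^{-t} - e^{-2t}
        grid = np.linspace(1e-4, 20, 400001)
        brute = float(np.max(np.exp(-grid) - np.exp(-2 * grid)))
        assert value == pytest.approx(brute, abs=1e-6)
        # closed form: e^{-t} - e^{-2t} peaks at ln 2 with value 1/4
        assert value == pytest.approx(0.25, abs=1e-9)
        assert t_at == pytest.approx(math.log(2), abs=1e-5)


class TestAlphaFactorization:
    @pytest.mark.parametrize("s", [0, 1, 2])
    def test_identity_at_finite_time(self, path3, s):
        S = {0, 1, 2}
        lhs = sf.snapshot_likelihood(path3, {s}, S, 1.0)
        rhs = sf.ml_first_k(path3, S, {s}) * sf.alpha(path3, s, S, 1.0)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_limits(self, path3):
        assert sf.alpha(path3, 0, {0, 1, 2}, math.inf) == pytest.approx(1.0)
        assert sf.alpha(path3, 1, {0, 1, 2}, 0.0) == 0.0

    def test_undefined_when_unreachable(self, path3):
        with pytest.raises(ValueError):
            sf.alpha(path3, 0, {0, 2}, 1.0)


class TestRandomTimeEstimator:
    def test_point_mass_identifies_center(self, path3):
        res = sf.ml_random_time(
            path3, {0, 1, 2}, sf.ObservationTimeDistribution.point(1.0)
        )
        assert res.argmax == (frozenset({1}),)
        assert not res.degenerate

    @pytest.mark.parametrize(
        "dist",
        [
            sf.ObservationTimeDistribution.exponential(1.0),
            sf.ObservationTimeDistribution.uniform(0.2, 3.0),
        ],
    )
    def test_random_time_laws_identify_center(self, path3, dist):
        res = sf.ml_random_time(path3, {0, 1, 2}, dist)
        assert res.argmax == (frozenset({1}),)

    def test_exponential_scores_closed_form(self, path3):
        # E[(1-e^-T)^2] = 1/3 and E[1 - e^-T - T e^-T] = 1/4 for T ~ Exp(1)
        res = sf.ml_random_time(
            path3, {0, 1, 2}, sf.ObservationTimeDistribution.exponential(1.0)
        )
        assert res.scores[frozenset({1})] == pytest.approx(1 / 3, abs=1e-8)
        assert res.scores[frozenset({0})] == pytest.approx(1 / 4, abs=1e-8)

    def test_full_hypothesis_scores_one(self, path3):
        res = sf.ml_random_time(
            path3,
            {0, 1, 2},
            sf.ObservationTimeDistribution.point(1.0),
            hypotheses=[{0, 1, 2}],
        )
        assert res.scores[frozenset({0, 1, 2})] == pytest.approx(1.0)

    def test_tabulated_density_must_normalize(self):
        with pytest.raises(ValueError, match="integrates"):
            sf.ObservationTimeDistribution.tabulated([0, 1, 2], [1.0, 1.0, 1.0])

    def test_detect_flags_classical_degeneracy(self, path3):
        res = sf.detect(path3, {0, 1, 2}, "ml-k")
        assert res.degenerate
        assert len(res.argmax) == 3
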