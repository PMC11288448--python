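"""Exact chain solver: closed-form oracles, identities and the neutral
N-equation system."""

from fractions import Fraction

import numpy as np
import pytest

from moranbd import families
from moranbd.exact import (CapacityError, MoranParams, balanced_fp_formula,
                           balanced_fp_vector, fixation_time_max,
                           neutral_fp_vector, solve_exact,
                           solve_exact_rational, step_distribution)
from moranbd.families import random_graph_fixture
from moranbd.graph import DirectedGraph

from conftest import moran_fp_complete


class TestStepDistribution:
    def test_two_cycle_neutral_single_mutant(self):
        g = families.cycle(2)
        d = step_distribution(g, 1.0, {0})
        assert d == pytest.approx({0b00: 0.5, 0b11: 0.5})

    def test_complete_k3_neutral_enumerated(self, k3):
        # parent each w.p. 1/3, victim uniform over the other two
        d = step_distribution(k3, 1.0, {0})
        assert d[0b000] == pytest.approx(1 / 3)      # mutant replaced
        assert d[0b001] == pytest.approx(1 / 3)      # lazy: r replaces r
        assert d[0b011] + d[0b101] == pytest.approx(1 / 3)

    def test_absorbing_states_fixed(self, k3):
        full = 0b111
        assert step_distribution(k3, 2.0, full) == {full: 1.0}
        assert step_distribution(k3, 2.0, 0) == {0: 1.0}

    @pytest.mark.parametrize("seed", range(20))
    def test_probabilities_sum_to_one(self, seed):
        g = random_graph_fixture("strongly_connected", 5, 0.4, seed)
        rng = np.random.default_rng(seed)
        s = int(rng.integers(1, 2 ** 5 - 1))
        assert sum(step_distribution(g, 1.7, s).values()) == pytest.approx(1.0)


class TestSolveExact:
    def test_two_cycle_absorbs_in_one_step(self):
        sol = solve_exact(families.cycle(2), 1.0)
        assert sol.fp[0b01] == pytest.approx(0.5)
        assert sol.at[0b01] == pytest.approx(1.0)
        assert sol.ft[0b01] == pytest.approx(1.0)
        assert sol.ext[0b01] == pytest.approx(1.0)

    def test_complete_k3_neutral_lumped_oracle(self, k3):
        # lumping by mutant count gives a lazy +-1 walk: fp = 1/3, at = 3
        sol = solve_exact(k3, 1.0)
        assert sol.fp[0b001] == pytest.approx(1 / 3, rel=1e-10)
        assert sol.at[0b001] == pytest.approx(3.0, rel=1e-10)

    @pytest.mark.parametrize("n,r", [(3, 2.0), (4, 1.5), (5, 1.1), (4, 1.0)])
    def test_complete_graph_matches_birth_death_closed_form(self, n, r):
        sol = solve_exact(families.complete(n), r)
        assert sol.fp_single == pytest.approx(
            np.full(n, moran_fp_complete(n, r)), rel=1e-10)

    def test_rational_solver_agrees_with_float_path(self, k3):
        fr = solve_exact_rational(k3, Fraction(2))
        assert fr[0b001] == Fraction(4, 7)
        sol = solve_exact(k3, 2.0)
        for s, val in fr.items():
            assert sol.fp[s] == pytest.approx(float(val), abs=1e-12)

    def test_conditional_time_undefined_at_boundaries(self, star4):
        sol = solve_exact(star4, 1.2)
        assert np.isnan(sol.ft[0]) and sol.ft[-1] == 0.0
        assert np.isnan(sol.ext[-1]) and sol.ext[0] == 0.0

    def test_capacity_guard(self):
        with pytest.raises(CapacityError):
            solve_exact(families.cycle(15), 1.0)

    def test_disadvantageous_fitness_supported(self, k3):
        sol = solve_exact(k3, 0.5)
        assert sol.fp[0b001] == pytest.approx(moran_fp_complete(3, 0.5),
                                              rel=1e-10)

    def test_invalid_fitness_rejected(self):
        with pytest.raises(ValueError):
            MoranParams(r=0.0)

    def test_active_steps_clock_shorter(self, star4):
        lazy = solve_exact(star4, 1.1)
        active = solve_exact(star4, 1.1, count_lazy_steps=False)
        assert active.at[0b0010] < lazy.at[0b0010]
        # fixation probability does not depend on the clock
        assert active.fp_single == pytest.approx(lazy.fp_single, rel=1e-10)


@pytest.mark.parametrize("seed", range(25))
@pytest.mark.parametrize("r", [1.0, 1.1, 2.0, 10.0])
def test_time_decomposition_identity(seed, r):
    """at = fp*ft + (1-fp)*ext at every transient configuration."""
    g = random_graph_fixture("strongly_connected", 5, 0.3, seed)
    sol = solve_exact(g, r)
    n_states = 1 << g.n_nodes
    for s in range(1, n_states - 1):
        recomposed = sol.fp[s] * sol.ft[s] + (1 - sol.fp[s]) * sol.ext[s]
        assert recomposed == pytest.approx(sol.at[s], rel=1e-10)


@pytest.mark.parametrize("seed", range(25))
def test_neutral_fixation_probability_is_additive(seed):
    """At r=1, fp(S) equals the sum of single-mutant fp over S: the
    reduction that collapses 2^N equations to N."""
    g = random_graph_fixture("strongly_connected", 5, 0.35, seed)
    sol = solve_exact(g, 1.0)
    singles = sol.fp_single
    n_states = 1 << g.n_nodes
    for s in range(n_states):
        expected = sum(singles[v] for v in range(g.n_nodes) if s >> v & 1)
        assert sol.fp[s] == pytest.approx(expected, abs=1e-10)


@pytest.mark.parametrize("seed", range(15))
def test_regular_graphs_are_isothermal(seed):
    """Single-mutant fp on any regular graph equals the complete-graph
    value for the same N and r (1-D birth-death closed form)."""
    g = random_graph_fixture("regular", 6, 0.4, seed)
    for r in (1.0, 1.3, 2.0):
        sol = solve_exact(g, r)
        assert sol.fp_single == pytest.approx(
            np.full(6, moran_fp_complete(6, r)), rel=1e-9)


class TestNeutralVector:
    def test_complete_graph_uniform(self):
        nfp = neutral_fp_vector(families.complete(5))
        assert nfp.fp_single == pytest.approx(np.full(5, 0.2), rel=1e-10)
        assert nfp.fp_min == pytest.approx(0.2)

    def test_star4_center_and_leaves(self, star4):
        nfp = neutral_fp_vector(star4)
        assert nfp.fp_single[0] == pytest.approx(0.1, rel=1e-10)
        assert nfp.fp_single[1:] == pytest.approx(np.full(3, 0.3), rel=1e-10)

    def test_directed_cycle_uniform(self):
        nfp = neutral_fp_vector(families.cycle(7))
        assert nfp.fp_single == pytest.approx(np.full(7, 1 / 7), rel=1e-10)

    @pytest.mark.parametrize("seed", range(30))
    def test_agrees_with_full_chain_and_bounds(self, seed):
        g = random_graph_fixture("strongly_connected", 6, 0.3, seed)
        nfp = neutral_fp_vector(g)
        sol = solve_exact(g, 1.0)
        assert nfp.fp_single == pytest.approx(sol.fp_single, abs=1e-10)
        assert nfp.fp_single.sum() == pytest.approx(1.0)
        assert nfp.fp_min <= 1 / g.n_nodes + 1e-12


class TestBalancedFormula:
    def test_star4_values(self, star4):
        assert balanced_fp_formula(star4, 1) == pytest.approx(0.3)
        assert balanced_fp_formula(star4, 0) == pytest.approx(0.1)
        assert balanced_fp_formula(star4, 0) >= 1 / 16  # >= 1/N^2

    def test_directed_cycle_uniform(self):
        g = families.cycle(6)
        assert balanced_fp_formula(g, 3) == pytest.approx(1 / 6)

    def test_rejected_on_unbalanced_graph(self):
        g = families.fan(2)  # triangle-blade fan is not balanced
        with pytest.raises(Exception):
            balanced_fp_formula(g, 0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_neutral_vector_on_undirected_fixtures(self, seed):
        g = random_graph_fixture("undirected", 6, 0.4, seed)
        assert balanced_fp_vector(g) == pytest.approx(
            neutral_fp_vector(g).fp_single, abs=1e-10)

    def test_balance_characterizes_reciprocal_indegree_law(self):
        """is_balanced(g) holds iff the neutral single-mutant fp is
        proportional to 1/indegree: true on the vortex, false on the
        wide superstar (whose neutral law deviates from 1/indegree)."""
        for g, expect in [(families.vortex(2), True),
                          (families.superstar(2, 1, 3), False),
                          (families.metafunnel(2, 2), False)]:
            nfp = neutral_fp_vector(g).fp_single
            recip = np.array([1 / g.indegree(v) for v in range(g.n_nodes)])
            prop = np.allclose(nfp, recip / recip.sum(), atol=1e-10)
            assert g.is_balanced() == expect
            assert prop == expect


def test_fixation_time_max_trivial_cases():
    assert fixation_time_max(families.cycle(2), 3.0) == pytest.approx(1.0)
    star = families.star(4)
    sol = solve_exact(star, 1.0)
    assert fixation_time_max(star, 1.0) == pytest.approx(
        np.nanmax(sol.ft[1:]))
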