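"""Unit tests for the equilibrium model: constants, ideal yield, full solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from transglyc import (
    DomainError,
    PhosphorolysisEntry,
    TransglycosylationSystem,
    apparent_constant,
    ideal_yield,
    phosphate_gap,
    solve_equilibrium,
    yield_vs_phosphate,
)

SPECIES = ("N1", "B1", "N2", "B2", "P", "P1P")


class TestApparentConstant:
    @pytest.mark.parametrize(
        "args, expected",
        [
            ((1.0, 1.0, 1.0, 1.0), 1.0),
            # phosphorolysis-only equilibrium of 1 mM nucleoside + 1 mM
            # phosphate at K = 0.16: xi/(1-xi) = sqrt(K), xi = 2/7
            ((5.0 / 7, 2.0 / 7, 2.0 / 7, 5.0 / 7), 0.16),
        ],
    )
    def test_recovers_constant_from_composition(self, args, expected):
        assert apparent_constant(*args) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize(
        "args",
        [
            (1.0, 0.5, 0.5, 0.0),  # zero phosphate: quotient undefined
            (0.0, 0.5, 0.5, 1.0),  # zero nucleoside
            (1.0, -0.1, 0.5, 1.0),  # negative base
        ],
    )
    def test_rejects_degenerate_compositions(self, args):
        with pytest.raises(DomainError):
            apparent_constant(*args)


class TestIdealYield:
    def test_symmetric_linear_case(self):
        # K_N = 1 degenerates the quadratic; exact harmonic-style solution
        res = ideal_yield(1.0, 1.0, 0.5)
        assert res.N2_mM == pytest.approx(1.0 / 3.0, rel=1e-12)
        assert res.yield_fraction == pytest.approx(2.0 / 3.0, rel=1e-12)

    @pytest.mark.parametrize(
        "K_N, N1_0, B2_0, expected_n2",
        [
            # frozen from a brute-force scan of the quadratic's roots with
            # feasibility filtering (independent of the closed form used here)
            (16.0, 1.0, 0.5, 0.4734013676289095),
            (16.0 / 35.0, 1.0, 0.5, 0.2739289754781712),
        ],
    )
    def test_matches_brute_force_roots(self, K_N, N1_0, B2_0, expected_n2):
        res = ideal_yield(K_N, N1_0, B2_0)
        assert res.N2_mM == pytest.approx(expected_n2, abs=1e-9)
        assert res.yield_fraction == pytest.approx(expected_n2 / B2_0, abs=1e-9)

    def test_no_donor_no_product(self):
        assert ideal_yield(5.0, 0.0, 1.0) == (0.0, 0.0)

    @pytest.mark.parametrize("bad", [{"K_N": 0.0}, {"K_N": -1.0}, {"B2_0": 0.0}])
    def test_rejects_nonpositive_inputs(self, bad):
        kwargs = dict(K_N=2.0, N1_0=1.0, B2_0=0.5)
        kwargs.update(bad)
        with pytest.raises(DomainError):
            ideal_yield(**kwargs)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        K_N=st.floats(1e-3, 1e3),
        N1_0=st.floats(1e-3, 50.0),
        B2_0=st.floats(1e-3, 50.0),
    )
    def test_root_selection_feasible_and_satisfies_mass_action(self, K_N, N1_0, B2_0):
        """The selected root lies in [0, min(N1_0, B2_0)] and satisfies the
        net-reaction mass action law; the rejected branch is infeasible."""
        x = ideal_yield(K_N, N1_0, B2_0).N2_mM
        upper = min(N1_0, B2_0)
        assert 0.0 <= x <= upper * (1 + 1e-12)
        lhs = x * x
        rhs = K_N * (N1_0 - x) * (B2_0 - x)
        assert lhs == pytest.approx(rhs, rel=1e-6, abs=1e-12)
        if abs(K_N - 1.0) > 1e-6:
            # the other quadratic root always violates feasibility
            s = N1_0 + B2_0
            disc = K_N * (K_N * (N1_0 - B2_0) ** 2 + 4 * N1_0 * B2_0)
            other = (K_N * s + math.sqrt(disc)) / (2 * (K_N - 1.0))
            if not math.isclose(other, x, rel_tol=1e-9):
                assert other < -1e-12 or other > upper * (1 + 1e-9)


class TestDomainTypes:
    def test_entry_requires_positive_constant(self):
        with pytest.raises(DomainError):
            PhosphorolysisEntry(species_id="uridine", K=0.0)
        with pytest.raises(DomainError):
            PhosphorolysisEntry(species_id="", K=0.1)

    def test_system_requires_positive_acceptor(self):
        with pytest.raises(DomainError):
            TransglycosylationSystem(K1=0.1, K2=0.1, N1_0=1.0, B2_0=0.0, P_0=1.0)

    def test_system_rejects_negative_concentrations(self):
        with pytest.raises(DomainError):
            TransglycosylationSystem(K1=0.1, K2=0.1, N1_0=-1.0, B2_0=0.5, P_0=1.0)


class TestSolveEquilibrium:
    def test_known_high_k2_condition(self, uridine_ethynyluracil_system):
        # frozen from the nested grid-refinement oracle (tests/conftest.py)
        state = solve_equilibrium(uridine_ethynyluracil_system)
        assert state.N2 == pytest.approx(0.11694, abs=1e-4)
        assert state.yield_fraction == pytest.approx(0.23388, abs=2e-4)

    def test_known_low_k2_condition(self, uridine_adenine_system):
        state = solve_equilibrium(uridine_adenine_system)
        assert state.N2 == pytest.approx(0.43036, abs=1e-4)
        assert state.yield_fraction == pytest.approx(0.86072, abs=2e-4)

    def test_phosphorus_free_system_is_frozen(self):
        sys_ = TransglycosylationSystem(K1=0.16, K2=0.35, N1_0=1.0, B2_0=0.5, P_0=0.0)
        state = solve_equilibrium(sys_)
        assert (state.N1, state.B2, state.N2, state.yield_fraction) == (1.0, 0.5, 0.0, 0.0)

    def test_vanishing_phosphate_approaches_ideal_yield(self):
        sys_ = TransglycosylationSystem(K1=0.16, K2=0.35, N1_0=1.0, B2_0=0.5, P_0=1e-9)
        state = solve_equilibrium(sys_)
        ideal = ideal_yield(sys_.K_N, 1.0, 0.5).yield_fraction
        assert state.yield_fraction == pytest.approx(ideal, abs=1e-6)

    def test_negligible_acceptor_reduces_to_single_phosphorolysis(self):
        # with essentially no acceptor base, only the donor phosphorolysis
        # runs: xi^2 = K1 (N1_0 - xi)(P_0 - xi), xi = sqrt(K)/(1+sqrt(K))
        sys_ = TransglycosylationSystem(
            K1=0.16, K2=0.35, N1_0=1.0, B2_0=1e-12, P_0=1.0
        )
        state = solve_equilibrium(sys_)
        assert state.B1 == pytest.approx(2.0 / 7.0, abs=1e-9)
        assert state.N1 == pytest.approx(5.0 / 7.0, abs=1e-9)

    def test_preloaded_intermediate_and_product_conserve_pools(self):
        sys_ = TransglycosylationSystem(
            K1=0.3, K2=0.2, N1_0=1.0, B2_0=0.5, P_0=1.0,
            B1_0=0.2, N2_0=0.4, P1P_0=0.1,
        )
        st_ = solve_equilibrium(sys_)
        assert st_.N1 + st_.B1 == pytest.approx(sys_.N1_0 + sys_.B1_0, abs=1e-12)
        assert st_.N2 + st_.B2 == pytest.approx(sys_.N2_0 + sys_.B2_0, abs=1e-12)
        assert st_.N1 + st_.N2 + st_.P1P == pytest.approx(
            sys_.N1_0 + sys_.N2_0 + sys_.P1P_0, abs=1e-12
        )
        assert st_.P + st_.P1P == pytest.approx(sys_.P_0 + sys_.P1P_0, abs=1e-12)

    def test_rejects_nonpositive_tolerance(self, uridine_adenine_system):
        with pytest.raises(DomainError):
            solve_equilibrium(uridine_adenine_system, tol=0.0)


class TestYieldVsPhosphate:
    def test_ladder_matches_single_solves(self):
        pred = yield_vs_phosphate(0.16, 0.35, 1.0, 0.5, [0.2, 1.0, 10.0])
        # frozen from the grid-refinement oracle at each level
        expected = [0.52656, 0.46248, 0.23388]
        got = [y for _, y in pred.yields_at_phosphate]
        assert got == pytest.approx(expected, abs=2e-4)
        assert pred.ideal_yield == pytest.approx(0.54786, abs=1e-4)

    def test_empty_ladder(self):
        pred = yield_vs_phosphate(0.16, 0.01, 1.0, 0.5, [])
        assert pred.yields_at_phosphate == ()
        assert pred.ideal_yield == pytest.approx(0.94680, abs=1e-4)

    def test_zero_equivalents_reports_catalytic_limit(self):
        pred = yield_vs_phosphate(0.16, 0.35, 1.0, 0.5, [0.0])
        assert pred.yields_at_phosphate[0][1] == pred.ideal_yield

    def test_yields_nonincreasing_in_phosphate_and_below_ideal(self):
        equivs = [0.0, 0.1, 0.3, 1.0, 3.0, 10.0, 30.0]
        pred = yield_vs_phosphate(0.7, 0.2, 2.0, 1.0, equivs)
        ys = [y for _, y in pred.yields_at_phosphate]
        assert all(a >= b - 1e-12 for a, b in zip(ys, ys[1:]))
        assert all(y <= pred.ideal_yield + 1e-12 for y in ys)


class TestPhosphateGap:
    def test_zero_phosphate_zero_gap(self):
        assert phosphate_gap(0.16, 0.35, 1.0, 0.5, 0.0) == 0.0

    def test_high_k2_product_suffers_large_gap(self):
        gap = phosphate_gap(0.16, 0.35, 1.0, 0.5, 10.0)
        assert gap == pytest.approx(31.4, abs=0.2)

    def test_low_k2_product_tolerates_phosphate(self):
        gap = phosphate_gap(0.16, 0.01, 1.0, 0.5, 10.0)
        assert gap == pytest.approx(8.6, abs=0.2)


def test_yield_monotone_in_donor_and_kn():
    """More donor, or a larger net constant at fixed K2, never hurts yield."""
    ys = [
        solve_equilibrium(
            TransglycosylationSystem(K1=0.16, K2=0.35, N1_0=n1, B2_0=0.5, P_0=0.5)
        ).yield_fraction
        for n1 in np.linspace(0.1, 5.0, 12)
    ]
    assert all(a <= b + 1e-10 for a, b in zip(ys, ys[1:]))
    ys = [
        solve_equilibrium(
            TransglycosylationSystem(K1=k1, K2=0.35, N1_0=1.0, B2_0=0.5, P_0=0.5)
        ).yield_fraction
        for k1 in np.geomspace(0.01, 10.0, 12)
    ]
    assert all(a <= b + 1e-10 for a, b in zip(ys, ys[1:]))
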