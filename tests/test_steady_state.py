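"""Stationary solutions, approximation branches and the titration threshold."""

import numpy as np
import pytest
import sympy
from hypothesis import given, settings, strategies as st

import cole2sim as c
from cole2sim.steady_state import ZERO_REPORT_CUTOFF, _cubic_coefficients


def _sympy_stationary_solutions(p: c.RegulationParameters):
    """Independent oracle: solve the un-eliminated 3-equation system exactly."""
    M, A, S = sympy.symbols("M A S", real=True)
    R = lambda x: sympy.Rational(str(x))
    eqs = [
        R(p.alpha_M) - R(p.delta_M) * M - R(p.k_M) * M * A,
        R(p.alpha_A) - R(p.delta_A) * A
        - R(p.k_M) * R(p.p_M) * M * A - R(p.k_S) * R(p.p_S) * A * S,
        R(p.N * p.alpha_S) - R(p.delta_S) * S - R(p.k_S) * A * S,
    ]
    sols = sympy.solve(eqs, [M, A, S], dict=True)
    out = []
    for s in sols:
        vals = [complex(v) for v in (s[M], s[A], s[S])]
        if all(abs(v.imag) < 1e-9 and v.real >= -1e-9 for v in vals):
            out.append(np.array([v.real for v in vals]))
    return out


class TestSteadyStateExact:
    def test_decoupled_limit(self):
        p = c.RegulationParameters(k_M=0.0, k_S=0.0)
        st_ = c.steady_state_exact(p)
        assert np.allclose(
            st_.as_array(),
            [p.alpha_M / p.delta_M, p.alpha_A / p.delta_A, p.N * p.alpha_S / p.delta_S],
        )

    def test_no_targets_leaves_free_csra_only(self):
        p = c.RegulationParameters(alpha_M=0.0, alpha_S=0.0)
        st_ = c.steady_state_exact(p)
        assert st_.M_star == pytest.approx(0.0, abs=1e-12)
        assert st_.S_star == pytest.approx(0.0, abs=1e-12)
        assert st_.A_star == pytest.approx(p.alpha_A / p.delta_A)

    @pytest.mark.parametrize("alpha_M,s_eff", [(10.0, 20.0), (30.0, 20.0),
                                               (30.0, 40.0), (50.0, 40.0)])
    def test_matches_polynomial_system_oracle(self, alpha_M, s_eff):
        p = c.RegulationParameters(alpha_M=alpha_M).with_srna_production(s_eff)
        oracle = _sympy_stationary_solutions(p)
        assert len(oracle) == 1, "stationary state should be unique"
        got = c.steady_state_exact(p).as_array()
        assert np.allclose(got, oracle[0], rtol=1e-6, atol=1e-9)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        alpha_M=st.floats(0, 80), s_eff=st.floats(0, 80),
        alpha_A=st.floats(0.1, 80), delta_A=st.floats(1e-4, 0.2),
    )
    def test_residuals_vanish_at_returned_state(self, alpha_M, s_eff, alpha_A, delta_A):
        p = c.RegulationParameters(
            alpha_M=alpha_M, alpha_A=alpha_A, delta_A=delta_A
        ).with_srna_production(s_eff)
        st_ = c.steady_state_exact(p)
        resid = np.abs(c.reduced_derivatives(tuple(st_.as_array()), p))
        scale = max(p.alpha_M, p.alpha_A, p.srna_production, 1.0)
        assert resid.max() < 1e-6 * scale
        assert min(st_.as_array()) >= 0.0


class TestSteadyStateApprox:
    def test_deep_sub_threshold_keeps_only_free_csra(self):
        p = c.RegulationParameters(alpha_M=1.0).with_srna_production(5.0)
        st_ = c.steady_state_approx(p)
        assert st_.branch == "high_abundance_approx"
        assert st_.regime == "sub_threshold"
        assert st_.M_star < ZERO_REPORT_CUTOFF
        assert st_.S_star < ZERO_REPORT_CUTOFF
        # CsrA near its unregulated balance (production minus titration flux)
        expected_A = (p.alpha_A - p.alpha_M - p.srna_production) / p.delta_A
        assert st_.A_star == pytest.approx(expected_A, rel=0.05)

    @pytest.mark.parametrize("s_eff", [20.0, 40.0])
    def test_agrees_with_cubic_away_from_threshold(self, s_eff):
        base = c.RegulationParameters().with_srna_production(s_eff)
        locus = c.threshold_condition(base).locus_alpha_M(s_eff)
        for alpha_M in np.linspace(1.0, 70.0, 40):
            if abs(alpha_M - locus) <= 2.0:
                continue
            p = base.replace(alpha_M=float(alpha_M))
            ex = c.steady_state_exact(p).as_array()
            ap = c.steady_state_approx(p).as_array()
            mask = ex > 1e-6
            assert np.all(np.abs(ap[mask] - ex[mask]) / ex[mask] < 0.05)

    def test_branches_cross_where_omitted_terms_balance(self):
        """On the transition line both quadratics err only by the omitted term."""
        base = c.RegulationParameters().with_srna_production(20.0)
        surf = c.phase_surface(np.linspace(30.0, 50.0, 5), np.array([19.0, 20.0]),
                               base)
        a_trans = surf.transition_alpha_M[1]
        assert np.isfinite(a_trans)
        p = base.replace(alpha_M=float(a_trans))
        c3, c2, c1, c0 = _cubic_coefficients(p)
        A_ex = c.steady_state_exact(p).A_star
        # at the crossing the two omitted terms have comparable magnitude
        assert abs(abs(c3) * A_ex**3 - abs(c0)) < 5.0 * max(abs(c0), 1e-12)
        # and the selected branch's error is bounded by the omitted term scale
        A_ap = c.steady_state_approx(p).A_star
        cubic = lambda A: ((c3 * A + c2) * A + c1) * A + c0
        assert abs(cubic(A_ap)) <= 2.0 * (abs(c3) * A_ap**3 + abs(c0))

    def test_degenerate_uncoupled_parameters_fall_back_to_exact(self):
        p = c.RegulationParameters(k_M=0.0, k_S=0.0)
        st_ = c.steady_state_approx(p)
        assert np.allclose(st_.as_array(), c.steady_state_exact(p).as_array())


class TestThreshold:
    def test_printed_operating_point_is_sub_threshold(self):
        """alpha_A = 58.52 with effective sRNA production 57.5 and no mRNA."""
        p = c.RegulationParameters(alpha_M=0.0)
        assert p.alpha_A == 58.52
        assert p.srna_production == pytest.approx(57.5)
        assert not c.threshold_condition(p).super_threshold

    def test_doubled_production_is_super_threshold(self):
        p = c.RegulationParameters(alpha_M=0.0)
        p = p.replace(alpha_M=2.0 * p.alpha_A - p.srna_production)
        assert c.threshold_condition(p).super_threshold

    def test_exact_solution_crosses_half_molecule_near_locus(self):
        """Cubic-root oracle scan: M* jumps through 0.5 in a narrow band."""
        base = c.RegulationParameters()
        for s_eff in (20.0, 40.0):
            locus = float(c.threshold_condition(base).locus_alpha_M(s_eff))
            p = base.with_srna_production(s_eff)
            below = c.steady_state_exact(p.replace(alpha_M=locus - 1.0)).M_star
            above = c.steady_state_exact(p.replace(alpha_M=locus + 1.0)).M_star
            assert below < 0.5 < above

    def test_locus_reduces_to_production_balance_for_certain_coremoval(self):
        p = c.RegulationParameters(p_M=1.0, p_S=1.0)
        thr = c.threshold_condition(p)
        s_grid = np.array([10.0, 30.0, 57.5])
        assert np.allclose(thr.locus_alpha_M(s_grid), p.alpha_A - s_grid)


class TestPhaseSurface:
    @pytest.fixture(scope="class")
    def surface(self):
        grid = np.linspace(2.0, 80.0, 14)
        return c.phase_surface(grid, grid, c.RegulationParameters())

    def test_mutual_exclusion_away_from_threshold(self, surface):
        thr = surface.threshold_alpha_M[None, :]
        dist = np.abs(surface.alpha_M_grid[:, None] - thr)
        away = dist > 3.0
        joint_min = np.minimum(surface.M, surface.A)
        assert joint_min[away].max() < 1.0

    def test_mrna_monotone_in_both_production_rates(self, surface):
        assert np.all(np.diff(surface.M, axis=0) >= -1e-8)
        assert np.all(np.diff(surface.M, axis=1) >= -1e-8)

    def test_free_csra_non_increasing_in_both_axes(self, surface):
        assert np.all(np.diff(surface.A, axis=0) <= 1e-8)
        assert np.all(np.diff(surface.A, axis=1) <= 1e-8)

    def test_zero_reporting_convention(self, surface):
        rep = surface.reported("M")
        assert np.all(rep[surface.M < ZERO_REPORT_CUTOFF] == 0.0)
        assert np.all(rep[surface.M >= ZERO_REPORT_CUTOFF]
                      == surface.M[surface.M >= ZERO_REPORT_CUTOFF])

    def test_csra_declines_as_mrna_production_rises(self, surface):
        # anti-correlation structure across the plane
        dM = np.diff(surface.M, axis=0)
        dA = np.diff(surface.A, axis=0)
        assert np.all(dM * dA <= 1e-8)

    def test_invalid_grids_rejected(self):
        p = c.RegulationParameters()
        with pytest.raises(ValueError):
            c.phase_surface([3.0, 2.0], [1.0, 2.0], p)
        with pytest.raises(ValueError):
            c.phase_surface([1.0, 2.0], [1.0, 2.0], p, method="magic")
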