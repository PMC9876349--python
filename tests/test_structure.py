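"""Oxygen/waste fields, structure relations and snapshot estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import solve_banded

from spheroidox.structure import (
    OxygenParams,
    Phase,
    SpheroidStructure,
    WasteParams,
    alpha_from_critical_radius,
    classify_phase,
    critical_radius_from_constants,
    inhibited_radius_algebraic,
    necrotic_radius_algebraic,
    oxygen_profile,
    percent_to_mmhg,
    predict_hypoxic_radius,
    snapshot_estimate,
    waste_profile,
)
from conftest import bisect


def fd_field(R_o, R_n, source, boundary_value, n=10_000):
    """Finite-difference solution of u'' + (2/r) u' = source on [R_n, R_o].

    No-flux at the inner boundary (ghost node; at r = 0 the symmetric limit
    is 3 u'' = source), Dirichlet u(R_o) = boundary_value; uniform grid.
    Independent oracle for the closed-form radial profiles.
    """
    r = np.linspace(R_n, R_o, n)
    h = r[1] - r[0]
    ab = np.zeros((3, n))   # banded (upper, diag, lower)
    rhs = np.full(n, source)
    idx = np.arange(1, n - 1)
    ab[0, idx + 1] = 1.0 / h**2 + 1.0 / (r[idx] * h)   # upper diagonal
    ab[1, idx] = -2.0 / h**2                           # main diagonal
    ab[2, idx - 1] = 1.0 / h**2 - 1.0 / (r[idx] * h)   # lower diagonal
    # inner no-flux row: (2 u_1 - 2 u_0)/h^2 = source (or source/3 at r = 0)
    ab[1, 0] = -2.0 / h**2
    ab[0, 1] = 2.0 / h**2
    rhs[0] = source / 3.0 if R_n == 0.0 else source
    # outer Dirichlet row
    ab[1, -1] = 1.0
    ab[2, -2] = 0.0
    rhs[-1] = boundary_value
    u = solve_banded((1, 1), ab, rhs)
    return r, u


class TestProfiles:
    def test_surface_pressure_is_ambient(self):
        oxy = OxygenParams(p_inf=21.0, grad_coeff=3e-4)
        assert oxygen_profile(200.0, 200.0, 0.0, oxy) == pytest.approx(21.0)

    def test_centre_pressure_vanishes_at_critical_radius(self):
        oxy = OxygenParams.from_critical_radius(p_inf=21.0, R_c=200.0)
        assert oxygen_profile(0.0, 200.0, 0.0, oxy) == pytest.approx(0.0, abs=1e-12)

    def test_core_boundary_pressure_zero_for_consistent_core(self):
        oxy = OxygenParams.from_critical_radius(p_inf=21.0, R_c=100.0)
        R_o = 141.42
        R_n = necrotic_radius_algebraic(R_o, oxy.R_c)
        assert oxygen_profile(R_n, R_o, R_n, oxy) == pytest.approx(0.0, abs=1e-9)
        # pressure is p_n = 0 throughout the core
        assert oxygen_profile(0.5 * R_n, R_o, R_n, oxy) == 0.0

    @pytest.mark.parametrize("R_o,R_n", [(141.42, 50.0), (300.0, 120.0), (250.0, 0.0)])
    def test_oxygen_profile_matches_finite_difference_oracle(self, R_o, R_n):
        oxy = OxygenParams(p_inf=21.0, grad_coeff=21.0 / 260.0**2)
        r, p_fd = fd_field(R_o, R_n, 6.0 * oxy.grad_coeff, oxy.p_inf)
        p = oxygen_profile(np.maximum(r, R_n), R_o, R_n, oxy)
        keep = p > 1e-6  # the closed form clips negative pressures at zero
        assert np.allclose(p[keep], p_fd[keep], rtol=1e-4)

    @pytest.mark.parametrize("R_o,R_n", [(100.0, 0.0), (220.0, 80.0)])
    def test_waste_profile_matches_finite_difference_oracle(self, R_o, R_n):
        waste = WasteParams(prod_coeff=1e-3, beta_i=10.0)
        r, b_fd = fd_field(R_o, R_n, -6.0 * waste.prod_coeff, 0.0)
        b = waste_profile(np.maximum(r, R_n), R_o, R_n, waste)
        assert np.allclose(b, b_fd, rtol=1e-4, atol=1e-9)

    def test_waste_profile_trivials(self):
        waste = WasteParams(prod_coeff=1e-3, beta_i=1.0)
        assert waste_profile(100.0, 100.0, 0.0, waste) == pytest.approx(0.0, abs=1e-12)
        assert waste_profile(0.0, 100.0, 0.0, waste) == pytest.approx(10.0)

    @given(st.floats(50.0, 400.0), st.floats(0.0, 0.9), st.integers(0, 10**6))
    @settings(max_examples=50, deadline=None, derandomize=True,
              database=None)
    def test_profile_monotonicity(self, R_o, xi_n, seed):
        R_n = xi_n * R_o
        oxy = OxygenParams(p_inf=21.0, grad_coeff=10 ** (-4 + (seed % 17) / 8.0))
        waste = WasteParams(prod_coeff=10 ** (-4 + (seed % 13) / 6.0), beta_i=1.0)
        r = np.linspace(R_n, R_o, 200)
        p = oxygen_profile(r, R_o, R_n, oxy)
        b = waste_profile(r, R_o, R_n, waste)
        assert np.all(np.diff(p) >= -1e-9)
        assert np.all(np.diff(b) <= 1e-9)
        assert p[-1] == pytest.approx(oxy.p_inf)

    def test_invalid_radial_arguments_raise(self):
        oxy = OxygenParams(p_inf=21.0, grad_coeff=3e-4)
        with pytest.raises(ValueError):
            oxygen_profile(250.0, 200.0, 0.0, oxy)
        with pytest.raises(ValueError):
            oxygen_profile(-1.0, 200.0, 0.0, oxy)
        with pytest.raises(ValueError):
            oxygen_profile(50.0, 200.0, 220.0, oxy)


class TestAlgebraicInversions:
    def test_subcritical_spheroid_has_no_core(self):
        assert necrotic_radius_algebraic(100.0, 120.0) == 0.0

    def test_half_radius_special_case(self):
        # at R_n = R_o/2 the core relation gives R_c^2 = R_o^2/2
        R_o = 141.4214
        assert necrotic_radius_algebraic(R_o, 100.0) == pytest.approx(
            70.7107, abs=1e-3)

    def test_pythagorean_inhibited_radius(self):
        assert inhibited_radius_algebraic(250.0, 0.0, 150.0) == pytest.approx(200.0)

    def test_inhibited_radius_before_formation(self):
        assert inhibited_radius_algebraic(100.0, 0.0, 150.0) == 0.0

    def test_inversions_match_bisection_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            R_o = rng.uniform(60.0, 500.0)
            R_c = rng.uniform(40.0, R_o)
            R_n = necrotic_radius_algebraic(R_o, R_c)
            res = R_o**2 - 3 * R_n**2 + 2 * R_n**3 / R_o - R_c**2
            assert abs(res) < 1e-6
            ref = bisect(lambda x: R_o**2 - 3 * x**2 + 2 * x**3 / R_o - R_c**2,
                         0.0, R_o)
            assert R_n == pytest.approx(ref, abs=1e-6)

            Rbar = rng.uniform(0.5 * R_c, R_c)
            R_i = inhibited_radius_algebraic(R_o, R_n, Rbar)
            if R_i > 0 and R_i > R_n:
                resid = R_o**2 - R_i**2 - 2 * R_n**3 * (1 / R_i - 1 / R_o) - Rbar**2
                assert abs(resid) < 1e-6
                ref_i = bisect(
                    lambda x: R_o**2 - x**2 - 2 * R_n**3 * (1 / x - 1 / R_o) - Rbar**2,
                    max(R_n, 1e-9), R_o)
                assert R_i == pytest.approx(ref_i, abs=1e-6)

    def test_nonfinite_inputs_raise(self):
        with pytest.raises(ValueError):
            necrotic_radius_algebraic(np.nan, 100.0)
        with pytest.raises(ValueError):
            inhibited_radius_algebraic(100.0, np.inf, 50.0)


class TestUnitConversions:
    def test_critical_radius_hand_arithmetic(self):
        # sqrt(6 * 2e-9 * 100 / (1e-7 * 3e7)) m = 632.46 um
        assert critical_radius_from_constants(2e-9, 1e-7, 3e7, 100.0) == pytest.approx(
            632.4555, abs=1e-3)

    def test_pressure_scaling_law(self):
        r1 = critical_radius_from_constants(2e-9, 1e-7, 3e7, 100.0)
        r2 = critical_radius_from_constants(2e-9, 1e-7, 3e7, 200.0)
        assert r2 / r1 == pytest.approx(math.sqrt(2.0), rel=1e-12)

    def test_alpha_roundtrip_identity(self):
        k, alpha, Omega, p = 2e-9, 1e-7, 3e7, percent_to_mmhg(21.0)
        R_c = critical_radius_from_constants(k, alpha, Omega, p)
        assert alpha_from_critical_radius(k, R_c, Omega, p) == pytest.approx(
            alpha, rel=1e-12)

    def test_invalid_constants_raise(self):
        with pytest.raises(ValueError):
            critical_radius_from_constants(0.0, 1e-7, 3e7, 100.0)


class TestPhasesAndSnapshots:
    @pytest.mark.parametrize("kw,expected", [
        (dict(R_o=100.0), Phase.I),
        (dict(R_o=300.0, R_i=120.0), Phase.II),
        (dict(R_o=400.0, R_n=90.0, R_i=200.0), Phase.III),
    ])
    def test_phase_classification(self, kw, expected):
        assert classify_phase(SpheroidStructure(**kw)) is expected

    def test_fraction_invariants(self):
        st_ = SpheroidStructure(R_o=400.0, R_n=90.0, R_i=200.0, R_p=150.0)
        for xi in (st_.xi_n, st_.xi_i, st_.xi_p):
            assert 0.0 <= xi <= 1.0

    def test_snapshot_inverts_forward_construction(self):
        """Forward-construct phase-(ii)/(iii) structures and invert exactly."""
        for R_c, Rbar, R_o in [(250.0, 175.0, 320.0), (150.0, 140.0, 200.0),
                               (250.0, 175.0, 220.0)]:
            R_n = necrotic_radius_algebraic(R_o, R_c)
            R_i = inhibited_radius_algebraic(R_o, R_n, Rbar)
            est = snapshot_estimate(SpheroidStructure(R_o=R_o, R_n=R_n, R_i=R_i))
            if R_n > 0:
                assert est.R_c == pytest.approx(R_c, rel=1e-9)
            if R_i > 0:
                assert est.Rbar == pytest.approx(Rbar, rel=1e-9)

    def test_snapshot_on_phase_one_is_flagged_not_raised(self):
        est = snapshot_estimate(SpheroidStructure(R_o=100.0))
        assert not est.estimable_oxygen and not est.estimable_waste
        assert math.isnan(est.R_c) and math.isnan(est.Rbar)

    def test_inhibition_pressure_at_surface_is_ambient(self):
        oxy = OxygenParams.from_critical_radius(p_inf=21.0, R_c=250.0)
        est = snapshot_estimate(
            SpheroidStructure(R_o=200.0, R_n=0.0, R_i=200.0), oxy=oxy)
        assert est.p_i == pytest.approx(21.0)

    def test_noisy_snapshot_estimates_recover_critical_radius(self):
        """Monte-Carlo: median estimated R_c within 5% of truth at sigma=2um."""
        rng = np.random.default_rng(42)
        R_c_true, Rbar_true = 250.0, 175.0
        estimates = []
        for _ in range(100):
            R_o = rng.uniform(280.0, 380.0)
            R_n = necrotic_radius_algebraic(R_o, R_c_true)
            R_i = inhibited_radius_algebraic(R_o, R_n, Rbar_true)
            st_ = SpheroidStructure(
                R_o=R_o + 2.0 * rng.standard_normal(),
                R_n=max(R_n + 2.0 * rng.standard_normal(), 0.0),
                R_i=max(R_i + 2.0 * rng.standard_normal(), 0.0))
            est = snapshot_estimate(st_)
            if est.estimable_oxygen:
                estimates.append(est.R_c)
        assert abs(np.median(estimates) - R_c_true) / R_c_true < 0.05

    def test_measured_inversion_clipping_warns(self):
        st_ = SpheroidStructure(R_o=300.0, R_n=100.0, R_i=80.0)
        with pytest.warns(UserWarning, match="clipping"):
            assert st_.inhibited_radius_clipped() == 100.0


class TestHypoxicRadius:
    def setup_method(self):
        self.oxy = OxygenParams.from_critical_radius(p_inf=21.0, R_c=250.0)

    def test_threshold_at_ambient_returns_outer_radius(self):
        assert predict_hypoxic_radius(300.0, 50.0, self.oxy, 21.0) == pytest.approx(300.0)

    def test_zero_threshold_collapses_to_necrotic_boundary(self):
        R_o = 300.0
        R_n = necrotic_radius_algebraic(R_o, self.oxy.R_c)
        assert predict_hypoxic_radius(R_o, R_n, self.oxy, 0.0) == pytest.approx(
            R_n, abs=1e-6)

    def test_intermediate_threshold_matches_bisection(self):
        R_o = 320.0
        R_n = necrotic_radius_algebraic(R_o, self.oxy.R_c)
        p_hyp = 5.0
        rp = predict_hypoxic_radius(R_o, R_n, self.oxy, p_hyp)
        ref = bisect(lambda r: oxygen_profile(r, R_o, R_n, self.oxy) - p_hyp,
                     R_n, R_o, tol=1e-10)
        assert rp == pytest.approx(ref, abs=1e-6)

    def test_threshold_above_ambient_warns_and_returns_outer(self):
        with pytest.warns(UserWarning):
            assert predict_hypoxic_radius(300.0, 0.0, self.oxy, 30.0) == 300.0
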