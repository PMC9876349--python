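"""Switching models: parameter relaxation, core-volume dynamics, limits."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from spheroidox.adaptation import (
    FOUR_PI_3,
    DeoxygenationParams,
    lambda_hat,
    necrotic_volume_rhs,
    predicted_necrotic_radius,
    relax,
    reoxygenation_outer_rhs,
    solve_deoxygenation,
    solve_reoxygenation,
)
from spheroidox.greenspan import GreenspanParams, solve_greenspan
from spheroidox.structure import necrotic_radius_algebraic
from spheroidox.synthetic import ground_truth_bundle
from conftest import bisect


class TestRelaxation:
    def test_continuity_at_switch(self):
        assert relax(10.0, 4.0, 1.0, 2.0, 2.0) == pytest.approx(10.0)

    def test_long_time_limit(self):
        assert relax(10.0, 4.0, 1.0, 2.0 + 80.0, 2.0) == pytest.approx(4.0)

    def test_direct_substitution(self):
        assert relax(10.0, 4.0, 1.0, 3.0, 2.0) == pytest.approx(
            4.0 + 6.0 / math.e, abs=1e-6)

    def test_pre_switch_time_raises(self):
        with pytest.raises(ValueError):
            relax(10.0, 4.0, 1.0, 1.0, 2.0)

    def test_shell_death_rate(self):
        assert lambda_hat(2.0, 0.5, 1.0, 2.0) == pytest.approx(0.5)
        assert lambda_hat(3.0, 0.5, 1.0, 2.0) == pytest.approx(0.5 * math.e)
        t = np.linspace(2.0, 6.0, 50)
        vals = [lambda_hat(x, 0.5, 1.0, 2.0) for x in t]
        assert all(np.diff(vals) > 0)


class TestPredictedCore:
    def test_subcritical_returns_zero(self):
        assert predicted_necrotic_radius(100.0, 200.0) == 0.0

    def test_quasi_steady_core_jumps_above_dynamic_core_at_deoxygenation(self):
        """Dropping p_inf 21% -> 2% at the switch shrinks R_c(t), so the
        predicted core exceeds the carried-over core for any pre-switch state."""
        params, _ = ground_truth_bundle("deoxy_like")
        for R_o in (160.0, 195.0, 240.0):
            R_n_pre = necrotic_radius_algebraic(R_o, params.R_c_pre)
            R_c_post = math.sqrt(params.p_inf_post / params.a_n)
            assert predicted_necrotic_radius(R_o, R_c_post) > R_n_pre

    def test_matches_bisection(self):
        R_o, R_c = 220.0, 140.0
        ref = bisect(lambda x: R_o**2 - 3 * x**2 + 2 * x**3 / R_o - R_c**2, 0, R_o)
        assert predicted_necrotic_radius(R_o, R_c) == pytest.approx(ref, abs=1e-6)


class TestCoreVolumeOde:
    def test_closed_form_growth(self):
        """lambda = 0, constant lamhat: V(t) = V+ (1 - exp(-3 lamhat t))."""
        lamhat, Rnp = 0.8, 100.0
        Vp = FOUR_PI_3 * Rnp**3
        sol = solve_ivp(lambda t, v: [necrotic_volume_rhs(v[0], Rnp, 0.0, lamhat)],
                        (0, 2), [0.0], rtol=1e-10, atol=1e-6)
        assert sol.y[0, -1] == pytest.approx(Vp * (1 - np.exp(-3 * lamhat * 2)), rel=1e-6)

    def test_fixed_point(self):
        Rnp = 80.0
        Vp = FOUR_PI_3 * Rnp**3
        assert necrotic_volume_rhs(Vp, Rnp, 0.0, 1.3) == pytest.approx(0.0, abs=1e-6)

    def test_negative_volume_raises(self):
        with pytest.raises(ValueError):
            necrotic_volume_rhs(-1.0, 10.0, 0.1, 0.1)


def deoxy_oracle(params, t_end, dt):
    """Independent fixed-step RK4 on the coupled (R_o, V_n) system."""

    def nec(R_o, R_c):
        if R_o <= R_c:
            return 0.0
        return bisect(lambda x: R_o**2 - 3 * x**2 + 2 * x**3 / R_o - R_c**2, 0, R_o,
                      tol=1e-11)

    def inh(R_o, R_n, Rbar):
        if R_o <= Rbar:
            return 0.0
        if R_n <= 0:
            return math.sqrt(R_o**2 - Rbar**2)
        if R_o**2 - 3 * R_n**2 + 2 * R_n**3 / R_o - Rbar**2 < 0:
            return 0.0
        return bisect(
            lambda x: R_o**2 - x**2 - 2 * R_n**3 * (1 / x - 1 / R_o) - Rbar**2,
            R_n, R_o, tol=1e-11)

    p = params
    t_s = p.t_s
    R_c_pre = math.sqrt(p.p_inf_pre / p.a_n)

    def f(t, y):
        R_o, V = y
        if t < t_s:
            R_n = nec(R_o, R_c_pre)
            R_i = inh(R_o, R_n, p.Rbar_n)
            inner = max(R_i**3, R_n**3)
            return [p.s_n / (3 * R_o**2) * (R_o**3 - inner)
                    - p.lam_n * R_n**3 / R_o**2, 0.0]
        ds = t - t_s
        a = p.a_h + (p.a_n - p.a_h) * math.exp(-ds / p.tau_alpha)
        Rbar = p.Rbar_h + (p.Rbar_n - p.Rbar_h) * math.exp(-ds / p.tau_Rbar)
        s = p.s_h + (p.s_n - p.s_h) * math.exp(-ds / p.tau_s)
        lam = p.lam_h + (p.lam_n - p.lam_h) * math.exp(-ds / p.tau_lam)
        lamhat = p.lamhat0 * math.exp(ds / p.tau_lamhat)
        Rnp = nec(R_o, math.sqrt(p.p_inf_post / a))
        Vp = FOUR_PI_3 * Rnp**3
        R_n = (max(V, 0.0) / FOUR_PI_3) ** (1 / 3)
        R_i = inh(R_o, min(R_n, R_o * 0.999999), Rbar)
        inner = max(R_i**3, R_n**3)
        dR = s / (3 * R_o**2) * (R_o**3 - inner) - lam * R_n**3 / R_o**2
        dV = 3 * lamhat * (Vp - V) - 3 * lam * V
        return [dR, dV]

    y = [p.R_o0, 0.0]
    t = 0.0
    steps = int(round(t_end / dt))
    for _ in range(steps):
        k1 = f(t, y)
        k2 = f(t + dt / 2, [y[i] + dt / 2 * k1[i] for i in range(2)])
        k3 = f(t + dt / 2, [y[i] + dt / 2 * k2[i] for i in range(2)])
        k4 = f(t + dt, [y[i] + dt * k3[i] for i in range(2)])
        y = [y[i] + dt / 6 * (k1[i] + 2 * k2[i] + 2 * k3[i] + k4[i]) for i in range(2)]
        t += dt
    return y


@pytest.fixture(scope="module")
def deoxy_preset():
    return ground_truth_bundle("deoxy_like")[0]


@pytest.fixture(scope="module")
def deoxy_trajectory(deoxy_preset):
    return solve_deoxygenation(deoxy_preset, np.linspace(0, 8, 321), dt=0.002)


@pytest.fixture(scope="module")
def reoxy_preset():
    return ground_truth_bundle("reoxy_like")[0]


class TestDeoxygenation:

    def test_degenerate_switch_reduces_to_constant_model(self):
        """Equal endpoints and matched pressures make the switch a no-op
        (phases i-ii horizon, where the core plays no role)."""
        p = DeoxygenationParams(
            R_o0=100.0, a_n=21.0 / 300**2, a_h=21.0 / 300**2, tau_alpha=0.5,
            Rbar_n=180.0, Rbar_h=180.0, tau_Rbar=0.5, s_n=0.6, s_h=0.6, tau_s=0.5,
            lam_n=0.4, lam_h=0.4, tau_lam=0.5, lamhat0=1e-9, tau_lamhat=1.0,
            t_s=2.0, p_inf_pre=21.0, p_inf_post=21.0)
        t = np.linspace(0, 5, 51)
        sw = solve_deoxygenation(p, t, dt=0.002)
        ref = solve_greenspan(
            GreenspanParams.from_radii(R_o0=100.0, s=0.6, R_c=300.0, Rbar=180.0,
                                       lam=0.4), t)
        assert np.allclose(sw.R_o, ref.R_o, atol=2e-3)
        assert np.allclose(sw.R_i, ref.R_i, atol=2e-3)

    def test_state_continuity_at_switch(self, deoxy_preset, deoxy_trajectory):
        t = deoxy_trajectory.t
        i = np.searchsorted(t, deoxy_preset.t_s)
        assert abs(deoxy_trajectory.R_o[i] - deoxy_trajectory.R_o[i - 1]) < 1.0
        assert abs(deoxy_trajectory.V_n[i] - deoxy_trajectory.V_n[i - 1]) < 1e-6
        # relaxing coefficients start from the pre-switch endpoint values
        assert deoxy_trajectory.s_t[i] == pytest.approx(deoxy_preset.s_n, rel=1e-6)
        assert deoxy_trajectory.lam_t[i] == pytest.approx(deoxy_preset.lam_n, rel=1e-6)
        assert deoxy_trajectory.Rbar_t[i] == pytest.approx(deoxy_preset.Rbar_n, rel=1e-6)

    def test_core_volume_consistency(self, deoxy_trajectory):
        assert np.all(deoxy_trajectory.V_n >= 0.0)
        assert np.allclose(deoxy_trajectory.R_n, (deoxy_trajectory.V_n / FOUR_PI_3) ** (1 / 3),
                           atol=1e-9)

    def test_long_time_limit_recovers_hypoxia_endpoints(self, deoxy_preset):
        """Parameters relax to the h endpoints; the dynamic core converges to
        the quasi-steady one within 0.5 um by t_s + 20 tau_lamhat."""
        t_end = deoxy_preset.t_s + 20 * deoxy_preset.tau_lamhat
        tr = solve_deoxygenation(deoxy_preset, np.linspace(0, t_end, 101), dt=0.002)
        assert tr.s_t[-1] == pytest.approx(deoxy_preset.s_h, rel=1e-2)
        assert tr.lam_t[-1] == pytest.approx(deoxy_preset.lam_h, rel=1e-2)
        assert tr.Rbar_t[-1] == pytest.approx(deoxy_preset.Rbar_h, rel=1e-2)
        assert abs(tr.R_n[-1] - tr.R_n_plus[-1]) < 0.5

    def test_outer_radius_plateau_while_structure_reorganises(self, deoxy_preset, deoxy_trajectory):
        t = deoxy_trajectory.t
        i = np.searchsorted(t, deoxy_preset.t_s)
        rel_change = abs(deoxy_trajectory.R_o[-1] - deoxy_trajectory.R_o[i]) / deoxy_trajectory.R_o[i]
        assert rel_change < 0.15
        assert deoxy_trajectory.xi_n[-1] - deoxy_trajectory.xi_n[i] > 0.2

    def test_late_time_fractions_match_pure_hypoxia_growth(self, deoxy_preset):
        tr = solve_deoxygenation(deoxy_preset, np.linspace(0, 50, 101))
        hyp = solve_greenspan(
            GreenspanParams.from_radii(
                R_o0=100.0, s=deoxy_preset.s_h, R_c=deoxy_preset.R_c_post_limit,
                Rbar=deoxy_preset.Rbar_h, lam=deoxy_preset.lam_h),
            np.linspace(0, 50, 101))
        assert abs(tr.R_n[-1] / tr.R_o[-1] - hyp.R_n[-1] / hyp.R_o[-1]) < 0.02
        assert abs(tr.R_i[-1] / tr.R_o[-1] - hyp.R_i[-1] / hyp.R_o[-1]) < 0.02

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_fixed_step_rk4_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        p = DeoxygenationParams(
            R_o0=rng.uniform(100, 150), a_n=21.0 / rng.uniform(220, 280) ** 2,
            a_h=2.0 / rng.uniform(130, 170) ** 2, tau_alpha=rng.uniform(0.2, 1.0),
            Rbar_n=rng.uniform(160, 190), Rbar_h=rng.uniform(130, 150),
            tau_Rbar=rng.uniform(0.2, 1.0), s_n=rng.uniform(0.4, 0.8),
            s_h=rng.uniform(0.5, 0.9), tau_s=rng.uniform(0.5, 1.5),
            lam_n=rng.uniform(0.2, 0.5), lam_h=rng.uniform(0.5, 1.2),
            tau_lam=rng.uniform(0.5, 1.5), lamhat0=rng.uniform(0.3, 1.0),
            tau_lamhat=rng.uniform(0.8, 2.0), t_s=2.0)
        ref_Ro, ref_V = deoxy_oracle(p, 6.0, 1e-3)
        tr = solve_deoxygenation(p, np.array([0.0, 6.0]), dt=0.002)
        assert tr.R_o[-1] == pytest.approx(ref_Ro, rel=1e-4)
        assert tr.V_n[-1] == pytest.approx(ref_V, rel=2e-3)

    def test_instantaneous_and_frozen_timescale_limits(self, deoxy_preset):
        from dataclasses import replace

        t = np.linspace(0, 8, 81)
        fast = replace(deoxy_preset, tau_alpha=1e-6, tau_Rbar=1e-6, tau_s=1e-6,
                       tau_lam=1e-6)
        tr_fast = solve_deoxygenation(fast, t)
        post = t > deoxy_preset.t_s + 0.1
        assert np.allclose(tr_fast.s_t[post], deoxy_preset.s_h)
        assert np.allclose(tr_fast.Rbar_t[post], deoxy_preset.Rbar_h)
        slow = replace(deoxy_preset, tau_alpha=1e9, tau_Rbar=1e9, tau_s=1e9, tau_lam=1e9)
        tr_slow = solve_deoxygenation(slow, t)
        assert np.allclose(tr_slow.s_t, deoxy_preset.s_n)
        assert np.allclose(tr_slow.Rbar_t, deoxy_preset.Rbar_n)


class TestReoxygenation:
    def test_transient_phase_reversal(self, reoxy_preset):
        """The regression preset walks the growth phases in reverse after the
        switch (iii -> ii -> i) before resuming the usual order."""
        tr = solve_reoxygenation(reoxy_preset, np.linspace(0, 14, 1401))
        seq = tr.phase_sequence()
        values = [p.value for p in seq]
        joined = ",".join(values)
        assert "phase_iii,phase_ii,phase_i,phase_ii,phase_iii" in joined

    def test_core_shrinks_without_recovery_boost(self, reoxy_preset):
        from dataclasses import replace

        p = replace(reoxy_preset, nu=0.0, lamtilde0=30.0)
        tr = solve_reoxygenation(p, np.linspace(0, 6, 601))
        post = tr.t >= p.t_s
        shrinking = post & (tr.R_n > tr.R_n_plus + 1e-9)
        V = tr.V_n[shrinking]
        assert np.all(np.diff(V) <= 1e-9)

    def test_full_recovery_conserves_volume_in_outer_balance(self):
        """With nu = 1 the cleared shell converts necrotic -> living in place:
        the outer-radius balance reduces exactly to its s and lambda terms."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            R_o = rng.uniform(120, 300)
            R_n = rng.uniform(0, 0.8) * R_o
            R_i = rng.uniform(R_n, R_o)
            V_n = FOUR_PI_3 * R_n**3
            V_plus = rng.uniform(0, V_n)
            s, lam, lamt = rng.uniform(0.2, 1.0, 3)
            full = reoxygenation_outer_rhs(R_o, R_i, R_n, V_n, V_plus, s, lam,
                                           lamt, nu=1.0)
            plain = s / (3 * R_o**2) * (R_o**3 - max(R_i**3, R_n**3)) \
                - lam * R_n**3 / R_o**2
            assert full == pytest.approx(plain, rel=1e-12)
            # with nu = 0 the entire cleared shell leaves the spheroid
            none = reoxygenation_outer_rhs(R_o, R_i, R_n, V_n, V_plus, s, lam,
                                           lamt, nu=0.0)
            shell = 3 * lamt * (V_n - V_plus)
            assert plain - none == pytest.approx(shell / (4 * np.pi * R_o**2),
                                                 rel=1e-9)

    def test_nu_bounds_enforced(self, reoxy_preset):
        from dataclasses import replace

        with pytest.raises(ValueError):
            replace(reoxy_preset, nu=1.2)

    def test_core_reformation_after_clearance(self, reoxy_preset):
        tr = solve_reoxygenation(reoxy_preset, np.linspace(0, 14, 701))
        # cleared in the middle, re-formed (algebraic, R_n = R_n_plus) at the end
        mid = (tr.t > 3.0) & (tr.t < 3.5)
        assert np.all(tr.R_n[mid] == 0.0)
        assert tr.R_n[-1] > 0
        assert tr.R_n[-1] == pytest.approx(tr.R_n_plus[-1], abs=1e-6)
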