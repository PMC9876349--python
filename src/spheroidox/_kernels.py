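"""Fixed-step integration kernels for the growth models.

These are the computational hot path: likelihood-based calibration evaluates
the forward model tens of thousands of times, so the solvers here are written
as flat numba-compiled functions.  The reference integration path for the
constant-environment model lives in :mod:`.greenspan` (scipy, adaptive step,
event detection); agreement between the two is asserted in the test suite.

Scheme: the outer radius is advanced with classical RK4; the necrotic-volume
state of the switching models is advanced with an exact exponential step of
its locally linear ODE dV/dt = A(t) - B(t) V (Strang-split around the R_o
step).  The exponential step is unconditionally stable, which matters because
the core-adaptation rates lambda-hat / lambda-tilde grow exponentially after
the oxygen switch and make the volume equation arbitrarily stiff at late
times; in that limit the step lands exactly on the quasi-steady core volume.

Parameter vector layouts (positional, used by the inference module):

greenspan  theta_g = (R_o0, s, R_c, gamma, Q)
deoxy      theta_d = (R_o0, a_n, a_h, tau_a, Rbar_n, Rbar_h, tau_Rbar,
                      s_n, s_h, tau_s, lam_n, lam_h, tau_lam,
                      lamhat0, tau_lamhat)
reoxy      theta_r = (R_o0, R_n0, a_n, a_h, tau_a, Rbar_n, Rbar_h, tau_Rbar,
                      s_n, s_h, tau_s, lam_n, lam_h, tau_lam,
                      lamtilde0, tau_lamtilde, nu)

where a = p_inf / R_c^2 is the lumped oxygen-gradient coefficient, so the
time-varying critical radius is R_c(t) = sqrt(p_inf_current / a(t)).
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


FOUR_PI_3 = 4.0 * math.pi / 3.0
_EXP_CAP = 40.0  # cap on growing-exponential arguments; beyond this the
                 # exponential step is saturated anyway
_RN_FLOOR = 1e-2  # um; a dynamic core below this is reported as absent (the
                  # shrinking core volume decays exponentially and never
                  # reaches exactly zero)


@njit(cache=True)
def necrotic_root(R_o, R_c):
    """Unique R_n in [0, R_o) with R_c^2 = R_o^2 - 3 R_n^2 + 2 R_n^3/R_o.

    Safeguarded Newton (bisection fallback); the residual is monotone
    decreasing in R_n on [0, R_o].
    """
    if R_o <= R_c:
        return 0.0
    lo = 0.0
    hi = R_o
    x = 0.5 * R_o
    for _ in range(200):
        f = R_o * R_o - 3.0 * x * x + 2.0 * x * x * x / R_o - R_c * R_c
        if f > 0.0:
            lo = x
        else:
            hi = x
        df = -6.0 * x + 6.0 * x * x / R_o
        if df != 0.0:
            xn = x - f / df
        else:
            xn = 0.5 * (lo + hi)
        if xn <= lo or xn >= hi:
            xn = 0.5 * (lo + hi)
        if abs(xn - x) < 1e-12 * R_o + 1e-12:
            x = xn
            break
        x = xn
    return x


@njit(cache=True)
def inhibited_root(R_o, R_n, Rbar):
    """Unique R_i in [R_n, R_o) with Rbar^2 = R_o^2 - R_i^2 - 2R_n^3(1/R_i - 1/R_o).

    Returns 0 when the inhibited region has not formed (R_o <= Rbar, or the
    waste maximum at the core boundary is below threshold).
    """
    if R_o <= Rbar:
        return 0.0
    if R_n <= 0.0:
        return math.sqrt(R_o * R_o - Rbar * Rbar)
    g_at_rn = R_o * R_o - 3.0 * R_n * R_n + 2.0 * R_n * R_n * R_n / R_o - Rbar * Rbar
    if g_at_rn < 0.0:
        return 0.0
    lo = R_n
    hi = R_o
    x = 0.5 * (lo + hi)
    rn3 = R_n * R_n * R_n
    for _ in range(200):
        g = R_o * R_o - x * x - 2.0 * rn3 * (1.0 / x - 1.0 / R_o) - Rbar * Rbar
        if g > 0.0:
            lo = x
        else:
            hi = x
        dg = -2.0 * x + 2.0 * rn3 / (x * x)
        if dg != 0.0:
            xn = x - g / dg
        else:
            xn = 0.5 * (lo + hi)
        if xn <= lo or xn >= hi:
            xn = 0.5 * (lo + hi)
        if abs(xn - x) < 1e-12 * R_o + 1e-12:
            x = xn
            break
        x = xn
    return x


@njit(cache=True)
def _greenspan_drdt(R_o, s, lam, R_c, Rbar):
    R_n = necrotic_root(R_o, R_c)
    R_i = inhibited_root(R_o, R_n, Rbar)
    inner = max(R_i * R_i * R_i, R_n * R_n * R_n)
    return s / (3.0 * R_o * R_o) * (R_o * R_o * R_o - inner) \
        - lam * R_n * R_n * R_n / (R_o * R_o)


@njit(cache=True)
def greenspan_radii(theta, t_eval, dt):
    """Integrate the constant-environment model; sample (R_o, R_i, R_n) at t_eval.

    ``t_eval`` must be non-decreasing and start at >= 0; integration starts
    at t = 0 from R_o(0) = theta[0].
    """
    R_o0, s, R_c, gamma, Q = theta[0], theta[1], theta[2], theta[3], theta[4]
    lam = gamma * s
    Rbar = Q * R_c
    n = t_eval.shape[0]
    out = np.empty((3, n))
    t = 0.0
    R = R_o0
    j = 0
    # emit any samples at (or numerically before) the current time
    while j < n and t_eval[j] <= t + 1e-12:
        R_n = necrotic_root(R, R_c)
        out[0, j] = R
        out[1, j] = inhibited_root(R, R_n, Rbar)
        out[2, j] = R_n
        j += 1
    while j < n:
        h = dt
        if t + h > t_eval[j]:
            h = t_eval[j] - t
        k1 = _greenspan_drdt(R, s, lam, R_c, Rbar)
        k2 = _greenspan_drdt(R + 0.5 * h * k1, s, lam, R_c, Rbar)
        k3 = _greenspan_drdt(R + 0.5 * h * k2, s, lam, R_c, Rbar)
        k4 = _greenspan_drdt(R + h * k3, s, lam, R_c, Rbar)
        R = R + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t = t + h
        while j < n and t_eval[j] <= t + 1e-12:
            R_n = necrotic_root(R, R_c)
            out[0, j] = R
            out[1, j] = inhibited_root(R, R_n, Rbar)
            out[2, j] = R_n
            j += 1
    return out


@njit(cache=True)
def _relax(v_from, v_to, tau, dt_since_switch):
    return v_to + (v_from - v_to) * math.exp(-dt_since_switch / tau)


@njit(cache=True)
def _grow_exp(v0, tau, dt_since_switch):
    arg = dt_since_switch / tau
    if arg > _EXP_CAP:
        arg = _EXP_CAP
    return v0 * math.exp(arg)


@njit(cache=True)
def _vn_exp_step(V, A, B, h):
    """Exact step of dV/dt = A - B V over h (B >= 0)."""
    if B * h < 1e-10:
        return V + (A - B * V) * h
    Vinf = A / B
    return Vinf + (V - Vinf) * math.exp(-B * h)


@njit(cache=True)
def switching_trajectory(theta, t_eval, t_s, p_pre, p_post, deoxy, dt):
    """Integrate a deoxygenation (deoxy=True) or re-oxygenation model.

    theta is theta_d (15 entries) when deoxy, else theta_r (17 entries); see
    module docstring.  Returns an (8, n) array with rows
    (R_o, R_i, R_n, R_n_plus, V_n, s_t, lam_t, Rbar_t) at t_eval.

    Pre-switch the constant-environment model runs with the "from"-endpoint
    parameters; R_o and V_n carry over continuously at t_s.  Post-switch the
    coefficients relax exponentially to the "to" endpoints while the core
    volume relaxes toward the quasi-steady volume set by the instantaneous
    oxygen field.  For re-oxygenation the reported core radius is
    max(dynamic, quasi-steady): once clearance completes the model reduces to
    the plain algebraic core.
    """
    if deoxy:
        R_o0 = theta[0]
        a_from, a_to, tau_a = theta[1], theta[2], theta[3]
        Rb_from, Rb_to, tau_Rb = theta[4], theta[5], theta[6]
        s_from, s_to, tau_s = theta[7], theta[8], theta[9]
        l_from, l_to, tau_l = theta[10], theta[11], theta[12]
        rate0, tau_rate = theta[13], theta[14]
        nu = 0.0
        R_n0 = -1.0
    else:
        R_o0 = theta[0]
        R_n0 = theta[1]
        # endpoints stored as (normoxia, hypoxia); re-oxygenation relaxes h -> n
        a_to, a_from, tau_a = theta[2], theta[3], theta[4]
        Rb_to, Rb_from, tau_Rb = theta[5], theta[6], theta[7]
        s_to, s_from, tau_s = theta[8], theta[9], theta[10]
        l_to, l_from, tau_l = theta[11], theta[12], theta[13]
        rate0, tau_rate = theta[14], theta[15]
        nu = theta[16]

    R_c_pre = math.sqrt(p_pre / a_from)
    Rbar_pre = Rb_from

    n = t_eval.shape[0]
    out = np.empty((8, n))
    t = 0.0
    R = R_o0
    V = 0.0
    j = 0

    # ---- pre-switch: plain constant-environment growth ----
    while j < n and t_eval[j] <= min(t, t_s) + 1e-12:
        R_n = necrotic_root(R, R_c_pre)
        out[0, j] = R
        out[1, j] = inhibited_root(R, R_n, Rbar_pre)
        out[2, j] = R_n
        out[3, j] = R_n
        out[4, j] = FOUR_PI_3 * R_n * R_n * R_n
        out[5, j] = s_from
        out[6, j] = l_from
        out[7, j] = Rbar_pre
        j += 1
    while t < t_s - 1e-12:
        h = dt
        if t + h > t_s:
            h = t_s - t
        if j < n and t + h > t_eval[j]:
            h = t_eval[j] - t
        k1 = _greenspan_drdt(R, s_from, l_from, R_c_pre, Rbar_pre)
        k2 = _greenspan_drdt(R + 0.5 * h * k1, s_from, l_from, R_c_pre, Rbar_pre)
        k3 = _greenspan_drdt(R + 0.5 * h * k2, s_from, l_from, R_c_pre, Rbar_pre)
        k4 = _greenspan_drdt(R + h * k3, s_from, l_from, R_c_pre, Rbar_pre)
        R = R + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t = t + h
        while j < n and t_eval[j] <= t + 1e-12 and t_eval[j] < t_s - 1e-12:
            R_n = necrotic_root(R, R_c_pre)
            out[0, j] = R
            out[1, j] = inhibited_root(R, R_n, Rbar_pre)
            out[2, j] = R_n
            out[3, j] = R_n
            out[4, j] = FOUR_PI_3 * R_n * R_n * R_n
            out[5, j] = s_from
            out[6, j] = l_from
            out[7, j] = Rbar_pre
            j += 1
    t = t_s

    # ---- state hand-over at the switch ----
    R_n_ts = necrotic_root(R, R_c_pre)
    if not deoxy and R_n0 >= 0.0:
        if t_s <= 1e-12 or R_n0 > R_n_ts:
            R_n_ts = R_n0
    V = FOUR_PI_3 * R_n_ts * R_n_ts * R_n_ts

    # ---- post-switch ----
    while j < n:
        # emit sample if due at current time
        while j < n and t_eval[j] <= t + 1e-12:
            ds = t - t_s
            a_t = _relax(a_from, a_to, tau_a, ds)
            Rb_t = _relax(Rb_from, Rb_to, tau_Rb, ds)
            s_t = _relax(s_from, s_to, tau_s, ds)
            l_t = _relax(l_from, l_to, tau_l, ds)
            R_c_t = math.sqrt(p_post / a_t)
            Rnp = necrotic_root(R, R_c_t)
            R_n_dyn = (V / FOUR_PI_3) ** (1.0 / 3.0)
            R_n = R_n_dyn if deoxy else max(R_n_dyn, Rnp)
            if R_n < _RN_FLOOR:
                R_n = 0.0
            if R_n > R:
                R_n = R
            out[0, j] = R
            out[1, j] = inhibited_root(R, min(R_n, 0.999999 * R), Rb_t)
            out[2, j] = R_n
            out[3, j] = Rnp
            out[4, j] = FOUR_PI_3 * R_n * R_n * R_n
            out[5, j] = s_t
            out[6, j] = l_t
            out[7, j] = Rb_t
            j += 1
        if j >= n:
            break
        h = dt
        if t + h > t_eval[j]:
            h = t_eval[j] - t

        # coefficients at step start / midpoint / end
        ds0 = t - t_s
        dsm = ds0 + 0.5 * h
        ds1 = ds0 + h
        a_m = _relax(a_from, a_to, tau_a, dsm)
        Rb_m = _relax(Rb_from, Rb_to, tau_Rb, dsm)
        s_m = _relax(s_from, s_to, tau_s, dsm)
        l_m = _relax(l_from, l_to, tau_l, dsm)
        R_c_m = math.sqrt(p_post / a_m)

        # half-step V with start coefficients
        a_0 = _relax(a_from, a_to, tau_a, ds0)
        l_0 = _relax(l_from, l_to, tau_l, ds0)
        rate_0 = _grow_exp(rate0, tau_rate, ds0)
        Rnp0 = necrotic_root(R, math.sqrt(p_post / a_0))
        Vp0 = FOUR_PI_3 * Rnp0 * Rnp0 * Rnp0
        if deoxy:
            A = 3.0 * rate_0 * Vp0
            B = 3.0 * (rate_0 + l_0)
        else:
            if V > Vp0:
                A = 3.0 * rate_0 * Vp0
                B = 3.0 * (rate_0 + l_0)
            else:
                A = 0.0
                B = 3.0 * l_0
        V = _vn_exp_step(V, A, B, 0.5 * h)

        # RK4 on R_o with core held at the half-step volume
        R_n_dyn = (V / FOUR_PI_3) ** (1.0 / 3.0)
        rate_m = _grow_exp(rate0, tau_rate, dsm)
        Rnp_m = necrotic_root(R, R_c_m)
        R_n_eff = R_n_dyn if deoxy else max(R_n_dyn, Rnp_m)
        Vp_m = FOUR_PI_3 * Rnp_m ** 3
        shell = 0.0
        if not deoxy and V > Vp_m:
            shell = 3.0 * rate_m * (V - Vp_m)

        def_drdt_args = (s_m, l_m, Rb_m, R_n_eff, nu, shell)
        k1 = _switch_drdt(R, def_drdt_args)
        k2 = _switch_drdt(R + 0.5 * h * k1, def_drdt_args)
        k3 = _switch_drdt(R + 0.5 * h * k2, def_drdt_args)
        k4 = _switch_drdt(R + h * k3, def_drdt_args)
        R = R + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

        # half-step V with end coefficients and updated R_o
        a_1 = _relax(a_from, a_to, tau_a, ds1)
        l_1 = _relax(l_from, l_to, tau_l, ds1)
        rate_1 = _grow_exp(rate0, tau_rate, ds1)
        Rnp1 = necrotic_root(R, math.sqrt(p_post / a_1))
        Vp1 = FOUR_PI_3 * Rnp1 * Rnp1 * Rnp1
        if deoxy:
            A = 3.0 * rate_1 * Vp1
            B = 3.0 * (rate_1 + l_1)
        else:
            if V > Vp1:
                A = 3.0 * rate_1 * Vp1
                B = 3.0 * (rate_1 + l_1)
            else:
                A = 0.0
                B = 3.0 * l_1
        V = _vn_exp_step(V, A, B, 0.5 * h)
        t = t + h
    return out


@njit(cache=True)
def _switch_drdt(R, args):
    """dR_o/dt for the switching models at frozen core state.

    args = (s_t, lam_t, Rbar_t, R_n_eff, nu, shell) where ``shell`` is the
    instantaneous shell-clearance volume rate 3*lamtilde*(V_n - V_plus)_+ (zero
    for deoxygenation); a fraction nu of it recovers as living volume so only
    (1 - nu) leaves the spheroid.
    """
    s_t, l_t, Rb_t, R_n, nu, shell = args
    if R_n > R:
        R_n = R
    R_i = inhibited_root(R, min(R_n, 0.999999 * R), Rb_t)
    inner = max(R_i * R_i * R_i, R_n * R_n * R_n)
    dr = s_t / (3.0 * R * R) * (R * R * R - inner) - l_t * R_n ** 3 / (R * R)
    dr -= (1.0 - nu) * shell / (4.0 * math.pi * R * R)
    return dr
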