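"""Growth models for an instantaneous switch of external oxygen at t_s.

Deoxygenation (normoxia -> hypoxia): before the switch the spheroid follows
the constant-environment model with the normoxia-endpoint parameters.  At t_s
the external pressure drops and the internal oxygen field re-equilibrates
instantaneously, so the quasi-steady ("predicted") necrotic radius R_n_plus
jumps above the actual core radius.  Cells in the newly anoxic shell
R_n < r < R_n_plus die at a per-volume rate lamhat(t) = lamhat0 *
exp((t - t_s)/tau_lamhat) that grows in time, so the dynamic core relaxes up
to the quasi-steady one.  Meanwhile every bulk parameter v in
{alpha, lambda, s, Rbar} adapts exponentially between its condition
endpoints, v(t) = v_to + (v_from - v_to) exp(-(t - t_s)/tau_v).  The core
volume obeys

    dV_n/dt = 3 lamhat(t) [ (4 pi/3) R_n_plus^3 - V_n ] - 3 lambda(t) V_n,
    R_n(t) = (3 V_n / 4 pi)^(1/3).

Re-oxygenation (hypoxia -> normoxia) is the mirror construction: R_n_plus
drops below R_n at the switch, the re-oxygenated shell R_n_plus < r < R_n is
cleared at rate lamtilde(t) = lamtilde0 * exp((t - t_s)/tau_lamtilde), a
fraction nu of the cleared volume recovers as living cells (and therefore
stays in the spheroid) while (1 - nu) diffuses out, and the bulk parameters
relax hypoxia -> normoxia.  The outer-radius balance becomes

    R_o^2 dR_o/dt = (s(t)/3)[R_o^3 - max(R_i^3, R_n^3)] - lambda(t) R_n^3
                    - (1 - nu) * 3 lamtilde(t) [V_n - V_plus]_+ / (4 pi),

so that with nu = 1 the total volume changes only through the s and lambda
terms while the core is cleared.  Once the shrinking core crosses the
quasi-steady radius the model reduces to the plain algebraic core
(R_n = R_n_plus), which lets the usual growth phases resume — including the
transient reverse sequence iii -> ii -> i -> ii -> iii seen experimentally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels
from .structure import SpheroidStructure, classify_phase, necrotic_radius_algebraic

__all__ = [
    "DeoxygenationParams",
    "ReoxygenationParams",
    "SwitchingTrajectory",
    "relax",
    "lambda_hat",
    "predicted_necrotic_radius",
    "necrotic_volume_rhs",
    "reoxygenation_outer_rhs",
    "solve_deoxygenation",
    "solve_reoxygenation",
]

FOUR_PI_3 = 4.0 * math.pi / 3.0


def relax(v_n: float, v_h: float, tau: float, t: float, t_s: float) -> float:
    """Exponential parameter adaptation v_h + (v_n - v_h) exp(-(t - t_s)/tau).

    ``v_n`` is the pre-switch endpoint (value at t = t_s), ``v_h`` the
    post-switch limit; applied identically to alpha, lambda, s and Rbar.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if t < t_s:
        raise ValueError(f"relax is defined for t >= t_s (got t={t}, t_s={t_s})")
    return v_h + (v_n - v_h) * math.exp(-(t - t_s) / tau)


def lambda_hat(t: float, lambda_hat0: float, tau_lambda_hat: float, t_s: float) -> float:
    """Growing shell-death rate lamhat0 * exp((t - t_s)/tau_lamhat), [1/day].

    Because it grows without bound, the core-volume equation is eventually
    dominated by this term and R_n -> R_n_plus.
    """
    if t < t_s:
        raise ValueError(f"lambda_hat is defined for t >= t_s (got t={t})")
    return lambda_hat0 * math.exp(min((t - t_s) / tau_lambda_hat, _kernels._EXP_CAP))


def predicted_necrotic_radius(R_o: float, R_c_t: float) -> float:
    """Quasi-steady necrotic radius under the instantaneous oxygen field.

    Same inversion as the constant-environment core relation, evaluated with
    the time-varying critical radius R_c(t) = sqrt(p_inf / a(t)).
    """
    return necrotic_radius_algebraic(R_o, R_c_t)


def necrotic_volume_rhs(V_n: float, R_n_plus: float, lambda_t: float,
                        lambda_hat_t: float) -> float:
    """dV_n/dt = 3 lamhat [(4pi/3) R_n_plus^3 - V_n] - 3 lambda V_n (deoxygenation)."""
    if V_n < 0:
        raise ValueError("V_n must be non-negative")
    return 3.0 * lambda_hat_t * (FOUR_PI_3 * R_n_plus**3 - V_n) - 3.0 * lambda_t * V_n


def reoxygenation_outer_rhs(R_o: float, R_i: float, R_n: float, V_n: float,
                            V_plus: float, s_t: float, lambda_t: float,
                            lambda_tilde_t: float, nu: float) -> float:
    """dR_o/dt during re-oxygenation, including the (1 - nu) shell outflow.

    The shell-clearance volume rate is 3 lamtilde (V_n - V_plus)_+; a fraction
    nu of it converts necrotic -> living in place (no change to total volume),
    the remainder leaves the spheroid.
    """
    shell = 3.0 * lambda_tilde_t * max(V_n - V_plus, 0.0)
    inner = max(R_i**3, R_n**3)
    dr = s_t / (3.0 * R_o**2) * (R_o**3 - inner) - lambda_t * R_n**3 / R_o**2
    return dr - (1.0 - nu) * shell / (4.0 * math.pi * R_o**2)


@dataclass(frozen=True)
class DeoxygenationParams:
    """Fifteen free parameters of the deoxygenation model plus the protocol.

    ``a_n``/``a_h`` are the lumped oxygen-gradient coefficients
    a = p_inf / R_c^2 estimated in normoxia / hypoxia (each with its own
    ambient pressure); they play the role of the consumption-rate endpoints.
    The protocol fields (t_s, p_inf_pre, p_inf_post) are fixed by the
    experimental design, not fitted.
    """

    R_o0: float
    a_n: float
    a_h: float
    tau_alpha: float
    Rbar_n: float
    Rbar_h: float
    tau_Rbar: float
    s_n: float
    s_h: float
    tau_s: float
    lam_n: float
    lam_h: float
    tau_lam: float
    lamhat0: float
    tau_lamhat: float
    t_s: float = 2.0
    p_inf_pre: float = 21.0
    p_inf_post: float = 2.0

    def __post_init__(self) -> None:
        free = self.as_array()
        if np.any(free[np.r_[0:13, 14]] <= 0) or self.lamhat0 < 0:
            raise ValueError("rates, radii and timescales must be positive")
        if self.t_s < 0 or self.p_inf_pre <= 0 or self.p_inf_post <= 0:
            raise ValueError("invalid protocol settings")

    @classmethod
    def from_critical_radii(cls, R_c_n: float, R_c_h: float, *, p_inf_pre: float = 21.0,
                            p_inf_post: float = 2.0, **kwargs) -> "DeoxygenationParams":
        """Build endpoints from the critical radii measured in each condition."""
        return cls(a_n=p_inf_pre / R_c_n**2, a_h=p_inf_post / R_c_h**2,
                   p_inf_pre=p_inf_pre, p_inf_post=p_inf_post, **kwargs)

    @property
    def R_c_pre(self) -> float:
        return math.sqrt(self.p_inf_pre / self.a_n)

    @property
    def R_c_post_limit(self) -> float:
        return math.sqrt(self.p_inf_post / self.a_h)

    def as_array(self) -> np.ndarray:
        return np.array([
            self.R_o0, self.a_n, self.a_h, self.tau_alpha,
            self.Rbar_n, self.Rbar_h, self.tau_Rbar,
            self.s_n, self.s_h, self.tau_s,
            self.lam_n, self.lam_h, self.tau_lam,
            self.lamhat0, self.tau_lamhat,
        ])


@dataclass(frozen=True)
class ReoxygenationParams:
    """Seventeen free parameters of the re-oxygenation model plus the protocol.

    Endpoint subscripts keep their condition meaning (n = normoxia,
    h = hypoxia); the relaxations run h -> n here.  ``R_n0`` is the core
    radius at the switch; ``nu`` in [0, 1] is the recovered fraction of the
    cleared shell volume.
    """

    R_o0: float
    R_n0: float
    a_n: float
    a_h: float
    tau_alpha: float
    Rbar_n: float
    Rbar_h: float
    tau_Rbar: float
    s_n: float
    s_h: float
    tau_s: float
    lam_n: float
    lam_h: float
    tau_lam: float
    lamtilde0: float
    tau_lamtilde: float
    nu: float
    t_s: float = 2.0
    p_inf_pre: float = 2.0
    p_inf_post: float = 21.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.nu <= 1.0):
            raise ValueError(f"nu must lie in [0, 1], got {self.nu}")
        if self.R_n0 < 0 or self.R_n0 >= self.R_o0:
            raise ValueError("require 0 <= R_n0 < R_o0")
        positives = [self.R_o0, self.a_n, self.a_h, self.tau_alpha, self.Rbar_n,
                     self.Rbar_h, self.tau_Rbar, self.s_n, self.s_h, self.tau_s,
                     self.lam_n, self.lam_h, self.tau_lam, self.tau_lamtilde]
        if min(positives) <= 0 or self.lamtilde0 < 0:
            raise ValueError("rates, radii and timescales must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([
            self.R_o0, self.R_n0, self.a_n, self.a_h, self.tau_alpha,
            self.Rbar_n, self.Rbar_h, self.tau_Rbar,
            self.s_n, self.s_h, self.tau_s,
            self.lam_n, self.lam_h, self.tau_lam,
            self.lamtilde0, self.tau_lamtilde, self.nu,
        ])


@dataclass
class SwitchingTrajectory:
    """Solution of a switching model, with the core-volume state exposed."""

    t: np.ndarray
    R_o: np.ndarray
    R_i: np.ndarray
    R_n: np.ndarray
    R_n_plus: np.ndarray
    V_n: np.ndarray
    s_t: np.ndarray
    lam_t: np.ndarray
    Rbar_t: np.ndarray
    a_t: np.ndarray
    phase: list
    t_s: float

    @property
    def xi_n(self) -> np.ndarray:
        return self.R_n / self.R_o

    @property
    def xi_i(self) -> np.ndarray:
        return self.R_i / self.R_o

    def phase_sequence(self) -> list:
        """Phases along the trajectory with consecutive duplicates removed."""
        seq: list = []
        for ph in self.phase:
            if not seq or seq[-1] != ph:
                seq.append(ph)
        return seq


def _wrap(theta: np.ndarray, t_grid: np.ndarray, t_s: float, p_pre: float,
          p_post: float, deoxy: bool, dt: float,
          a_from: float, a_to: float, tau_a: float) -> SwitchingTrajectory:
    out = _kernels.switching_trajectory(theta, t_grid, t_s, p_pre, p_post, deoxy, dt)
    a_t = np.where(
        t_grid < t_s, a_from,
        a_to + (a_from - a_to) * np.exp(-np.maximum(t_grid - t_s, 0.0) / tau_a),
    )
    phases = [
        classify_phase(SpheroidStructure(R_o=float(ro), R_n=float(rn), R_i=float(ri)))
        for ro, rn, ri in zip(out[0], np.minimum(out[2], out[0]), np.minimum(out[1], out[0]))
    ]
    return SwitchingTrajectory(
        t=t_grid, R_o=out[0], R_i=out[1], R_n=out[2], R_n_plus=out[3],
        V_n=out[4], s_t=out[5], lam_t=out[6], Rbar_t=out[7], a_t=a_t,
        phase=phases, t_s=t_s,
    )


def solve_deoxygenation(params: DeoxygenationParams, t_grid: Sequence[float],
                        dt: float = 0.005) -> SwitchingTrajectory:
    """Simulate growth through a normoxia -> hypoxia switch at params.t_s.

    Pre-switch the trajectory coincides with the constant-environment model at
    the normoxia endpoints; R_o and V_n carry over continuously at the switch.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D grid")
    if t_grid[-1] <= params.t_s:
        raise ValueError("t_grid must extend beyond the switch time")
    return _wrap(params.as_array(), t_grid, params.t_s, params.p_inf_pre,
                 params.p_inf_post, True, dt, params.a_n, params.a_h,
                 params.tau_alpha)


def solve_reoxygenation(params: ReoxygenationParams, t_grid: Sequence[float],
                        dt: float = 0.005) -> SwitchingTrajectory:
    """Simulate growth through a hypoxia -> normoxia switch at params.t_s."""
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D grid")
    if t_grid[-1] <= params.t_s:
        raise ValueError("t_grid must extend beyond the switch time")
    return _wrap(params.as_array(), t_grid, params.t_s, params.p_inf_pre,
                 params.p_inf_post, False, dt, params.a_h, params.a_n,
                 params.tau_alpha)
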