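"""Greenspan's tumour-spheroid growth model in a constant environment.

The model is a differential-algebraic system: one ODE for the outer radius
driven by volume conservation,

    R_o^2 dR_o/dt = (s/3) [R_o^3 - max(R_i^3, R_n^3)] - lambda R_n^3,

coupled to the two algebraic structure relations of :mod:`.structure` that
pin the necrotic radius R_n (oxygen threshold, critical radius R_c) and the
inhibited radius R_i (waste threshold, formation radius Rbar) to the current
R_o.  ``s`` [1/day] is the volume-production rate of proliferating cells and
``lambda = gamma * s`` [1/day] the volume-loss rate from the necrotic core.

The five-parameter vector is (R_o(0), s, R_c, gamma, Q) with Rbar = Q * R_c.
The DAE is index-reduced: the algebraic constraints have unique roots in the
valid bracket, so they are resolved inside the ODE right-hand side and the
system is integrated as a scalar ODE in R_o with event detection for region
formation.  While both inner regions are absent the model is exactly
exponential, R_o(t) = R_o(0) exp(s t / 3), and the inhibited region forms at
t = (3/s) log(Rbar / R_o(0)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .structure import (
    SpheroidStructure,
    classify_phase,
    inhibited_radius_algebraic,
    necrotic_radius_algebraic,
)

__all__ = ["GreenspanParams", "Trajectory", "greenspan_rhs", "solve_greenspan",
           "inhibited_onset_time"]


@dataclass(frozen=True)
class GreenspanParams:
    """Parameters (R_o(0), s, R_c, gamma, Q); Rbar = Q R_c, lambda = gamma s."""

    R_o0: float
    s: float
    R_c: float
    gamma: float
    Q: float

    def __post_init__(self) -> None:
        if min(self.R_o0, self.s, self.R_c, self.gamma, self.Q) <= 0:
            raise ValueError(f"all Greenspan parameters must be positive: {self}")

    @property
    def lam(self) -> float:
        return self.gamma * self.s

    @property
    def Rbar(self) -> float:
        return self.Q * self.R_c

    @classmethod
    def from_radii(cls, R_o0: float, s: float, R_c: float, Rbar: float,
                   lam: float) -> "GreenspanParams":
        """Bijective reparameterisation in (R_o(0), R_c, Rbar, s, lambda)."""
        return cls(R_o0=R_o0, s=s, R_c=R_c, gamma=lam / s, Q=Rbar / R_c)

    def as_array(self) -> np.ndarray:
        return np.array([self.R_o0, self.s, self.R_c, self.gamma, self.Q])

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "GreenspanParams":
        return cls(*(float(v) for v in theta))


@dataclass
class Trajectory:
    """Model solution on an output grid, radii in um, times in days."""

    t: np.ndarray
    R_o: np.ndarray
    R_i: np.ndarray
    R_n: np.ndarray
    phase: list
    t_inhibited_forms: Optional[float] = None
    t_necrotic_forms: Optional[float] = None

    def structure_at(self, idx: int) -> SpheroidStructure:
        return SpheroidStructure(
            R_o=float(self.R_o[idx]), R_n=float(self.R_n[idx]),
            R_i=float(self.R_i[idx]), t=float(self.t[idx]),
        )


def greenspan_rhs(R_o: float, R_i: float, R_n: float, params: GreenspanParams) -> float:
    """dR_o/dt for a consistent structural state.

    max(R_i^3, R_n^3) is kept literal so regimes with R_n > R_i (possible
    under the oxygen-inhibition interpretation) remain representable.
    """
    if R_o <= 0:
        raise ValueError("R_o must be positive")
    inner = max(R_i**3, R_n**3)
    return params.s / (3.0 * R_o**2) * (R_o**3 - inner) - params.lam * R_n**3 / R_o**2


def _consistent_structure(R_o: float, params: GreenspanParams) -> tuple[float, float]:
    R_n = necrotic_radius_algebraic(R_o, params.R_c)
    R_i = inhibited_radius_algebraic(R_o, R_n, params.Rbar)
    return R_n, R_i


class SolverFailure(RuntimeError):
    """Integration failed; carries the last successfully computed state."""

    def __init__(self, message: str, last_t: float, last_state: dict):
        super().__init__(message)
        self.last_t = last_t
        self.last_state = last_state


def solve_greenspan(
    params: GreenspanParams,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
    initial_structure: Optional[SpheroidStructure] = None,
) -> Trajectory:
    """Integrate the Greenspan DAE over ``t_grid`` (days, starting at 0).

    The algebraic constraints are resolved by root-finding inside the rhs;
    region-formation times are located by ``solve_ivp`` event detection on
    sign changes of R_o - Rbar and R_o - R_c.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 2 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D grid")
    R_start = params.R_o0 if initial_structure is None else initial_structure.R_o

    def rhs(t, y):
        R_o = max(y[0], 1e-6)
        R_n, R_i = _consistent_structure(R_o, params)
        return [greenspan_rhs(R_o, R_i, R_n, params)]

    ev_inhib = lambda t, y: y[0] - params.Rbar
    ev_necro = lambda t, y: y[0] - params.R_c

    sol = solve_ivp(
        rhs, (t_grid[0], t_grid[-1]), [R_start], t_eval=t_grid,
        events=[ev_inhib, ev_necro], rtol=rtol, atol=atol, method="LSODA",
        max_step=0.25,
    )
    if not sol.success:
        last_t = sol.t[-1] if len(sol.t) else t_grid[0]
        last = sol.y[0, -1] if sol.y.size else R_start
        raise SolverFailure(f"Greenspan integration failed: {sol.message}",
                            float(last_t), {"R_o": float(last)})

    R_o = sol.y[0]
    R_n = np.empty_like(R_o)
    R_i = np.empty_like(R_o)
    for j, ro in enumerate(R_o):
        R_n[j], R_i[j] = _consistent_structure(float(ro), params)

    def first_event(times: np.ndarray, already: bool) -> Optional[float]:
        if already:
            return float(t_grid[0])
        return float(times[0]) if len(times) else None

    traj = Trajectory(
        t=t_grid, R_o=R_o, R_i=R_i, R_n=R_n,
        phase=[classify_phase(SpheroidStructure(R_o=float(a), R_n=float(b), R_i=float(c)))
               for a, b, c in zip(R_o, R_n, R_i)],
        t_inhibited_forms=first_event(sol.t_events[0], R_start >= params.Rbar),
        t_necrotic_forms=first_event(sol.t_events[1], R_start >= params.R_c),
    )
    return traj


def inhibited_onset_time(params: GreenspanParams) -> float:
    """Time at which the inhibited region forms, t = (3/s) log(Rbar/R_o(0)).

    Exact while growth is purely exponential (requires Rbar <= R_c so the
    inhibited region forms first).  Under the waste interpretation this time
    is independent of the oxygen parameters.  Returns 0 if already formed.
    """
    if params.Rbar <= params.R_o0:
        return 0.0
    return (3.0 / params.s) * math.log(params.Rbar / params.R_o0)
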