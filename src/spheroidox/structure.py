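"""Steady-state oxygen and waste fields inside a spherically symmetric spheroid.

A growing avascular spheroid develops up to three concentric regions: a
proliferating rim (``R_i < r < R_o``), a living but proliferation-inhibited
shell (``R_n < r < R_i``) and a necrotic core (``r < R_n``).  Because oxygen
and metabolic-waste diffusion are fast relative to growth, both fields are
quasi-steady at every instant and admit closed forms.  Oxygen obeys

    (k / r^2) d/dr (r^2 dp/dr) = Omega * alpha   on  R_n < r < R_o,

with ``p(R_o) = p_inf`` and no flux into the core, giving

    p(r) = p_inf - a * [R_o^2 - r^2 - 2 R_n^3 (1/r - 1/R_o)],

with the lumped gradient coefficient ``a = Omega * alpha / (6 k)``.  Waste is
produced at constant rate by living cells and satisfies the sign-flipped
problem with ``beta(R_o) = 0``.  Evaluating the oxygen field at the necrotic
threshold ``p = p_n = 0`` yields the algebraic constraint

    R_c^2 = R_o^2 - 3 R_n^2 + 2 R_n^3 / R_o,

where ``R_c = sqrt(p_inf / a)`` is the outer radius at which the core first
forms.  Evaluating the waste field at the inhibition threshold yields

    Rbar^2 = R_o^2 - R_i^2 - 2 R_n^3 (1/R_i - 1/R_o),

with ``Rbar`` the outer radius at which the inhibited region first forms.
Inverting these two relations at measured radii gives per-spheroid snapshot
estimates of ``R_c``, the oxygen consumption rate ``alpha``, the inhibition
pressure ``p_i`` and ``Rbar`` — no time-course needed.

All radii are in micrometres, pressures in the same unit as ``p_inf``
(conventionally % O2), times in days.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "SpheroidStructure",
    "OxygenParams",
    "WasteParams",
    "Hypothesis",
    "Phase",
    "SnapshotEstimate",
    "oxygen_profile",
    "waste_profile",
    "necrotic_radius_algebraic",
    "inhibited_radius_algebraic",
    "critical_radius_from_constants",
    "alpha_from_critical_radius",
    "percent_to_mmhg",
    "snapshot_estimate",
    "predict_hypoxic_radius",
    "classify_phase",
]

#: abs tolerance for radius roots, in micrometres
ROOT_XTOL = 1e-9

#: default conversion: 100 % O2 corresponds to one atmosphere
MMHG_PER_PERCENT = 7.6


class Phase(str, Enum):
    """Greenspan growth phases: (i) exponential, (ii) inhibited, (iii) necrotic."""

    I = "phase_i"
    II = "phase_ii"
    III = "phase_iii"


class Hypothesis(str, Enum):
    """Which mechanism bounds the inhibited region.

    H1: oxygen below threshold p_i arrests cells, so Rbar^2 = R_c^2 Q^2 with
    Q^2 = (p_inf - p_i)/p_inf.  H2: metabolic waste above threshold beta_i
    arrests cells, so Rbar^2 = 6 beta_i kappa / P, independent of oxygen.
    """

    H1_OXYGEN_INHIBITION = "H1_oxygen_inhibition"
    H2_WASTE_INHIBITION = "H2_waste_inhibition"


@dataclass(frozen=True)
class SpheroidStructure:
    """A per-spheroid snapshot of the concentric radii, in micrometres."""

    R_o: float
    R_n: float = 0.0
    R_i: float = 0.0
    R_p: Optional[float] = None
    t: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.R_o) or self.R_o <= 0:
            raise ValueError(f"R_o must be positive and finite, got {self.R_o}")
        for name in ("R_n", "R_i"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be non-negative and finite, got {v}")
        if self.R_n > self.R_o or self.R_i > self.R_o:
            raise ValueError(
                f"inner radii exceed outer: R_n={self.R_n}, R_i={self.R_i}, R_o={self.R_o}"
            )
        if self.R_p is not None and not (0.0 <= self.R_p <= self.R_o):
            raise ValueError(f"R_p={self.R_p} outside [0, R_o={self.R_o}]")

    @property
    def xi_n(self) -> float:
        return self.R_n / self.R_o

    @property
    def xi_i(self) -> float:
        return self.R_i / self.R_o

    @property
    def xi_p(self) -> Optional[float]:
        return None if self.R_p is None else self.R_p / self.R_o

    def inhibited_radius_clipped(self) -> float:
        """R_i for profile evaluation; noisy measurements with R_i < R_n are clipped."""
        if 0.0 < self.R_i < self.R_n:
            warnings.warn(
                f"measured R_i={self.R_i:.3f} < R_n={self.R_n:.3f}; "
                "clipping R_i to R_n for profile evaluation",
                stacklevel=2,
            )
            return self.R_n
        return self.R_i


@dataclass(frozen=True)
class OxygenParams:
    """Oxygen field parameters in lumped form.

    ``grad_coeff`` is a = Omega*alpha/(6k) in pressure-units per um^2; the
    critical radius satisfies R_c = sqrt(p_inf / a).  SI constants (k, Omega)
    enter only through the explicit conversion helpers below.
    """

    p_inf: float
    grad_coeff: float
    p_n: float = 0.0

    def __post_init__(self) -> None:
        if self.p_inf <= 0 or self.grad_coeff <= 0:
            raise ValueError("p_inf and grad_coeff must be positive")

    @classmethod
    def from_critical_radius(cls, p_inf: float, R_c: float, p_n: float = 0.0) -> "OxygenParams":
        if R_c <= 0:
            raise ValueError("R_c must be positive")
        return cls(p_inf=p_inf, grad_coeff=p_inf / R_c**2, p_n=p_n)

    @property
    def R_c(self) -> float:
        return math.sqrt(self.p_inf / self.grad_coeff)


@dataclass(frozen=True)
class WasteParams:
    """Waste field parameters in lumped form: prod_coeff = P/(6 kappa).

    ``Rbar = sqrt(beta_i / prod_coeff)`` is the outer radius at which the
    inhibited region first forms (hypothesis 2).
    """

    prod_coeff: float
    beta_i: float

    def __post_init__(self) -> None:
        if self.prod_coeff <= 0 or self.beta_i <= 0:
            raise ValueError("prod_coeff and beta_i must be positive")

    @classmethod
    def from_inhibition_radius(cls, Rbar: float, beta_i: float = 1.0) -> "WasteParams":
        if Rbar <= 0:
            raise ValueError("Rbar must be positive")
        return cls(prod_coeff=beta_i / Rbar**2, beta_i=beta_i)

    @property
    def Rbar(self) -> float:
        return math.sqrt(self.beta_i / self.prod_coeff)


def _geometry_factor(r, R_o: float, R_n: float):
    """The shared shape factor R_o^2 - r^2 - 2 R_n^3 (1/r - 1/R_o).

    Handles r -> 0 when R_n = 0 (harmonic term vanishes identically).
    """
    r = np.asarray(r, dtype=float)
    if R_n < 1e-8:  # sub-atomic core: no harmonic term (avoids 0 * inf at r -> 0)
        return R_o**2 - r**2
    inv_r = np.where(r > 0, 1.0 / np.where(r > 0, r, 1.0), np.inf)
    return R_o**2 - r**2 - 2.0 * R_n**3 * (inv_r - 1.0 / R_o)


def _check_radial_args(r, R_o: float, R_n: float) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if not np.isfinite(R_o) or not np.isfinite(R_n) or R_o <= 0 or R_n < 0 or R_n >= R_o:
        raise ValueError(f"require 0 <= R_n < R_o, got R_n={R_n}, R_o={R_o}")
    if np.any(~np.isfinite(r)) or np.any(r < 0) or np.any(r > R_o * (1 + 1e-12)):
        raise ValueError("r must lie in [0, R_o]")
    return np.minimum(r, R_o)


def oxygen_profile(r, R_o: float, R_n: float, oxy: OxygenParams):
    """Oxygen partial pressure p(r) within the spheroid.

    Closed-form solution of the quasi-steady diffusion-consumption problem
    with p(R_o) = p_inf and p = p_n = 0 inside the core.  Continuous in r,
    monotone non-decreasing on [R_n, R_o], clipped below at zero.
    """
    r = _check_radial_args(r, R_o, R_n)
    p = oxy.p_inf - oxy.grad_coeff * _geometry_factor(np.maximum(r, R_n), R_o, R_n)
    p = np.maximum(p, 0.0)
    out = np.where(r < R_n, oxy.p_n, p)
    return out.item() if out.ndim == 0 else out


def waste_profile(r, R_o: float, R_n: float, waste: WasteParams):
    """Waste concentration beta(r): zero at the surface, maximal at the core.

    Production is confined to living cells (R_n < r < R_o); inside the core
    the concentration is flat at its r = R_n value.
    """
    r = _check_radial_args(r, R_o, R_n)
    beta = waste.prod_coeff * _geometry_factor(np.maximum(r, R_n), R_o, R_n)
    out = np.maximum(beta, 0.0)
    return out.item() if out.ndim == 0 else out


def _necrotic_residual(R_n: float, R_o: float, R_c: float) -> float:
    # R_o^2 - 3 R_n^2 + 2 R_n^3 / R_o - R_c^2, monotone decreasing in R_n on [0, R_o]
    return R_o**2 - 3.0 * R_n**2 + 2.0 * R_n**3 / R_o - R_c**2


def necrotic_radius_algebraic(R_o: float, R_c: float) -> float:
    """Necrotic radius implied by the oxygen field at the threshold p_n = 0.

    Returns the unique root of R_c^2 = R_o^2 - R_n^2 - (2 R_n^2/R_o)(R_o - R_n)
    in [0, R_o), or 0 when R_o <= R_c (core not yet formed).
    """
    if not (np.isfinite(R_o) and np.isfinite(R_c)) or R_o <= 0 or R_c <= 0:
        raise ValueError(f"R_o and R_c must be positive finite, got {R_o}, {R_c}")
    if R_o <= R_c:
        return 0.0
    return brentq(_necrotic_residual, 0.0, R_o, args=(R_o, R_c), xtol=ROOT_XTOL)


def _inhibited_residual(R_i: float, R_o: float, R_n: float, Rbar: float) -> float:
    return R_o**2 - R_i**2 - 2.0 * R_n**3 * (1.0 / R_i - 1.0 / R_o) - Rbar**2


def inhibited_radius_algebraic(R_o: float, R_n: float, Rbar: float) -> float:
    """Inhibited radius implied by the waste field at the threshold beta_i.

    Solves Rbar^2 = R_o^2 - R_i^2 - 2 R_n^3 (1/R_i - 1/R_o) for R_i in
    [R_n, R_o).  Returns 0 when the spheroid is too small (R_o <= Rbar) or the
    waste maximum never reaches the threshold.
    """
    if not all(np.isfinite(v) for v in (R_o, R_n, Rbar)) or R_o <= 0 or R_n < 0 or Rbar <= 0:
        raise ValueError(f"invalid arguments R_o={R_o}, R_n={R_n}, Rbar={Rbar}")
    if R_n >= R_o:
        raise ValueError("require R_n < R_o")
    if R_o <= Rbar:
        return 0.0
    if R_n == 0.0:
        return math.sqrt(R_o**2 - Rbar**2)
    if _inhibited_residual(R_n, R_o, R_n, Rbar) < 0.0:
        # waste maximum (at the core boundary) is below the threshold
        return 0.0
    return brentq(_inhibited_residual, R_n, R_o, args=(R_o, R_n, Rbar), xtol=ROOT_XTOL)


def percent_to_mmhg(p_percent: float, factor: float = MMHG_PER_PERCENT) -> float:
    """Convert an oxygen partial pressure in % O2 to mmHg (default 760 mmHg = 100%)."""
    return p_percent * factor


def critical_radius_from_constants(k: float, alpha: float, Omega: float, p_mmHg: float) -> float:
    """Critical outer radius R_c = sqrt(6 k p / (alpha Omega)), returned in um.

    ``k`` [m^2/s], ``alpha`` [m^3/kg/s], ``Omega`` [mmHg kg/m^3], ``p`` [mmHg].
    The caller converts % to mmHg first (see :func:`percent_to_mmhg`).
    """
    if min(k, alpha, Omega, p_mmHg) <= 0:
        raise ValueError("all physical constants must be positive")
    return math.sqrt(6.0 * k * p_mmHg / (alpha * Omega)) * 1e6


def alpha_from_critical_radius(k: float, R_c_um: float, Omega: float, p_mmHg: float) -> float:
    """Oxygen consumption rate from a measured critical radius; inverts the above."""
    if min(k, R_c_um, Omega, p_mmHg) <= 0:
        raise ValueError("all arguments must be positive")
    return 6.0 * k * p_mmHg / (Omega * (R_c_um * 1e-6) ** 2)


def classify_phase(structure: SpheroidStructure) -> Phase:
    """Growth phase from a snapshot: necrotic core wins, then inhibited shell."""
    if structure.R_n > 0.0:
        return Phase.III
    if structure.R_i > 0.0:
        return Phase.II
    return Phase.I


def predict_hypoxic_radius(R_o: float, R_n: float, oxy: OxygenParams, p_hyp: float) -> float:
    """Radius at which oxygen falls to the hypoxia-marker threshold p_hyp.

    Root of p(r) = p_hyp in [R_n, R_o]; the surface always sits at p_inf, so a
    threshold above p_inf returns R_o with a warning.
    """
    if p_hyp > oxy.p_inf:
        warnings.warn(
            f"p_hyp={p_hyp} exceeds p_inf={oxy.p_inf}; the spheroid surface can "
            "never be hypoxic, returning R_o",
            stacklevel=2,
        )
        return float(R_o)
    if p_hyp < oxy.p_n:
        raise ValueError(f"p_hyp={p_hyp} below the necrotic threshold {oxy.p_n}")
    f = lambda r: oxygen_profile(r, R_o, R_n, oxy) - p_hyp
    if f(R_n) >= 0.0:
        # the whole living shell sits above threshold: hypoxic boundary collapses
        # onto the necrotic boundary (R_p = R_n, possibly 0)
        return float(R_n)
    return brentq(f, R_n, R_o, xtol=1e-9)


@dataclass(frozen=True)
class SnapshotEstimate:
    """Per-spheroid estimates inverted from a single structural snapshot.

    Fields are NaN when the spheroid has not reached the phase in which the
    corresponding quantity is defined (flagged, not raised).
    """

    R_c: float = math.nan
    alpha: float = math.nan
    p_i: float = math.nan
    Rbar: float = math.nan
    phase: Phase = Phase.I
    estimable_oxygen: bool = False
    estimable_waste: bool = False


def snapshot_estimate(
    structure: SpheroidStructure,
    oxy: Optional[OxygenParams] = None,
    hypothesis: Hypothesis = Hypothesis.H2_WASTE_INHIBITION,
    constants: Optional[dict] = None,
) -> SnapshotEstimate:
    """Invert the structure relations at one measured snapshot.

    R_c requires a necrotic core (phase iii); p_i and Rbar require an inhibited
    shell (phase ii or iii).  ``alpha`` is produced only when SI ``constants``
    (keys k, Omega, p_mmHg) are supplied.  The estimators are exact inverses of
    the forward formulas, so noiseless forward-constructed snapshots recover
    the generating parameters to solver tolerance.
    """
    phase = classify_phase(structure)
    R_o, R_n = structure.R_o, structure.R_n
    R_i = structure.inhibited_radius_clipped()

    R_c = math.nan
    alpha = math.nan
    ox_ok = R_n > 0.0
    if ox_ok:
        R_c = math.sqrt(max(_necrotic_residual(R_n, R_o, 0.0), 0.0))
        if constants is not None:
            alpha = alpha_from_critical_radius(
                constants["k"], R_c, constants["Omega"], constants["p_mmHg"]
            )

    p_i = math.nan
    Rbar = math.nan
    waste_ok = R_i > 0.0
    if waste_ok:
        if oxy is not None:
            p_i = oxygen_profile(R_i, R_o, R_n, oxy) if R_n < R_o else math.nan
        if hypothesis is Hypothesis.H2_WASTE_INHIBITION or oxy is None:
            Rbar = math.sqrt(max(_inhibited_residual(R_i, R_o, R_n, 0.0), 0.0))
        else:
            # H1: Rbar^2 = R_c^2 Q^2 with Q^2 = (p_inf - p_i)/p_inf
            Rbar = oxy.R_c * math.sqrt(max(oxy.p_inf - p_i, 0.0) / oxy.p_inf)

    return SnapshotEstimate(
        R_c=R_c,
        alpha=alpha,
        p_i=p_i,
        Rbar=Rbar,
        phase=phase,
        estimable_oxygen=ox_ok,
        estimable_waste=waste_ok,
    )
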