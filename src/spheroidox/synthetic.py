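"""Synthetic radial-measurement tables emulating the spheroid study designs.

Real experiments of this kind are end-point measurements: each spheroid is
harvested, cleared and imaged once, so a dataset is a cross-section of
independent spheroids per sampling day, not a longitudinal track.  The
generator reproduces that statistical structure: a single ground-truth
trajectory per condition, sampled at the design days, with iid additive
Gaussian measurement noise per radius channel (truncated at zero), structural
radii reported as 0 before the corresponding region has formed, and optional
multiplicative outliers to exercise the robust filtering path.

Design presets mirror the study layout: normoxia samples days 2, 3, 4, 6, 8
with 12 spheroids per day; hypoxia days 2, 4, 6, 8 with 7 per day; the
switching designs sample days 2, 3, 4, 6, 8 around a switch at t_s = 2 days.
The ground-truth parameter bundles are regression fixtures with magnitudes in
the 100-400 um range of these melanoma spheroids, not estimates of any real
cell line.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import _kernels
from .adaptation import DeoxygenationParams, ReoxygenationParams
from .greenspan import GreenspanParams
from .structure import OxygenParams, predict_hypoxic_radius

__all__ = [
    "ExperimentalDesign",
    "CHANNEL_COLUMNS",
    "simulate_radii",
    "generate_dataset",
    "ground_truth_bundle",
    "PRESETS",
]

#: channel name -> measurement-table column
CHANNEL_COLUMNS = {"R_o": "R_o_um", "R_n": "R_n_um", "R_i": "R_i_um", "R_p": "R_p_um"}

#: default measurement noise per channel, um
DEFAULT_SIGMA = 4.0


@dataclass(frozen=True)
class ExperimentalDesign:
    """Sampling layout and noise model for one synthetic experiment."""

    condition: str
    days: tuple = (2.0, 3.0, 4.0, 6.0, 8.0)
    spheroids_per_day: int = 12
    t_s: Optional[float] = None
    sigma: Union[float, dict] = DEFAULT_SIGMA
    outlier_fraction: float = 0.0
    outlier_factor: float = 10.0
    multiplicative_noise: bool = False
    include_R_p: bool = False
    p_hyp: float = 1.5

    def sigma_for(self, channel: str) -> float:
        if isinstance(self.sigma, dict):
            return float(self.sigma[channel])
        return float(self.sigma)

    def __post_init__(self) -> None:
        sigmas = (list(self.sigma.values()) if isinstance(self.sigma, dict)
                  else [self.sigma])
        if any(s < 0 for s in sigmas):
            raise ValueError("noise sigma must be non-negative")
        if not (0.0 <= self.outlier_fraction < 1.0):
            raise ValueError("outlier_fraction must lie in [0, 1)")


#: the study-like layouts
NORMOXIA_DESIGN = ExperimentalDesign(condition="normoxia", days=(2.0, 3.0, 4.0, 6.0, 8.0),
                                     spheroids_per_day=12)
HYPOXIA_DESIGN = ExperimentalDesign(condition="hypoxia", days=(2.0, 4.0, 6.0, 8.0),
                                    spheroids_per_day=7)
DEOXY_DESIGN = ExperimentalDesign(condition="deoxygenation", days=(2.0, 3.0, 4.0, 6.0, 8.0),
                                  spheroids_per_day=12, t_s=2.0)
REOXY_DESIGN = ExperimentalDesign(condition="reoxygenation", days=(2.0, 3.0, 4.0, 6.0, 8.0),
                                  spheroids_per_day=10, t_s=2.0)

AnyParams = Union[GreenspanParams, DeoxygenationParams, ReoxygenationParams]


def simulate_radii(params: AnyParams, days: Sequence[float], dt: float = 0.005) -> dict:
    """Noise-free (R_o, R_i, R_n) at the requested days for any growth model."""
    days = np.asarray(days, dtype=float)
    order = np.argsort(days, kind="stable")
    sorted_days = days[order]
    if isinstance(params, GreenspanParams):
        out = _kernels.greenspan_radii(params.as_array(), sorted_days, dt)[:3]
    elif isinstance(params, DeoxygenationParams):
        out = _kernels.switching_trajectory(
            params.as_array(), sorted_days, params.t_s,
            params.p_inf_pre, params.p_inf_post, True, dt)[:3]
    elif isinstance(params, ReoxygenationParams):
        out = _kernels.switching_trajectory(
            params.as_array(), sorted_days, params.t_s,
            params.p_inf_pre, params.p_inf_post, False, dt)[:3]
    else:
        raise TypeError(f"unsupported parameter type {type(params)!r}")
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    return {"R_o": out[0][inv], "R_i": out[1][inv], "R_n": out[2][inv]}


def _hypoxic_radii(params: AnyParams, days: np.ndarray, clean: dict,
                   p_hyp: float) -> np.ndarray:
    """Noise-free hypoxic radius R_p per day via the oxygen-field inversion."""
    R_p = np.empty_like(days, dtype=float)
    for j, d in enumerate(days):
        if isinstance(params, GreenspanParams):
            oxy = OxygenParams.from_critical_radius(p_inf=21.0, R_c=params.R_c)
        else:
            pre = d < params.t_s
            if isinstance(params, DeoxygenationParams):
                a = params.a_n if pre else params.a_h + (params.a_n - params.a_h) * np.exp(
                    -(d - params.t_s) / params.tau_alpha)
            else:
                a = params.a_h if pre else params.a_n + (params.a_h - params.a_n) * np.exp(
                    -(d - params.t_s) / params.tau_alpha)
            p_inf = params.p_inf_pre if pre else params.p_inf_post
            oxy = OxygenParams(p_inf=p_inf, grad_coeff=a)
        R_p[j] = predict_hypoxic_radius(
            float(clean["R_o"][j]), float(min(clean["R_n"][j], clean["R_o"][j])),
            oxy, min(p_hyp, oxy.p_inf))
    return R_p


def generate_dataset(params: AnyParams, design: ExperimentalDesign,
                     seed: int, dt: float = 0.005) -> pd.DataFrame:
    """Draw one synthetic end-point measurement table.

    Observed radii are the ground-truth trajectory at each design day plus
    iid Normal(0, sigma_channel) noise, truncated at 0.  Radii of regions that
    have not formed are 0 in truth and observed with the same noise model
    (then truncated), matching the measurement convention R_n = 0 before
    necrosis.  When ``design.outlier_fraction`` > 0, a random subset of
    (row, channel) entries is multiplied by ``design.outlier_factor``.
    Fully reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    days = np.asarray(design.days, dtype=float)
    clean = simulate_radii(params, days, dt=dt)
    if design.include_R_p:
        clean = {**clean, "R_p": _hypoxic_radii(params, days, clean, design.p_hyp)}

    rows = []
    sph = 0
    for j, d in enumerate(days):
        for _ in range(design.spheroids_per_day):
            sph += 1
            row = {"spheroid_id": f"{design.condition}_{sph:03d}", "day": float(d),
                   "condition": design.condition}
            for ch, col in CHANNEL_COLUMNS.items():
                if ch not in clean:
                    row[col] = np.nan
                    continue
                true_val = float(clean[ch][j])
                sd = design.sigma_for(ch) if not design.multiplicative_noise else 0.0
                if design.multiplicative_noise:
                    obs = true_val * (1.0 + design.sigma_for(ch) * rng.standard_normal())
                else:
                    obs = true_val + sd * rng.standard_normal()
                row[col] = max(obs, 0.0)
            rows.append(row)
    df = pd.DataFrame(rows)

    if design.outlier_fraction > 0.0:
        channels = [c for c in CHANNEL_COLUMNS.values() if df[c].notna().any()]
        n_cells = len(df) * len(channels)
        n_out = int(round(design.outlier_fraction * n_cells))
        flat = rng.choice(n_cells, size=n_out, replace=False)
        for k in flat:
            i, c = divmod(int(k), len(channels))
            df.loc[i, channels[c]] *= design.outlier_factor
    return df


# ---------------------------------------------------------------------------
# regression presets

def _normoxia_truth() -> GreenspanParams:
    return GreenspanParams(R_o0=130.0, s=0.6, R_c=250.0, gamma=0.6, Q=0.7)


def _hypoxia_truth() -> GreenspanParams:
    # faster per-volume proliferation in mild hypoxia; earlier necrosis
    return GreenspanParams.from_radii(R_o0=100.0, s=0.75, R_c=150.0, Rbar=140.0, lam=0.6)


def _deoxy_truth() -> DeoxygenationParams:
    # endpoints chosen so the trajectory reproduces the deoxygenation
    # phenomenology: outer radius approximately constant after the switch
    # while the internal fractions climb toward their hypoxia values, and a
    # necrotic core near its quasi-steady radius within a day of the switch
    return DeoxygenationParams(
        R_o0=130.0, a_n=21.0 / 250.0**2, a_h=2.0 / 150.0**2, tau_alpha=0.23,
        Rbar_n=175.0, Rbar_h=140.0, tau_Rbar=0.23, s_n=0.6, s_h=0.75, tau_s=1.0,
        lam_n=0.36, lam_h=1.4, tau_lam=1.0, lamhat0=2.0, tau_lamhat=0.3,
        t_s=2.0, p_inf_pre=21.0, p_inf_post=2.0,
    )


def _reoxy_truth() -> ReoxygenationParams:
    # tuned so the regression trajectory exhibits the transient reverse
    # phase sequence iii -> ii -> i -> ii -> iii after the switch
    return ReoxygenationParams(
        R_o0=97.0, R_n0=0.0, a_n=21.0 / 250.0**2, a_h=2.0 / 150.0**2, tau_alpha=0.23,
        Rbar_n=230.0, Rbar_h=140.0, tau_Rbar=0.8, s_n=0.6, s_h=0.75, tau_s=1.0,
        lam_n=0.36, lam_h=0.6, tau_lam=1.0, lamtilde0=20.0, tau_lamtilde=0.2,
        nu=0.75, t_s=2.0, p_inf_pre=2.0, p_inf_post=21.0,
    )


PRESETS = {
    "normoxia_like": (_normoxia_truth, NORMOXIA_DESIGN),
    "hypoxia_like": (_hypoxia_truth, HYPOXIA_DESIGN),
    "deoxy_like": (_deoxy_truth, DEOXY_DESIGN),
    "reoxy_like": (_reoxy_truth, REOXY_DESIGN),
}


def ground_truth_bundle(preset: str) -> tuple:
    """(ground-truth params, design) for a named regression preset."""
    try:
        factory, design = PRESETS[preset]
    except KeyError:
        raise KeyError(
            f"unknown preset {preset!r}; choose from {sorted(PRESETS)}") from None
    return factory(), design
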