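"""Likelihood-based calibration of the growth models to radial measurements.

The error model is iid additive Gaussian on each observed radius: for
observation y of channel c on day d,

    y ~ Normal( M_c(theta; d), sigma^2 ),

with a single shared noise scale sigma across the structural channels
(R_o, R_n, R_i) by default.  When ``sigma`` is not fixed it is profiled out
analytically (the concentrated log-likelihood -N/2 [log(2 pi sigma_hat^2)+1]
with sigma_hat^2 = SSE/N), which is also the initial error-variance estimate
handed to the MCMC stage.

Outliers are removed before fitting with the quartile rule (points beyond
1.5 IQR from the quartiles), applied independently per condition, channel and
sampling day; quartiles use linear interpolation between order statistics.

Maximum-likelihood estimation is multistart local optimisation: Latin-
hypercube starts over the parameter box, Nelder-Mead refinement of each, best
optimum returned — deterministic for a given seed.  Practical identifiability
is assessed by profile likelihood: for each parameter, the likelihood is
re-maximised over the remaining parameters along a grid, and the approximate
95% confidence interval is the region where the normalised profile stays
above the chi-square(1) cutoff of -1.92.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from . import _kernels
from .synthetic import CHANNEL_COLUMNS

__all__ = [
    "LikelihoodConfig",
    "ProfileResult",
    "MleResult",
    "flag_outliers",
    "filter_outliers",
    "make_greenspan_model",
    "make_deoxygenation_model",
    "make_reoxygenation_model",
    "log_likelihood",
    "residual_sse",
    "fit_mle",
    "profile_likelihood",
]

PROFILE_CUTOFF_95 = -1.9207294376957623  # -chi2(1 df).ppf(0.95) / 2

GREENSPAN_PARAM_NAMES = ("R_o0", "s", "R_c", "gamma", "Q")

#: model handle: (theta, days sorted ascending) -> array (3, n) of (R_o, R_i, R_n)
ForwardModel = Callable[[np.ndarray, np.ndarray], np.ndarray]


def make_greenspan_model(dt: float = 0.01) -> ForwardModel:
    """Constant-environment forward model on the 5-vector (R_o0, s, R_c, gamma, Q)."""

    def model(theta: np.ndarray, days: np.ndarray) -> np.ndarray:
        return _kernels.greenspan_radii(np.asarray(theta, float), days, dt)

    return model


def make_deoxygenation_model(t_s: float = 2.0, p_pre: float = 21.0,
                             p_post: float = 2.0, dt: float = 0.01) -> ForwardModel:
    """Deoxygenation forward model on the 15-vector theta_d (protocol fixed)."""

    def model(theta: np.ndarray, days: np.ndarray) -> np.ndarray:
        return _kernels.switching_trajectory(
            np.asarray(theta, float), days, t_s, p_pre, p_post, True, dt)[:3]

    return model


def make_reoxygenation_model(t_s: float = 2.0, p_pre: float = 2.0,
                             p_post: float = 21.0, dt: float = 0.01) -> ForwardModel:
    """Re-oxygenation forward model on the 17-vector theta_r (protocol fixed)."""

    def model(theta: np.ndarray, days: np.ndarray) -> np.ndarray:
        return _kernels.switching_trajectory(
            np.asarray(theta, float), days, t_s, p_pre, p_post, False, dt)[:3]

    return model


# ---------------------------------------------------------------------------
# outlier filtering

def flag_outliers(values: Sequence[float]) -> np.ndarray:
    """Quartile-rule outlier mask: beyond Q1 - 1.5 IQR or Q3 + 1.5 IQR.

    Quartiles use linear interpolation between order statistics.  Fewer than
    four finite values: nothing is flagged.  With IQR = 0 only strict
    departures from the common value are flagged.
    """
    values = np.asarray(values, dtype=float)
    mask = np.zeros(values.shape, dtype=bool)
    finite = np.isfinite(values)
    if finite.sum() < 4:
        return mask
    q1, q3 = np.percentile(values[finite], [25.0, 75.0])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    mask[finite] = (values[finite] < lo) | (values[finite] > hi)
    return mask


def filter_outliers(df: pd.DataFrame,
                    channels: Sequence[str] = ("R_o", "R_n", "R_i")) -> pd.DataFrame:
    """Add per-channel boolean ``<col>_outlier`` columns, grouped by
    (condition, day); flagged entries are excluded from likelihoods."""
    out = df.copy()
    for ch in channels:
        col = CHANNEL_COLUMNS[ch]
        flags = np.zeros(len(out), dtype=bool)
        for _, idx in out.groupby(["condition", "day"]).groups.items():
            idx = np.asarray(idx)
            flags[out.index.get_indexer(idx)] = flag_outliers(out.loc[idx, col].to_numpy())
        out[f"{col}_outlier"] = flags
    return out


# ---------------------------------------------------------------------------
# likelihood

@dataclass(frozen=True)
class LikelihoodConfig:
    """Gaussian observation model settings.

    ``sigma=None`` profiles the noise scale analytically; a positive float
    fixes it.  ``channels`` selects which radii enter the likelihood (the
    hypoxic radius R_p is validation-only and excluded by default).
    """

    channels: tuple = ("R_o", "R_n", "R_i")
    sigma: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("at least one observed channel is required")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive when fixed")


_CHANNEL_ROW = {"R_o": 0, "R_i": 1, "R_n": 2}


def _gather_observations(data: pd.DataFrame, cfg: LikelihoodConfig):
    """(unique sorted days, per-channel day-index arrays, observation arrays)."""
    days = np.sort(data["day"].unique().astype(float))
    day_pos = {d: j for j, d in enumerate(days)}
    obs = []
    for ch in cfg.channels:
        col = CHANNEL_COLUMNS[ch]
        keep = data[col].notna()
        flag_col = f"{col}_outlier"
        if flag_col in data.columns:
            keep &= ~data[flag_col].astype(bool)
        sub = data.loc[keep]
        idx = np.array([day_pos[float(d)] for d in sub["day"]], dtype=np.int64)
        obs.append((_CHANNEL_ROW[ch], idx, sub[col].to_numpy(dtype=float)))
    return days, obs


def compile_observations(data: pd.DataFrame,
                         cfg: LikelihoodConfig = LikelihoodConfig()):
    """Pre-extract observation arrays once; pass to the likelihood hot path."""
    return _gather_observations(data, cfg)


def residual_sse(theta: np.ndarray, data: pd.DataFrame, model: ForwardModel,
                 cfg: LikelihoodConfig = LikelihoodConfig(),
                 compiled=None) -> tuple:
    """(sum of squared residuals, number of observations); SSE=inf on failure.

    The forward model is evaluated once per distinct sampling day; missing
    entries and flagged outliers contribute nothing.  ``compiled`` (from
    :func:`compile_observations`) skips the table scan on repeated calls.
    """
    days, obs = compiled if compiled is not None else _gather_observations(data, cfg)
    try:
        pred = model(np.asarray(theta, dtype=float), days)
    except Exception:
        return np.inf, sum(len(o[2]) for o in obs)
    if not np.all(np.isfinite(pred)):
        return np.inf, sum(len(o[2]) for o in obs)
    sse = 0.0
    n = 0
    for row, idx, y in obs:
        r = y - pred[row, idx]
        sse += float(r @ r)
        n += len(y)
    return sse, n


def log_likelihood(theta: np.ndarray, data: pd.DataFrame, model: ForwardModel,
                   cfg: LikelihoodConfig = LikelihoodConfig(),
                   compiled=None) -> float:
    """Gaussian log-likelihood of the data at theta (shared sigma).

    With ``cfg.sigma`` fixed this is the exact iid normal log-density sum;
    with ``sigma=None`` the concentrated likelihood (sigma profiled out).
    Simulation failures return -inf so optimisers and samplers reject them.
    """
    sse, n = residual_sse(theta, data, model, cfg, compiled=compiled)
    if n == 0:
        raise ValueError("no usable observations for the configured channels")
    if not np.isfinite(sse):
        return -np.inf
    if cfg.sigma is not None:
        s2 = cfg.sigma**2
        return -0.5 * n * np.log(2.0 * np.pi * s2) - 0.5 * sse / s2
    s2_hat = max(sse / n, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * s2_hat) + 1.0)


# ---------------------------------------------------------------------------
# maximum likelihood

@dataclass
class MleResult:
    theta: np.ndarray
    log_lik: float
    sigma_hat: float
    n_obs: int
    start_values: np.ndarray
    start_loglik: np.ndarray
    param_names: Optional[tuple] = None

    def as_dict(self) -> dict:
        names = self.param_names or tuple(f"theta{i}" for i in range(len(self.theta)))
        return dict(zip(names, map(float, self.theta)))


def fit_mle(data: pd.DataFrame, model: ForwardModel, bounds: Sequence[tuple],
            n_starts: int = 8, seed: int = 0,
            cfg: LikelihoodConfig = LikelihoodConfig(),
            param_names: Optional[tuple] = None,
            x0: Optional[np.ndarray] = None) -> MleResult:
    """Multistart MLE over a bounded box; deterministic per seed.

    Starts are a Latin-hypercube sample of the box (plus ``x0`` if given),
    each refined by Nelder-Mead on the concentrated/fixed-sigma likelihood,
    and the best refined optimum is returned.  The returned likelihood is
    never below the likelihood of any start.
    """
    bounds = np.asarray(bounds, dtype=float)
    if bounds.ndim != 2 or bounds.shape[1] != 2 or np.any(~np.isfinite(bounds)):
        raise ValueError("bounds must be a finite (d, 2) array")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    d = len(bounds)
    sampler = qmc.LatinHypercube(d=d, seed=seed)
    starts = qmc.scale(sampler.random(n_starts), bounds[:, 0], bounds[:, 1])
    if x0 is not None:
        starts = np.vstack([np.asarray(x0, float)[None, :], starts])

    compiled = compile_observations(data, cfg)

    def neg_ll(theta):
        if np.any(theta < bounds[:, 0]) or np.any(theta > bounds[:, 1]):
            return np.inf
        return -log_likelihood(theta, data, model, cfg, compiled=compiled)

    best = None
    start_ll = np.empty(len(starts))
    failures = []
    for i, s in enumerate(starts):
        start_ll[i] = -neg_ll(s)
        try:
            res = minimize(neg_ll, s, method="Nelder-Mead",
                           options={"xatol": 1e-8, "fatol": 1e-10,
                                    "maxiter": 4000, "maxfev": 8000})
        except Exception as err:  # pragma: no cover - defensive
            failures.append(f"start {i}: {err}")
            continue
        cand = (-res.fun, np.clip(res.x, bounds[:, 0], bounds[:, 1]))
        if np.isfinite(cand[0]) and (best is None or cand[0] > best[0]):
            best = cand
    if best is None:
        raise RuntimeError("all optimisation starts failed: " + "; ".join(failures))
    ll, theta = best
    finite_start = start_ll[np.isfinite(start_ll)]
    if finite_start.size and ll < finite_start.max() - 1e-9:
        # fall back to the best raw start (should not happen for NM descent)
        theta = starts[int(np.nanargmax(start_ll))]
        ll = float(np.nanmax(start_ll))
    sse, n = residual_sse(theta, data, model, cfg)
    sigma_hat = float(np.sqrt(sse / n)) if np.isfinite(sse) else np.nan
    return MleResult(theta=theta, log_lik=float(ll), sigma_hat=sigma_hat, n_obs=n,
                     start_values=starts, start_loglik=start_ll,
                     param_names=tuple(param_names) if param_names else None)


# ---------------------------------------------------------------------------
# profile likelihood

@dataclass
class ProfileResult:
    param: str
    grid: np.ndarray
    profile: np.ndarray          # normalised: max = 0 at the MLE
    ci95: tuple
    theta_hat: np.ndarray
    multimodal: bool = False

    def contains(self, value: float) -> bool:
        lo, hi = self.ci95
        return lo <= value <= hi


def profile_likelihood(data: pd.DataFrame, model: ForwardModel, mle: MleResult,
                       param_index: int, bounds: Sequence[tuple],
                       grid: Optional[np.ndarray] = None, n_grid: int = 30,
                       cfg: LikelihoodConfig = LikelihoodConfig(),
                       param_name: Optional[str] = None) -> ProfileResult:
    """Profile the likelihood along one parameter.

    At each grid value the remaining parameters are re-optimised
    (Nelder-Mead, warm-started from the neighbouring grid point, sweeping
    outward from the MLE).  The 95% CI is where the normalised profile is
    >= -1.92, with linear interpolation at the crossings; a CI end clamped at
    the box edge means the data do not bound the parameter on that side.
    A non-unimodal profile sets ``multimodal`` (warning, not an error).
    """
    bounds = np.asarray(bounds, dtype=float)
    d = len(bounds)
    j = param_index
    if grid is None:
        grid = np.linspace(bounds[j, 0], bounds[j, 1], n_grid)
    grid = np.asarray(grid, dtype=float)
    others = [i for i in range(d) if i != j]

    compiled = compile_observations(data, cfg)

    def neg_ll_given(free, value):
        theta = np.empty(d)
        theta[j] = value
        theta[others] = free
        if np.any(theta < bounds[:, 0]) or np.any(theta > bounds[:, 1]):
            return np.inf
        return -log_likelihood(theta, data, model, cfg, compiled=compiled)

    prof = np.full(len(grid), -np.inf)

    if not others:
        # single-parameter model: the profile is the likelihood itself
        for k, v in enumerate(grid):
            prof[k] = -neg_ll_given(np.empty(0), v)
    else:
        def sweep(indices):
            free = mle.theta[others].copy()
            for k in indices:
                res = minimize(neg_ll_given, free, args=(grid[k],),
                               method="Nelder-Mead",
                               options={"xatol": 1e-7, "fatol": 1e-8,
                                        "maxiter": 2000, "maxfev": 4000})
                if np.isfinite(res.fun):
                    prof[k] = max(prof[k], -res.fun)
                    free = res.x
            return free

        k0 = int(np.argmin(np.abs(grid - mle.theta[j])))
        sweep(range(k0, len(grid)))
        sweep(range(k0, -1, -1))

    norm = prof - mle.log_lik
    norm = np.minimum(norm, 0.0)  # profile cannot exceed the global max

    above = norm >= PROFILE_CUTOFF_95
    if not above.any():
        ci = (np.nan, np.nan)
    else:
        idx = np.where(above)[0]
        lo_i, hi_i = idx[0], idx[-1]

        def crossing(inside_i, outside_i):
            f_in, f_out = norm[inside_i], norm[outside_i]
            x = grid[outside_i] + (PROFILE_CUTOFF_95 - f_out) / (f_in - f_out) * \
                (grid[inside_i] - grid[outside_i])
            if not others:
                # no nuisances: the exact profile is cheap, refine by brentq
                from scipy.optimize import brentq as _brentq

                g = lambda v: (-neg_ll_given(np.empty(0), v) - mle.log_lik
                               - PROFILE_CUTOFF_95)
                a, b = sorted((grid[inside_i], grid[outside_i]))
                try:
                    return _brentq(g, a, b, xtol=1e-12 * max(abs(a), abs(b), 1.0))
                except ValueError:
                    return x
            return x

        lo = grid[lo_i] if lo_i == 0 or not np.isfinite(norm[lo_i - 1]) \
            else crossing(lo_i, lo_i - 1)
        hi = grid[hi_i] if hi_i == len(grid) - 1 or not np.isfinite(norm[hi_i + 1]) \
            else crossing(hi_i, hi_i + 1)
        ci = (float(lo), float(hi))

    finite = np.isfinite(norm)
    interior_max = np.diff(np.sign(np.diff(norm[finite])))
    multimodal = bool((interior_max < -1).sum() > 1)
    if multimodal:
        warnings.warn(f"profile for parameter {param_name or j} is not unimodal",
                      stacklevel=2)

    return ProfileResult(param=param_name or f"theta{j}", grid=grid, profile=norm,
                         ci95=ci, theta_hat=mle.theta, multimodal=multimodal)
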