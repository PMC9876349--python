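"""Adaptive-Metropolis Bayesian calibration with convergence diagnostics.

Sampler: Haario-style adaptive Metropolis.  The proposal is a multivariate
normal whose covariance is periodically re-estimated from the chain history,
scaled by the usual 2.38^2/d factor plus a small diagonal jitter.  Priors are
uniform on the parameter box (bounded global search with flat-prior
Metropolis).  The Gaussian error variance sigma^2 is sampled alongside the
model parameters by its conjugate inverse-gamma full conditional,

    sigma^2 | theta, y  ~  InvGamma( (n0 + N)/2, (n0 S0^2 + SSE(theta))/2 ),

initialised from the mean squared error at the maximum-likelihood estimate —
the automatic error-standard-deviation estimation of the MCMCstat family of
samplers.

Convergence is assessed with the potential scale reduction factor computed
across chains.  Convention used here: with m chains of length n, within-chain
variance W and between-chain variance of means B/n,

    Rhat = sqrt( 1 + B / (n W) ),

i.e. the variance-ratio statistic without the (n-1)/n finite-sample
deflation, so m identical chains give exactly Rhat = 1.  Values below 1.1
are taken as converged.

Posterior prediction bands are central quantile intervals of trajectories
simulated at posterior draws, optionally with observation noise added from
the sampled sigma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .inference import (
    ForwardModel,
    LikelihoodConfig,
    MleResult,
    compile_observations,
    residual_sse,
)

__all__ = ["McmcConfig", "McmcResult", "rhat", "adaptive_metropolis", "run_mcmc",
           "prediction_intervals"]

#: central prediction-interval levels reported, in percent
PREDICTION_LEVELS = (50.0, 75.0, 95.0, 97.5, 99.5)


@dataclass(frozen=True)
class McmcConfig:
    """Chain settings.  The desk-scale default (4 x 20,000, 5,000 burn-in)
    keeps a five-parameter calibration in the minutes range; the study-scale
    profile is 4 x 250,000 with 50,000 burn-in."""

    n_chains: int = 4
    n_samples: int = 20_000
    burn_in: int = 5_000
    adapt_start: int = 500
    adapt_interval: int = 100
    sample_sigma: bool = True
    n0: float = 1.0  # prior weight (pseudo-observations) for the sigma^2 update

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_samples <= self.burn_in or self.burn_in < 0:
            raise ValueError("invalid chain settings")

    @classmethod
    def paper_scale(cls) -> "McmcConfig":
        return cls(n_samples=250_000, burn_in=50_000)


@dataclass
class McmcResult:
    chains: np.ndarray              # (n_chains, n_samples, d) including burn-in
    sigma2_chains: np.ndarray       # (n_chains, n_samples)
    burn_in: int
    param_names: tuple
    acceptance_rates: np.ndarray
    warnings_: list = field(default_factory=list)

    @property
    def posterior(self) -> np.ndarray:
        """(n_chains, kept, d) samples after burn-in removal."""
        return self.chains[:, self.burn_in:, :]

    @property
    def flat_posterior(self) -> np.ndarray:
        post = self.posterior
        return post.reshape(-1, post.shape[-1])

    def rhat(self) -> np.ndarray:
        return rhat(self.posterior)

    def summary(self) -> pd.DataFrame:
        """Per-parameter mean, sd, quartiles and Rhat of the kept samples."""
        flat = self.flat_posterior
        q = np.percentile(flat, [25.0, 50.0, 75.0], axis=0)
        return pd.DataFrame({
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1),
            "Q25": q[0], "Q50": q[1], "Q75": q[2],
            "rhat": self.rhat(),
        }, index=list(self.param_names))


def rhat(chains: np.ndarray) -> np.ndarray:
    """Potential scale reduction factor per parameter.

    ``chains`` has shape (m, n, d) (or (m, n) for a scalar parameter), m >= 2
    chains of equal length n >= 10.  Returns sqrt(1 + B/(n W)); see module
    docstring for the convention.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim == 2:
        chains = chains[:, :, None]
    m, n, d = chains.shape
    if m < 2:
        raise ValueError("Rhat needs at least two chains")
    if n < 10:
        raise ValueError("chains too short for Rhat")
    means = chains.mean(axis=1)                      # (m, d)
    W = chains.var(axis=1, ddof=1).mean(axis=0)      # (d,)
    B_over_n = means.var(axis=0, ddof=1)             # B/n
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.sqrt(1.0 + np.where(W > 0, B_over_n / W, 0.0))
    r = np.where((W == 0) & (B_over_n > 0), np.inf, r)
    return np.atleast_1d(r)


def adaptive_metropolis(
    log_target: Callable[[np.ndarray], float],
    x0: np.ndarray,
    bounds: np.ndarray,
    n_samples: int,
    seed: int,
    adapt_start: int = 500,
    adapt_interval: int = 100,
    init_scale: float = 0.05,
) -> tuple:
    """One adaptive-Metropolis chain for an arbitrary bounded log-density.

    Returns (samples (n_samples, d), acceptance rate).  Used directly for
    sampler validation on analytic targets; :func:`run_mcmc` layers the
    Gaussian error-variance Gibbs step on top.
    """
    rng = np.random.default_rng(seed)
    bounds = np.asarray(bounds, dtype=float)
    d = len(x0)
    x = np.asarray(x0, dtype=float).copy()
    lp = log_target(x)
    if not np.isfinite(lp):
        raise ValueError("initial point has zero posterior density")
    width = bounds[:, 1] - bounds[:, 0]
    cov = np.diag((init_scale * width) ** 2)
    chol = np.linalg.cholesky(cov)
    samples = np.empty((n_samples, d))
    accepted = 0
    sd = 2.38**2 / d
    eps = 1e-12
    for i in range(n_samples):
        prop = x + chol @ rng.standard_normal(d)
        if np.all(prop >= bounds[:, 0]) & np.all(prop <= bounds[:, 1]):
            lp_prop = log_target(prop)
            if np.log(rng.random()) < lp_prop - lp:
                x, lp = prop, lp_prop
                accepted += 1
        samples[i] = x
        if i >= adapt_start and (i + 1) % adapt_interval == 0:
            # adapt on the second half of the history only, so the slow
            # cold-start phase does not shrink the proposal
            hist_cov = np.cov(samples[i // 2: i + 1].T)
            cov = sd * hist_cov + sd * eps * np.eye(d)
            try:
                chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                chol = np.diag(np.sqrt(np.maximum(np.diag(cov), eps)))
    return samples, accepted / n_samples


def run_mcmc(
    data: pd.DataFrame,
    model: ForwardModel,
    bounds: Sequence[tuple],
    mle: MleResult,
    cfg: McmcConfig = McmcConfig(),
    seed: int = 0,
    cfg_lik: LikelihoodConfig = LikelihoodConfig(),
    param_names: Optional[tuple] = None,
) -> McmcResult:
    """Sample the posterior of a growth model's parameters.

    Flat priors on ``bounds``; chains start at the MLE; sigma^2 is sampled by
    its conjugate inverse-gamma conditional each iteration (initialised from
    the MLE mean squared error) unless ``cfg.sample_sigma`` is False, in which
    case the MLE sigma is held fixed.  Reproducible per seed.
    """
    bounds = np.asarray(bounds, dtype=float)
    d = bounds.shape[0]
    names = tuple(param_names) if param_names else (
        mle.param_names or tuple(f"theta{i}" for i in range(d)))
    x0 = np.clip(np.asarray(mle.theta, float), bounds[:, 0], bounds[:, 1])

    compiled = compile_observations(data, cfg_lik)
    sse0, n_obs = residual_sse(x0, data, model, cfg_lik, compiled=compiled)
    if not np.isfinite(sse0):
        raise ValueError("model cannot be simulated at the MLE")
    s2_init = max(sse0 / max(n_obs, 1), 1e-12)
    S0sq = s2_init

    chains = np.empty((cfg.n_chains, cfg.n_samples, d))
    sigma2 = np.empty((cfg.n_chains, cfg.n_samples))
    acc = np.empty(cfg.n_chains)
    msgs: list = []

    def sse_of(theta: np.ndarray) -> float:
        return residual_sse(theta, data, model, cfg_lik, compiled=compiled)[0]

    sd_scale = 2.38**2 / d
    eps = 1e-12
    for c in range(cfg.n_chains):
        rng = np.random.default_rng([seed, c])
        x = x0 + 1e-4 * (bounds[:, 1] - bounds[:, 0]) * rng.standard_normal(d)
        x = np.clip(x, bounds[:, 0], bounds[:, 1])
        s2 = s2_init
        sse_x = sse_of(x)
        width = bounds[:, 1] - bounds[:, 0]
        cov = np.diag((0.01 * width) ** 2)
        chol = np.linalg.cholesky(cov)
        n_acc = 0
        for i in range(cfg.n_samples):
            prop = x + chol @ rng.standard_normal(d)
            if np.all(prop >= bounds[:, 0]) and np.all(prop <= bounds[:, 1]):
                sse_p = sse_of(prop)
                if np.isfinite(sse_p):
                    log_alpha = -0.5 * (sse_p - sse_x) / s2
                    if np.log(rng.random()) < log_alpha:
                        x, sse_x = prop, sse_p
                        n_acc += 1
            if cfg.sample_sigma:
                shape = 0.5 * (cfg.n0 + n_obs)
                scale = 0.5 * (cfg.n0 * S0sq + sse_x)
                s2 = scale / rng.gamma(shape)
            chains[c, i] = x
            sigma2[c, i] = s2
            if i >= cfg.adapt_start and (i + 1) % cfg.adapt_interval == 0:
                hist = chains[c, i // 2: i + 1]
                cov = sd_scale * np.cov(hist.T) + sd_scale * eps * np.eye(d)
                try:
                    chol = np.linalg.cholesky(cov)
                except np.linalg.LinAlgError:
                    chol = np.diag(np.sqrt(np.maximum(np.diag(cov), eps)))
        acc[c] = n_acc / cfg.n_samples
        if not (0.05 <= acc[c] <= 0.6):
            msgs.append(f"chain {c}: acceptance rate {acc[c]:.3f} outside [0.05, 0.6]")

    if msgs:
        warnings.warn("; ".join(msgs), stacklevel=2)
    return McmcResult(chains=chains, sigma2_chains=sigma2, burn_in=cfg.burn_in,
                      param_names=names, acceptance_rates=acc, warnings_=msgs)


def prediction_intervals(
    result: McmcResult,
    model: ForwardModel,
    t_grid: Sequence[float],
    n_draws: int = 500,
    seed: int = 0,
    add_observation_noise: bool = True,
    levels: Sequence[float] = PREDICTION_LEVELS,
) -> dict:
    """Central posterior prediction bands per channel per time.

    Simulates the forward model at ``n_draws`` posterior samples (with
    replacement), optionally adding Gaussian observation noise with the
    jointly sampled sigma, and returns
    ``{channel: {level: (lower, upper) arrays over t_grid}}`` plus the
    posterior-median trajectory under key "median".  Bands are nested by
    construction of the central quantiles.
    """
    rng = np.random.default_rng(seed)
    t_grid = np.asarray(t_grid, dtype=float)
    flat = result.flat_posterior
    s2_flat = result.sigma2_chains[:, result.burn_in:].reshape(-1)
    idx = rng.integers(0, len(flat), size=n_draws)
    sims = np.empty((n_draws, 3, len(t_grid)))
    for k, i in enumerate(idx):
        sims[k] = model(flat[i], t_grid)
        if add_observation_noise:
            sims[k] += np.sqrt(s2_flat[i]) * rng.standard_normal(sims[k].shape)
    out: dict = {}
    for row, ch in ((0, "R_o"), (1, "R_i"), (2, "R_n")):
        bands = {}
        for lev in levels:
            half = lev / 2.0
            lo, hi = np.percentile(sims[:, row, :], [50.0 - half, 50.0 + half], axis=0)
            bands[lev] = (lo, hi)
        bands["median"] = np.percentile(sims[:, row, :], 50.0, axis=0)
        out[ch] = bands
    return out
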