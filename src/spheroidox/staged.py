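"""Staged calibration of the deoxygenation model.

The fifteen-parameter switching model is not fitted blind: the workflow
builds it up from simpler fits, each stage informing the next stage's
starting point and parameter box.

1. Fit a normal distribution to the first-day outer-radius measurements
   (normoxia) for R_o(0).
2. Per-spheroid snapshot inversions of the structure relations give R_c and
   Rbar for every phase-(ii)/(iii) spheroid in normoxia and hypoxia,
   summarised by fitted normals.
3. Full Bayesian calibration of the constant-environment model per condition
   (multistart MLE, then adaptive-Metropolis MCMC) yields the endpoint
   posteriors for s_n, s_h, lambda_n, lambda_h.
4. The switching data are analysed snapshot-by-snapshot: each post-switch
   spheroid gives an instantaneous estimate of the oxygen-gradient
   coefficient a(t) (equivalently the consumption rate, via the core
   relation with R_n taken at its quasi-steady value) and of Rbar(t) (via
   the inhibited-shell relation).  Fitting the exponential-relaxation form
   v_h + (v_n - v_h) exp(-(t - t_s)/tau) to these series by bounded global
   minimisation gives (a_n, a_h, tau_alpha) and (Rbar_n, Rbar_h, tau_Rbar).
5. The full parameter vector is fitted by multistart MLE and sampled by
   MCMC inside a box centred on the stage 1-4 estimates.
6. A posterior-predictive check reports the fraction of (non-outlier)
   observations inside the 95% prediction band.

Every stage's output is kept on the result object and can be serialised to
plain text for audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import differential_evolution

from .inference import (
    GREENSPAN_PARAM_NAMES,
    MleResult,
    fit_mle,
    filter_outliers,
    make_deoxygenation_model,
    make_greenspan_model,
)
from .mcmc import McmcConfig, McmcResult, prediction_intervals, run_mcmc
from .structure import Hypothesis, SpheroidStructure, snapshot_estimate

__all__ = ["StagedConfig", "StagedResult", "snapshot_series",
           "fit_relaxation", "staged_deoxygenation_calibration"]

DEOXY_PARAM_NAMES = (
    "R_o0", "a_n", "a_h", "tau_alpha", "Rbar_n", "Rbar_h", "tau_Rbar",
    "s_n", "s_h", "tau_s", "lam_n", "lam_h", "tau_lam", "lamhat0", "tau_lamhat",
)


@dataclass(frozen=True)
class StagedConfig:
    """Workflow settings; the MCMC profiles default to desk scale."""

    t_s: float = 2.0
    p_inf_pre: float = 21.0
    p_inf_post: float = 2.0
    greenspan_mcmc: McmcConfig = field(default_factory=lambda: McmcConfig(
        n_samples=4000, burn_in=1000))
    deoxy_mcmc: McmcConfig = field(default_factory=lambda: McmcConfig(
        n_samples=3000, burn_in=1000, adapt_start=300))
    n_starts: int = 6
    seed: int = 0
    greenspan_bounds_base: tuple = ((50.0, 400.0), (0.05, 2.0), (80.0, 500.0),
                                    (0.05, 3.0), (0.2, 1.0))


def _fit_normal(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    mu, sd = stats.norm.fit(values)
    return {"mean": float(mu), "sd": float(sd), "n": int(len(values))}


def snapshot_series(data: pd.DataFrame, p_inf) -> pd.DataFrame:
    """Per-row snapshot estimates of R_c, Rbar and the gradient coefficient.

    ``p_inf`` may be a scalar or a callable day -> ambient pressure (for
    switching protocols).  Rows whose phase does not permit an estimate carry
    NaN; outlier-flagged channels are not excluded here (filter first).
    """
    recs = []
    for _, row in data.iterrows():
        try:
            st = SpheroidStructure(R_o=row["R_o_um"], R_n=row.get("R_n_um", 0.0) or 0.0,
                                   R_i=row.get("R_i_um", 0.0) or 0.0)
        except ValueError:
            recs.append({"day": row["day"], "R_c": np.nan, "Rbar": np.nan, "a": np.nan})
            continue
        est = snapshot_estimate(st, hypothesis=Hypothesis.H2_WASTE_INHIBITION)
        p = p_inf(row["day"]) if callable(p_inf) else p_inf
        a = p / est.R_c**2 if np.isfinite(est.R_c) and est.R_c > 0 else np.nan
        recs.append({"day": float(row["day"]), "R_c": est.R_c, "Rbar": est.Rbar, "a": a})
    return pd.DataFrame(recs)


def fit_relaxation(days: np.ndarray, values: np.ndarray, t_s: float,
                   bounds: tuple, seed: int = 0, n_mcmc: int = 6000) -> dict:
    """Fit v(t) = v_h + (v_n - v_h) exp(-(t - t_s)/tau) to post-switch series.

    Bounded global least squares (differential evolution, deterministic per
    seed), followed by a short adaptive-Metropolis run on the concentrated
    Gaussian likelihood to quantify the (often substantial) uncertainty in
    the adaptation timescale.  ``bounds`` is ((v_n lo, hi), (v_h lo, hi),
    (tau lo, hi)).  Returns the point estimates, residual sd and per-
    parameter 95% credible intervals.
    """
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    keep = np.isfinite(values) & (days >= t_s)
    days, values = days[keep], values[keep]
    if len(values) < 4:
        raise ValueError("need at least 4 post-switch estimates to fit a relaxation")
    n = len(values)

    def sse(p):
        v_n, v_h, tau = p
        pred = v_h + (v_n - v_h) * np.exp(-(days - t_s) / tau)
        r = values - pred
        return float(r @ r)

    res = differential_evolution(sse, bounds=list(bounds), seed=seed, tol=1e-10,
                                 maxiter=400, polish=True)
    v_n, v_h, tau = res.x

    from .mcmc import adaptive_metropolis  # local import avoids a cycle

    barr = np.asarray(bounds, dtype=float)
    log_target = lambda p: -0.5 * n * np.log(max(sse(p) / n, 1e-300))
    x0 = np.clip(res.x, barr[:, 0], barr[:, 1])
    samples, _ = adaptive_metropolis(log_target, x0, barr, n_mcmc, seed=seed,
                                     adapt_start=300, adapt_interval=50)
    kept = samples[n_mcmc // 3:]
    ci = {name: tuple(np.percentile(kept[:, k], [2.5, 97.5]))
          for k, name in enumerate(("v_n", "v_h", "tau"))}
    return {"v_n": float(v_n), "v_h": float(v_h), "tau": float(tau),
            "resid_sd": float(np.sqrt(res.fun / max(len(values) - 3, 1))),
            "n": int(n),
            "ci95": {k: (float(lo), float(hi)) for k, (lo, hi) in ci.items()}}


@dataclass
class StagedResult:
    initial_radius_fit: dict
    snapshot_summaries: dict
    greenspan_normoxia: tuple      # (MleResult, McmcResult)
    greenspan_hypoxia: tuple
    alpha_relaxation: dict
    rbar_relaxation: dict
    deoxy_mle: MleResult
    deoxy_mcmc: McmcResult
    posterior_predictive_coverage: float
    config: StagedConfig

    def theta_d_summary(self) -> pd.DataFrame:
        return self.deoxy_mcmc.summary()

    def save(self, outdir) -> None:
        """Serialise every stage to plain text under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stage_meta = {
            "initial_radius_fit": self.initial_radius_fit,
            "snapshot_summaries": self.snapshot_summaries,
            "alpha_relaxation": self.alpha_relaxation,
            "rbar_relaxation": self.rbar_relaxation,
            "posterior_predictive_coverage": self.posterior_predictive_coverage,
            "deoxy_mle": self.deoxy_mle.as_dict(),
        }
        (outdir / "stages.json").write_text(json.dumps(stage_meta, indent=2))
        self.greenspan_normoxia[1].summary().to_csv(outdir / "greenspan_normoxia_posterior.csv")
        self.greenspan_hypoxia[1].summary().to_csv(outdir / "greenspan_hypoxia_posterior.csv")
        self.theta_d_summary().to_csv(outdir / "deoxygenation_posterior.csv")


def _calibrate_greenspan(data: pd.DataFrame, cfg: StagedConfig, seed: int,
                         R_o0_fit: dict, rc_fit: dict, rbar_fit: dict) -> tuple:
    bounds = np.asarray(cfg.greenspan_bounds_base, dtype=float).copy()
    # first-day radii bound R_o(0) from above only (growth is monotone in a
    # constant environment); the lower bound stays at the generic box edge
    bounds[0, 1] = min(bounds[0, 1], R_o0_fit["mean"] + 5 * max(R_o0_fit["sd"], 2.0))
    if np.isfinite(rc_fit.get("mean", np.nan)) and rc_fit.get("n", 0) >= 3:
        bounds[2] = (max(rc_fit["mean"] - 6 * max(rc_fit["sd"], 5.0), 40.0),
                     rc_fit["mean"] + 6 * max(rc_fit["sd"], 5.0))
    model = make_greenspan_model()
    mle = fit_mle(data, model, bounds, n_starts=cfg.n_starts, seed=seed,
                  param_names=GREENSPAN_PARAM_NAMES)
    mc = run_mcmc(data, model, bounds, mle, cfg=cfg.greenspan_mcmc, seed=seed,
                  param_names=GREENSPAN_PARAM_NAMES)
    return mle, mc


def staged_deoxygenation_calibration(
    normoxia_data: pd.DataFrame,
    hypoxia_data: pd.DataFrame,
    deoxy_data: pd.DataFrame,
    cfg: StagedConfig = StagedConfig(),
) -> StagedResult:
    """Run the six-stage deoxygenation calibration pipeline.

    The three tables use the standard measurement dialect.  Outliers are
    filtered per (condition, channel, day) before any fitting.  Stage
    failures raise with the stage named.
    """
    normoxia = filter_outliers(normoxia_data)
    hypoxia = filter_outliers(hypoxia_data)
    deoxy = filter_outliers(deoxy_data)
    seed = cfg.seed

    # --- stage 1: initial outer radius ---
    try:
        day1 = normoxia["day"].min()
        r_o0_fit = _fit_normal(normoxia.loc[
            (normoxia["day"] == day1) & ~normoxia["R_o_um_outlier"], "R_o_um"])
    except Exception as err:
        raise RuntimeError(f"stage 1 (initial radius fit) failed: {err}") from err

    # --- stage 2: snapshot inversions, per condition ---
    try:
        snaps = {}
        for label, tbl, p in (("normoxia", normoxia, cfg.p_inf_pre),
                              ("hypoxia", hypoxia, cfg.p_inf_post)):
            series = snapshot_series(tbl, p)
            snaps[label] = {
                "R_c": _fit_normal(series["R_c"].to_numpy()),
                "Rbar": _fit_normal(series["Rbar"].to_numpy()),
            }
    except Exception as err:
        raise RuntimeError(f"stage 2 (snapshot estimates) failed: {err}") from err

    # --- stage 3: constant-environment calibration per condition ---
    try:
        day1_h = hypoxia["day"].min()
        r_o0_h = _fit_normal(hypoxia.loc[
            (hypoxia["day"] == day1_h) & ~hypoxia["R_o_um_outlier"], "R_o_um"])
        g_n = _calibrate_greenspan(normoxia, cfg, seed, r_o0_fit,
                                   snaps["normoxia"]["R_c"], snaps["normoxia"]["Rbar"])
        g_h = _calibrate_greenspan(hypoxia, cfg, seed + 1, r_o0_h,
                                   snaps["hypoxia"]["R_c"], snaps["hypoxia"]["Rbar"])
    except Exception as err:
        raise RuntimeError(f"stage 3 (Greenspan calibration) failed: {err}") from err

    # --- stage 4: adaptation-timescale fits from switching snapshots ---
    try:
        p_of_day = lambda d: cfg.p_inf_pre if d < cfg.t_s else cfg.p_inf_post
        series = snapshot_series(deoxy, p_of_day)
        a_vals = series["a"].to_numpy()
        a_hi = np.nanmax(a_vals) * 3.0 if np.isfinite(a_vals).any() else 1.0
        alpha_fit = fit_relaxation(
            series["day"].to_numpy(), a_vals, cfg.t_s,
            bounds=((1e-6, a_hi), (1e-6, a_hi), (0.02, 10.0)), seed=seed)
        rb_vals = series["Rbar"].to_numpy()
        rb_hi = np.nanmax(rb_vals) * 2.0 if np.isfinite(rb_vals).any() else 500.0
        rbar_fit = fit_relaxation(
            series["day"].to_numpy(), rb_vals, cfg.t_s,
            bounds=((20.0, rb_hi), (20.0, rb_hi), (0.02, 10.0)), seed=seed)
    except Exception as err:
        raise RuntimeError(f"stage 4 (relaxation fits) failed: {err}") from err

    # --- stage 5: full deoxygenation model fit + MCMC ---
    try:
        gn_sum = g_n[1].summary()
        gh_sum = g_h[1].summary()
        gn_mean, gh_mean = gn_sum["mean"], gh_sum["mean"]
        s_n, s_h = gn_mean["s"], gh_mean["s"]
        lam_n = gn_mean["gamma"] * gn_mean["s"]
        lam_h = gh_mean["gamma"] * gh_mean["s"]
        # stage 1 estimates the radius at the first sampling day; the model's
        # R_o(0) is taken from the normoxia calibration (same time origin as
        # the pre-switch segment), with stage 1 providing the sanity scale
        R_o0_centre = float(gn_mean["R_o0"])
        R_o0_sd = max(float(gn_sum["sd"]["R_o0"]), 2.0)
        # the pre-switch endpoint of the gradient coefficient is poorly
        # constrained by post-switch snapshots; anchor it with the normoxia
        # critical-radius calibration a_n = p_pre / R_c_n^2
        a_n_anchor = cfg.p_inf_pre / float(gn_mean["R_c"]) ** 2
        centre = np.array([
            R_o0_centre, a_n_anchor, alpha_fit["v_h"], alpha_fit["tau"],
            rbar_fit["v_n"], rbar_fit["v_h"], rbar_fit["tau"],
            s_n, s_h, 1.0, lam_n, lam_h, 1.0, 0.5, 1.0,
        ])
        lo = centre * 0.4
        hi = centre * 2.5
        # timescales and the shell-death rate get broad dedicated boxes
        for j in (3, 6, 9, 12, 14):
            lo[j], hi[j] = 0.02, 10.0
        lo[13], hi[13] = 1e-3, 5.0
        lo[0] = max(R_o0_centre - 8 * R_o0_sd, 10.0)
        hi[0] = R_o0_centre + 8 * R_o0_sd
        bounds_d = np.column_stack([lo, hi])
        model_d = make_deoxygenation_model(t_s=cfg.t_s, p_pre=cfg.p_inf_pre,
                                           p_post=cfg.p_inf_post)
        mle_d = fit_mle(deoxy, model_d, bounds_d, n_starts=max(cfg.n_starts // 2, 2),
                        seed=seed + 2, param_names=DEOXY_PARAM_NAMES,
                        x0=np.clip(centre, lo, hi))
        mc_d = run_mcmc(deoxy, model_d, bounds_d, mle_d, cfg=cfg.deoxy_mcmc,
                        seed=seed + 3, param_names=DEOXY_PARAM_NAMES)
    except Exception as err:
        raise RuntimeError(f"stage 5 (full deoxygenation fit) failed: {err}") from err

    # --- stage 6: posterior-predictive coverage ---
    try:
        days = np.sort(deoxy["day"].unique().astype(float))
        bands = prediction_intervals(mc_d, model_d, days, n_draws=300, seed=seed + 4)
        day_pos = {d: j for j, d in enumerate(days)}
        inside = total = 0
        for ch, col in (("R_o", "R_o_um"), ("R_i", "R_i_um"), ("R_n", "R_n_um")):
            lo95, hi95 = bands[ch][95.0]
            keep = deoxy[col].notna() & ~deoxy[f"{col}_outlier"]
            for _, row in deoxy.loc[keep].iterrows():
                j = day_pos[float(row["day"])]
                total += 1
                inside += int(lo95[j] <= row[col] <= hi95[j])
        coverage = inside / total if total else np.nan
    except Exception as err:
        raise RuntimeError(f"stage 6 (posterior predictive) failed: {err}") from err

    return StagedResult(
        initial_radius_fit=r_o0_fit, snapshot_summaries=snaps,
        greenspan_normoxia=g_n, greenspan_hypoxia=g_h,
        alpha_relaxation=alpha_fit, rbar_relaxation=rbar_fit,
        deoxy_mle=mle_d, deoxy_mcmc=mc_d,
        posterior_predictive_coverage=coverage, config=cfg,
    )
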