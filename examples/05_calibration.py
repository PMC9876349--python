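"""Calibrating the growth model to a synthetic study-design dataset.

Draws a normoxia-design measurement table (5 sampling days x 12 spheroids,
sigma = 4 um noise), filters outliers by the quartile rule, fits the five
model parameters by multistart maximum likelihood, profiles the
proliferation rate for a 95% confidence interval, and runs a short
adaptive-Metropolis calibration with the Gelman-Rubin diagnostic.
"""

import numpy as np

from spheroidox import (
    McmcConfig,
    filter_outliers,
    fit_mle,
    generate_dataset,
    ground_truth_bundle,
    make_greenspan_model,
    profile_likelihood,
    run_mcmc,
)
from spheroidox.inference import GREENSPAN_PARAM_NAMES

BOUNDS = [(50, 400), (0.05, 2.0), (80, 500), (0.05, 3.0), (0.2, 1.0)]

truth, design = ground_truth_bundle("normoxia_like")
data = filter_outliers(generate_dataset(truth, design, seed=11))
model = make_greenspan_model()

mle = fit_mle(data, model, BOUNDS, n_starts=8, seed=1,
              param_names=GREENSPAN_PARAM_NAMES)
print("maximum-likelihood estimates (truth in parentheses):")
for name, val, tv in zip(GREENSPAN_PARAM_NAMES, mle.theta, truth.as_array()):
    print(f"  {name:5s} = {val:9.4f}   ({tv})")
print(f"  residual noise scale sigma_hat = {mle.sigma_hat:.2f} um "
      f"(generated with 4 um)")

grid = np.linspace(mle.theta[1] - 0.04, mle.theta[1] + 0.04, 15)
pr = profile_likelihood(data, model, mle, 1, BOUNDS, grid=grid, param_name="s")
print(f"\nprofile likelihood for s: 95% CI [{pr.ci95[0]:.4f}, {pr.ci95[1]:.4f}] "
      f"/day — a narrow, single-peaked profile means s is practically "
      "identifiable from this design")

res = run_mcmc(data, model, BOUNDS, mle,
               cfg=McmcConfig(n_samples=4000, burn_in=1000), seed=3,
               param_names=GREENSPAN_PARAM_NAMES)
print("\nposterior summary (4 chains x 4000, 1000 burn-in):")
print(res.summary().round(4))
print(f"max Rhat = {float(res.rhat().max()):.4f} "
      "(values below 1.1 indicate converged chains)")
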