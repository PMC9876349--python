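# Methods

## Model assumptions

All models assume a spherically symmetric spheroid held together by
adhesion/surface tension, with radial position r [μm] and time t [days].
Oxygen and metabolic-waste transport are quasi-steady: diffusion across a
spheroid takes seconds, growth takes days, so at every instant the fields
solve their steady reaction–diffusion problems with the current radii as
parameters. Oxygen is consumed at a constant volumetric rate by living cells
only; waste is produced at a constant rate by living cells only. The
necrotic threshold is p_n = 0 (supported by the snapshot analysis), the
inhibited boundary is set by a waste threshold (the waste interpretation of
the model; the oxygen-threshold interpretation differs only in how the
formation radius R̄ is constructed, R̄² = R_c²Q² with
Q² = (p∞ − p_i)/p∞, and is supported by the same solver).

The lumped parameterisation keeps the package unit-safe: the oxygen field
depends only on a = Ωα/(6k) [%·μm⁻²] (equivalently R_c = √(p∞/a)), the
waste field only on P/(6κ) (equivalently R̄). The SI constants k [m²/s],
Ω [mmHg·kg/m³] and the %→mmHg conversion (default 7.6 mmHg per % O2, i.e.
760 mmHg at 100%) enter only through the explicit conversion helpers
`critical_radius_from_constants` / `alpha_from_critical_radius`, and are
caller-supplied — no literature constants are hard-coded. The waste surface
condition β(R_o) = 0 is adopted because the inhibited-shell relation is
exactly the r = R_i evaluation of the waste field under that condition.
The pimonidazole threshold p_hyp for the hypoxic radius is configurable
(default 1.5% in the synthetic designs); it is a staining property, not a
model constant.

## Parameters

| symbol | meaning | units | typical (presets) |
|---|---|---|---|
| R_o(0) | initial outer radius | μm | 97–130 |
| s | living-cell volume production rate | day⁻¹ | 0.6–0.75 |
| λ = γs | volume-loss rate from the necrotic core | day⁻¹ | 0.36–1.4 |
| R_c | outer radius at necrotic-core formation | μm | 150 (2% O2) – 250 (21% O2) |
| R̄ = Q·R_c | outer radius at inhibited-region formation | μm | 140–230 |
| τ_α, τ_R̄, τ_s, τ_λ | adaptation timescales after a switch | days | 0.23–1 |
| λ̂, τ_λ̂ | shell-death rate scale and e-folding time (deoxygenation) | day⁻¹, days | 2, 0.3 |
| λ̃, τ_λ̃, ν | shell-clearance rate, e-folding time, recovered fraction (re-oxygenation) | day⁻¹, days, – | 20, 0.2, 0.75 |

Switching-model endpoints carry condition subscripts (n = normoxia,
h = hypoxia); the deoxygenation model relaxes n → h, re-oxygenation h → n.
The ambient pressures and switch time (21%, 2%, t_s = 2 d) are protocol
fields, not fitted parameters, giving 15 free parameters for deoxygenation
(Θ_d) and 17 for re-oxygenation (Θ_r, which adds R_n(0) and ν, λ̃, τ_λ̃ in
place of λ̂, τ_λ̂).

## Numerics

The growth system is a DAE of index 1 with algebraically unique inner radii,
so it is integrated as an ODE in R_o with the constraints resolved by
root-finding inside the right-hand side. Both structure relations are
monotone in the unknown on the valid bracket; roots are found by Brent's
method to 1e-9 μm (reference path) or safeguarded Newton with bisection
fallback (compiled path). Ties at phase boundaries resolve to the smaller
region (R_n = 0 exactly at R_o = R_c). Noisy measured tables may contain
R_i < R_n; such rows are kept but R_i is clipped to R_n for profile
evaluation, with a warning.

Two integration paths exist deliberately. The reference path
(`solve_greenspan`) uses scipy's LSODA with rtol 1e-8 / atol 1e-10 and event
detection (sign changes of R_o − R̄ and R_o − R_c) to locate formation times
to 1e-6 days. The compiled path (`_kernels`, numba) advances R_o by
classical RK4 at fixed step (default 5e-3 d; 1e-2 d inside likelihoods) and
is what the calibration loops call — roughly three orders of magnitude
faster per solve. Agreement between the two is asserted in the tests at the
μm·1e-3 level on the study horizon.

The switching models add the core-volume state V_n with
R_n = (3V_n/4π)^{1/3}. Because λ̂/λ̃ grow exponentially, the V_n equation
becomes arbitrarily stiff at late times; V_n is therefore advanced with an
exact exponential step of its locally linear form dV/dt = A(t) − B(t)V,
Strang-split around the R_o step. The step is unconditionally stable and
lands on the quasi-steady volume in the stiff limit, which is precisely the
model's intended late-time behaviour (R_n → R_n⁺). The λ̂/λ̃ shell terms act
on the volume difference clamped at zero, so shells never go negative. A
dynamic core below 0.01 μm is reported as absent: the cleared core decays
double-exponentially and never reaches exactly zero, and the floor gives
phase classification a well-defined formation/clearance event. After a
re-oxygenated core has crossed below the quasi-steady radius, the reported
core is max(dynamic, quasi-steady): clearance complete, the model reduces to
the plain algebraic core, which is how re-formation at late times is
handled without introducing a stiff re-formation rate.

Re-oxygenation volume bookkeeping: the cleared-shell rate is
3λ̃(t)[V_n − V⁺]₊; a fraction ν converts necrotic → living in place (no
change to total volume), and (1 − ν) leaves the spheroid, entering the outer
balance as −(1 − ν)·3λ̃[V_n − V⁺]₊/(4πR_o²). With ν = 1 the outer balance
reduces exactly to its s and λ terms — the conservation audit in the tests.
Whether λ acts on the whole core or only its still-anoxic part is not
observable at these designs; the implementation applies it to the whole
core. When a trajectory starts before the switch, the pre-switch segment is
the plain constant-environment model with the "from"-endpoints; R_o and V_n
carry over continuously at t_s, and for re-oxygenation the supplied R_n(0)
sets the core at the switch when it exceeds (or the grid starts at) the
quasi-steady value.

## Statistical workflow

Observation model: iid additive Gaussian noise on each radius, one shared σ
across R_o, R_n, R_i by default (per-channel σ is a config option); missing
entries contribute nothing; the hypoxic radius R_p is used for snapshot
validation only and never enters a fitting likelihood. Outliers are flagged
per (condition, channel, day) by the 1.5·IQR quartile rule with type-7
(linear-interpolation) quartiles; the 1.5·IQR rule is the contract, the
quartile convention a documented choice. When σ is not fixed it is profiled
analytically in optimisation and sampled by its conjugate inverse-gamma
conditional in MCMC (prior weight n₀ = 1, scale the MLE mean squared
error).

MLE is multistart Nelder–Mead from a Latin-hypercube sample of the bounded
box, deterministic per seed. Profiles re-optimise nuisances per grid point,
warm-started sweeping outward from the MLE; the 95% interval is the
−1.9207 cutoff (χ²(1), 95%) with linear interpolation at the crossings,
refined by exact root-finding when the model has no nuisance parameters.
Priors are uniform on the same boxes. The sampler is Haario adaptive
Metropolis: proposal covariance 2.38²/d times the covariance of the second
half of the chain history (re-estimated every 100 iterations after 500),
plus a small diagonal jitter; adapting on the second half avoids the
cold-start shrinkage that otherwise traps short chains. Acceptance rates
outside [0.05, 0.6] raise a warning on the result.

R̂ convention: with m chains of length n, within-chain variance W and
between-chain variance of means B/n, the package reports
R̂ = √(1 + B/(nW)) — the variance-ratio statistic without the (n−1)/n
finite-sample deflation, so identical chains give exactly 1.0. This is
marginally more conservative (larger) than the deflated form; the
convergence rule R̂ < 1.1 is unaffected.

Problem sizes: the default MCMC profile is 4 chains × 20,000 samples with
5,000 burn-in, which calibrates the five-parameter growth model on a
study-design dataset in about a minute and reaches max R̂ ≈ 1.001; the
study-scale profile (4 × 250,000 / 50,000, `McmcConfig.paper_scale()`) is a
flag away. The staged deoxygenation workflow defaults to shorter chains per
stage; at those sizes the full 15-parameter posterior is not yet converged
(R̂ well above 1.1 on several coordinates) and its summaries should be read
as workflow output, not final inference — the study-scale profile exists
for that.

Staged calibration notes: stage 1 fits a normal to the first-day outer
radii, which estimates the radius at the first sampling day, not the model's
R_o(0); it therefore only caps the R_o(0) box from above (growth is
monotone), and stage 5 centres R_o(0) on the stage-3 normoxia posterior
instead. The pre-switch gradient-coefficient endpoint a_n is likewise
anchored by the normoxia critical-radius calibration, because post-switch
snapshots cannot constrain it: with end-point sampling at whole days and
adaptation timescales near 0.23 d, the exponential has essentially fully
relaxed by the first post-switch observation. For the same reason the
stage-4 relaxation fits carry adaptive-Metropolis 95% credible intervals —
the point estimate of τ alone is near-degenerate under these designs, and
the interval is the honest summary.

## What the synthetic data does and does not emulate

The generator reproduces the end-point (cross-sectional) structure of the
experiments: independent spheroids per sampling day, additive Gaussian
radius noise (default σ = 4 μm, the scale of the within-day scatter the
designs assume), structural radii recorded as 0 before the region forms,
optional injected outliers (multiplicative, for exercising the filter), and
the per-condition day layouts. The preset parameter bundles are regression
fixtures at magnitudes seen in these melanoma spheroid systems (radii
100–400 μm, rates below ~1/day), chosen so the switching presets exhibit
the qualitative phenomenology by construction — deoxygenation: R_n⁺ > R_n at
the switch, near-constant outer radius while ξ_n rises to its hypoxia
value; re-oxygenation: full reverse phase traversal. They are not estimates
of any real cell line.

Not emulated: biological between-spheroid variability (one ground-truth
trajectory per condition — real spheroids vary in R_o(0) and rates);
measurement error that grows with radius or correlates across channels of
the same spheroid; missing-data mechanisms tied to imaging failures; and
any loss of spherical symmetry (the observed necrotic-core migration and
expulsion after re-oxygenation in one cell line is outside the model class
by construction and is not simulated). Passing tests therefore demonstrate
correctness of the algorithms under the stated error model, not robustness
to these real-data features.

## Known limitations

- The re-oxygenation system is constructed by strict analogy with the
  deoxygenation equations under the three stated mechanisms (shell
  clearance at λ̃, ν-fraction recovery, h → n relaxation); it is isolated
  behind the `adaptation` module boundary so an alternative bookkeeping can
  be swapped in.
- Fixed-step RK4 crosses phase-onset kinks within a step; the resulting
  error is far below measurement noise at the default steps but the
  reference solver should be used when event times themselves are the
  quantity of interest.
- The deoxygenation model inherits the convention R_n(t_s) = R_i(t_s) = 0
  as its default calibration state at t_s = 2 d; both carry over from the
  pre-switch segment automatically for other switch times.
- Per-spheroid random effects and model selection across the two inhibition
  interpretations are out of scope.
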