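# Methods

This note documents the model, the numerical choices and the design
decisions behind `bufferguts`, and what the synthetic-data tests do and do
not demonstrate.

## Model structure and assumptions

The package models time-resolved survival of arthropod cohorts exposed to a
single substance via `N ≥ 1` uptake routes. All routes are assumed to share
one mode of action, so route contributions combine additively (mixture
theory for similar modes of action); "independent joint action" combination
is deliberately out of scope. Exposure enters through a per-route buffer
state `B_i` (exoskeleton residue, gut content):

    dB_i/dt = η (C_i(t) − B_i),  B_i(0) = 0.

The buffer stage is a first-order relaxation toward the current external
level — the simplest operator consistent with a buffer that is loaded by
discrete exposure events and releases to the organism. It preserves the
family's defining structural properties: linearity of the cascade (hence
superposition and the unit-anchoring invariance), the stated free-parameter
counts, and the equivalence of summing before or after the damage stage
when kinetics are shared. It is isolated in one function
(`core._damage_step` plus the per-segment buffer update), so replacing it
with a different buffer law is a one-place change.

Scaled damage `D` is expressed in route-1 exposure units. Under
concentration addition (CA) a single dominant rate constant `k_d` acts on
the weighted buffer sum; under damage addition (DA) each route has its own
`k_d,i` and the per-route damages are summed with the same weights. With
`w_1 ≡ 1` the weights are identifiable and all thresholds are anchored to
route-1 units. For `N = 1`, CA and DA are algebraically identical, and when
all DA rate constants coincide DA collapses to CA exactly (both are
enforced by tests at 1e-10 / 1e-8).

Death mechanisms operate on the combined damage only (they are
route-agnostic):

* **SD** — hazard `k_k · max(0, D − z) + h_b`; killing rate `k_k`
  [1/(route-1 unit · d)], threshold `z` [route-1 units].
* **IT** — log-logistic individual thresholds, median `α` [route-1 units],
  shape `β` [–]; the running maximum of `D` determines the fraction killed.
  The running maximum is over the combined damage, not per route.

A single background hazard `h_b` [1/d] is shared by all treatments of a
calibration.

## Parameters and defaults

| parameter | units | default / prior | notes |
|---|---|---|---|
| η | 1/d | fixed 2.0 | structural constant of the buffer stage, never calibrated; 2.0/d is a placeholder on the timescale of acute effects (buffer turnover ≈ half a day) and is configurable |
| k_d (, k_d,i) | 1/d | log-normal, median 1, σ=1.5 | dominant rate constant(s) |
| w_i (i>1) | route-1 unit / route-i unit | log-normal, median 20, σ=1.5 (generic) | for the honeybee contact+oral convention the equal-potency value is 0.02 µg bee⁻¹ per mg kg⁻¹ (20 mg food/bee); pass `scale=` overrides |
| z, α | route-1 units | log-normal, median 0.1, σ=1.5 | SD threshold / IT median |
| k_k | 1/(route-1 unit · d) | log-normal, median 1, σ=1.5 | SD killing rate |
| β | – | log-normal, median 3, σ=1.5 | IT shape |
| h_b | 1/d | log-normal, median 0.01, σ=1.5, or fixed | background hazard |

Priors are calibration configuration, not part of the model; the defaults
are weakly informative order-of-magnitude statements and should be adapted
to the exposure units at hand (the worked examples override the medians for
`w_2`, `z`, `k_k` to honeybee scales).

## Exposure conventions

Internal time unit is days; the exposure discretization grid is 1 h =
1/24 d; segments are half-open `[t_start, t_end)`. Instantaneous
applications (topical doses) are modelled as 1-h pulses at the nominal
level, preserving one dose-hour of area under the curve. Acute-oral feeding
is a single window of up to 6 h (default 6 h when unreported); chronic oral
exposure is one constant segment over the whole test despite daily food
replenishment. Acute-oral doses (µg a.i./bee) are converted to food
concentrations (mg a.i./kg food) by dividing by the food consumed during
feeding, default 20 mg/bee (overridable per test). The conversion is linear
and invertible.

The acute-oral outlier rule excludes a test iff its 48-h LD50 differs by a
factor ≥ 8 from **every** other acute-oral test of the same compound
("each other" rather than a group mean; configurable) **and** its food-scale
LC50 is strictly below the compound's chronic 10-day LC50 ("considerably
lower" operationalized as strictly lower; threshold configurable). On the
bundled endpoint table this flags exactly three tests and retains 26.

## Numerics

* **States.** Exposure is piecewise constant and the cascade is linear, so
  `B` and `D` have an exact two-exponential closed form per segment; the
  default backend propagates it segment-by-segment, vectorized over
  evaluation times. The `k_d = η` resonance switches to the
  `τ·exp(−k_d τ)` limit at relative distance 1e-9. A stitched
  `scipy.integrate.solve_ivp` (LSODA, rtol 1e-10) backend is retained
  purely as an independent cross-check; tests require agreement to 1e-6
  relative on randomized instances.
* **SD hazard integral.** Exact on the piecewise-linear interpolant of `D`
  over the evaluation grid; within-interval threshold crossings are solved
  linearly, so the integral has no quadrature error beyond the grid
  resolution of `D` itself. The default grid is the union of exposure
  breakpoints, observation times and an hourly grid.
* **Likelihood.** Interval-censored multinomial kernel per treatment
  (deaths per observation interval + final survivors), with interval
  probabilities floored at 1e-12 before the log. The kernel omits the
  parameter-independent combinatorial coefficient; it is exactly additive
  over replicate batches, so summing replicates changes nothing.
* **MCMC.** Independent adaptive random-walk Metropolis chains in
  log-parameter space: 2.38/√d proposal scaling, empirical-covariance
  (Haario-type) adaptation during warm-up with an acceptance-targeted
  global factor (target 0.3, updated every 50 steps), proposal frozen for
  the sampling phase. Defaults: 16 chains, 2000 warm-up + 2000 draws;
  chain seeds are spawned from one `SeedSequence`. Chains are genuinely
  independent, which the chain filter requires. An ensemble sampler
  (emcee) run on the identical log-posterior serves as an independent
  cross-check of posterior quantiles in the test suite.
* **Chain filter.** A chain is dropped if any parameter's within-chain
  standard deviation is ≤ 1e-6 (frozen sampler) or its mean log-likelihood
  is more than 100 % worse than the best chain's mean
  (`mean < best − |best|`; multiplier configurable). The scale choice
  (log-likelihood rather than likelihood) targets the removal of
  pseudolocal modes; the best chain is always retained. Posterior
  quantiles (2.5/50/97.5 %) pool draws of kept chains only.
* **Selection metrics.** `BIC = k ln n − 2 logL` with `n` = number of
  post-t0 survival observations (time points × treatments after replicate
  summation; the t=0 baseline is not a random outcome) and `logL` the
  posterior-median-parameter log-likelihood in Bayesian mode (the maximum
  in ML mode); both conventions are documented here because `n` and the
  Bayesian plug-in are not uniquely determined by the formulas. NRMSE is
  RMSE of survivor counts normalized by the mean observed count; its
  uncertainty interval is posterior-parameter based (NRMSE recomputed over
  a posterior subsample), one of the two defensible conventions. PUI is
  the mean log10 quantile ratio over the non-background parameters. BIC
  ranking across datasets is rejected by the API.
* **Variant choice.** Screen on NRMSE and BIC (comparable = overlapping
  95 % NRMSE intervals when available, else an absolute NRMSE tolerance of
  0.02, and BIC within 2 of the best); among comparable candidates pick
  the lowest PUI, then the fewest free parameters. A rationale trail is
  returned.

## Synthetic data

The generator emulates honeybee standard designs: acute contact (1-h
pulse, 2-d daily observations), acute oral (6-h feeding, 2-d), chronic
oral (constant 10-d exposure, daily observations), batches of 10 bees
(default 4 batches per treatment). Concentration ladders are geometric
(factor 2) around the level giving 50 % end-of-test mortality under the
generating parameters, mirroring regulatory dose-ranging. Default
generating parameters (`default_true_params`) are honeybee-plausible:
k_d = 0.7/d, w₂ = 0.02 (equal potency under 20 mg food/bee), z = 0.002 µg
a.i./bee, k_k = 400 /(µg a.i./bee·d) (IT: α = 0.004, β = 2.5), h_b = 0 so
that studies isolate the substance effect. Death counts are drawn by
sequential conditional binomials from the model survival curve — exactly
the sampling model the likelihood assumes.

Consequently, passing recovery tests demonstrate internal consistency of
the simulate → likelihood → sampler → filter pipeline (correct coverage
under the assumed model), **not** robustness to features of real data the
generator omits: food avoidance and consumption decline at high
concentrations, between-batch heterogeneity, observation-time jitter, or
model misspecification of the buffer/damage kinetics.

The parameter-recovery check runs 20 seeded studies (3 designs × 5 levels ×
40 bees) with a reduced sampler (4 chains × 500+500) and requires every
generating parameter inside its 95 % credible interval in ≥ 90 % of runs;
these problem sizes keep the full suite fast while leaving the binomial
counting error of the coverage estimate acceptable.

## Validation scenarios

`make_validation_suite` emits the proposed combined-exposure validation
grid: one 1-h contact pulse at t = 0 crossed with oral windows of 1 and
2 days (durations deliberately absent from the calibration designs) at
inter-peak delays of 0–7 days. Default levels follow the worked pyrethroid
example (0.12 µg a.i./bee contact, 20 mg a.i./kg food oral).

## Known limitations

* The buffer law and η = 2.0/d are structural commitments, not calibrated
  quantities; species- or substance-specific buffer kinetics require
  changing one function and one constant.
* The SD hazard is resolved at the evaluation-grid scale; pathological
  damage traces varying much faster than 1 h would need a finer grid.
* Adaptive Metropolis mixes more slowly than gradient-based samplers on
  strongly correlated posteriors; the PUI and the emcee cross-check guard
  against silent failure, but long chains remain advisable for production
  calibrations.
* No species-specific preprocessing (fixed absorption assumptions), no
  independent-joint-action mixtures, and no use of measured internal
  concentrations (reduced-GUTS setting only).
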