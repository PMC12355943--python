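# bufferguts

Toxicokinetic–toxicodynamic (TKTD) survival modelling for terrestrial
arthropods exposed to a chemical via **multiple uptake routes** — typically
contact (topical) and oral (dietary) exposure in honeybee regulatory tests.
The package implements a buffered variant of the reduced General Unified
Threshold model of Survival (GUTS) that combines routes by **concentration
addition (CA)** or **damage addition (DA)** and couples damage to either the
**stochastic death (SD)** or the **individual tolerance (IT)** mechanism. It
is aimed at ecotoxicologists who want to calibrate one mechanistic survival
model to all available acute-contact, acute-oral and chronic-oral data for a
species/substance combination and then predict survival under non-standard,
combined exposure scenarios.

## Model

For each uptake route *i* with external exposure *C<sub>i</sub>(t)* (piecewise
constant, smallest time unit 1 h), a buffer state *B<sub>i</sub>* represents
residues on the exoskeleton or in the gut:

    dB_i/dt = η (C_i(t) − B_i),          B_i(0) = 0

with a fixed buffer speed constant η. Scaled damage *D* (in route-1 exposure
units) follows:

* **CA** — one shared dominant rate constant acting on the weighted buffer
  sum: `dD/dt = k_d (Σ_i w_i B_i − D)`
* **DA** — route-specific kinetics, summed afterwards:
  `dD_i/dt = k_d,i (B_i − D_i)`, `D = Σ_i w_i D_i`

with weights *w* (w₁ ≡ 1) converting route-*i* units into route-1 units.
Mortality follows either mechanism:

* **SD**: hazard `h(t) = k_k · max(0, D − z) + h_b`, so
  `S(t) = exp(−∫₀ᵗ h dτ)`
* **IT**: individual thresholds are log-logistic (median α, shape β);
  `S(t) = (1 − F(max_{τ≤t} D(τ))) · exp(−h_b t)`

Free parameters: 3 for one route; CA adds one weight per extra route
(N + 2), DA adds a weight and a rate constant (2N + 1); background hazard
*h<sub>b</sub>* is the "+1". Because exposure is piecewise constant and the
cascade is linear, the package solves the states with an exact
per-segment two-exponential closed form (a numeric ODE backend is kept as a
cross-check). Calibration is Bayesian (independent adaptive-Metropolis
chains over log-parameters with the stuck-chain filter) or maximum
likelihood, against the interval-censored multinomial survival likelihood.
Variants are compared with BIC, NRMSE and the parameter uncertainty index
(PUI).

## Worked example

Generate a synthetic honeybee-style study (acute contact, acute oral and
chronic oral designs, 40 bees per treatment, geometric concentration
ladders) from known parameters and recover them:

```python
from bufferguts import BufferGUTS, ModelSpec, SamplerSettings
from bufferguts.sampling import default_priors
from bufferguts.synth import default_templates, default_true_params, generate

spec = ModelSpec("CA", "SD", n_routes=2)             # contact + oral, SD
truth = default_true_params(spec)                    # kd=0.7/d, w2=0.02, z=0.002, kk=400
dataset = generate(spec, truth, default_templates(spec, truth), seed=11)

priors = default_priors(spec, include_hb=False,
                        scale={"w_2": 0.02, "z": 0.01, "kk": 50.0})
model = BufferGUTS(dataset, spec, priors=priors, fixed_hb=0.0)
res = model.fit(settings=SamplerSettings(n_chains=4, warmup=500, draws=500),
                seed=11)
print(res.summary())
```

prints (abridged):

```
Buffered GUTS survival model results
====================================================
Variant:        CA-SD  (routes: 2, eta=2.0/d)
Method:         mcmc
Treatments:     18
Observations:   84
Free params k:  4  (hb fixed at 0.0)
Log-likelihood: -315.504
BIC:            648.731
NRMSE:          4.72%
Chains kept:    4/4
PUI:            0.193

          mean       q2.5        q50      q97.5
kd     0.79060    0.65267    0.75673    1.28090
w_2    0.02324    0.02085    0.02314    0.02570
z      0.00246    0.00220    0.00246    0.00277
kk   328.25434  210.99699  334.12286  411.05430
```

The posterior medians sit close to the generating values (k_d = 0.7/d,
w₂ = 0.02, z = 0.002 µg a.i./bee, k_k = 400 /(µg a.i./bee · d)); the NRMSE
of ~5% of the mean observed survivor count says the fitted curves track the
counts closely, and all 4 chains passed the stuck/pseudolocal filter.

The same workflow is scriptable from the shell (`bufferguts synth`,
`calibrate`, `select`, `predict-unseen`, `predict-scenarios` — see
`bufferguts --help`), and the bundled honeybee endpoint table is available
as `bufferguts.honeybee_regulatory_tests()` for the unit-conversion and
outlier-exclusion preprocessing utilities.

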