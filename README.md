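# occabund

Integrated Bayesian occupancy-to-abundance modelling for species with very
low capture probability.

## The problem

Managers of endangered small mammals — the motivating system is a
heteromyid pocket mouse monitored across three coastal Southern California
subpopulations — need population abundance estimates, but per-occasion
live-trap capture probabilities of ~0.05 make direct density estimation
prohibitively expensive at landscape scale. Presence–absence monitoring
with track tubes is cheap and spatially extensive but does not by itself
yield abundance. `occabund` links the two: it fits, in one joint Bayesian
model,

* a **Huggins closed-population capture–recapture** model for density on
  the few live-trapped plots, with a Poisson partition
  `N = M + f`, `M ~ Poisson(λ p*)`, `λ = D̄·A`, and an effective trapped
  area `A = (L² + 4L·d/2 + π(d/2)²)·10⁻⁴` ha;
* a **single-season occupancy** model with a finite-population correction:
  the realized proportion of subplots occupied `Ψ = (s* + u)/s`, with
  `u ~ Binomial(s − s*, ψᶜ)` latent undetected-occupied subplots;
* the **hyper model** — the core contribution — regressing log expected
  density on the square roots of PSO and per-check detection probability:

  `log D̄ᵢ = β₀ + β₁√Ψᵢ + β₂√ρᵢ + εᵢ`, `εᵢ ~ N(0, σ_ε²)`.

The fitted relationship transfers density information from trapped plots to
tube-only plots, and representative resampling extends predictions to
unmonitored hectares, so subpopulation abundance comes with honest
uncertainty. Everything runs at two timescales: monthly (April–July
"snapshots") and the pooled 4-month season.

Who it is for: quantitative ecologists and monitoring-programme analysts
with collated capture/detection summaries (or the bundled synthetic-data
generator) who want density predictions from occupancy data.

## Worked example

```python
import occabund as oa

# a synthetic monitoring world at desk scale (8 plots x 2 years,
# 32 tube subplots per plot, 3 live-trapped core plots)
captures, tubes, registry, truth = oa.simulate(oa.preset("desk_small"), seed=1)

model = oa.IntegratedAbundanceModel.from_raw(captures, tubes, registry,
                                             timescale="short")
result = model.fit(chains=3, iterations=5000, seed=1)
print(result.summary(["beta0", "beta1", "beta2", "sigma_eps",
                      "mu_p", "mu_rho", "mu_psi"]))
```

prints (posterior mean, SD, central 90% credible interval, split R-hat):

```
                mean        sd       q05       q95      rhat
parameter
beta0      -2.138589  0.876619 -3.515552 -0.694201  1.008320
beta1       2.407050  1.493836 -0.195072  4.772688  1.010763
beta2       2.745059  1.560083  0.159400  5.321989  1.001825
sigma_eps   1.164092  0.205645  0.802928  1.460173  1.001796
mu_p       -2.412772  0.648332 -3.454861 -1.323532  1.001737
mu_rho     -0.082795  0.401689 -0.724285  0.590957  1.001255
mu_psi      0.067825  0.418624 -0.606269  0.755586  1.003781
```

Read: both hyper-model slopes are positive — density rises with occupancy
(β₁) and with detection (β₂) — and every generating value (β₁ = 3.15,
β₂ = 3.14, μ_p = logit 0.05 ≈ −2.94, μ_ρ = logit 0.47 ≈ −0.12,
μ_ψ = logit 0.59 ≈ 0.36) sits inside its 90% interval; R-hat < 1.1
throughout indicates the three chains agree. Abundance predictions then
follow from the fitted object:

```python
import numpy as np
frame = oa.SubpopulationFrame({"Oscar": 411, "Edson": 474, "SSM": 105})
totals = result.predict_abundance(frame, rng=np.random.default_rng(1))
```

giving one row of (mean, sd, q05, q95) per subpopulation-month, summing
Poisson plot abundances over every hectare — sampled plots use their own
posterior density draws, tube-only plots go through the hyper model, and
unsampled hectares resample representative plot-periods.

The same pipeline is scriptable from the shell:

```bash
occabund simulate --preset desk_small --seed 1 --out runs/raw
occabund collate  --raw-dir runs/raw --timescale short --out runs/summaries
occabund fit      --summary-dir runs/summaries --plots-dir runs/raw \
                  --seed 1 --out runs/fit
occabund predict  --fit-dir runs/fit --summary-dir runs/summaries \
                  --plots-dir runs/raw --seed 1 --out runs/pred
occabund report   --fit-dir runs/fit --predict-dir runs/pred \
                  --summary-dir runs/summaries --plots-dir runs/raw \
                  --out runs/report
```

`predict` refuses to run on a non-converged fit (any R-hat ≥ 1.1) unless
`--force` is given; every output directory carries a `manifest.json` with
config hash, seed and input digests.

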