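# Methods

## The scientific problem

Endangered small mammals with very low per-occasion capture probability are
expensive to monitor by live trapping, while presence–absence monitoring
(here, track tubes recording footprints in baited tubes) scales cheaply over
space and time. `occabund` implements an integrated Bayesian model that
*calibrates* the relationship between density and occupancy/detection on the
few plots where both data types exist, and then uses that relationship to
predict density — and hence abundance — wherever only presence–absence data
(or no data at all) are available.

The analysis unit is the **plot-period**: a 1-ha plot in one calendar month
of the April–July active season (the *short* timescale) or a whole season
(the *long* timescale, where month effects are dropped and an occasion is a
whole multi-night trapping session).

## Model components

### Density from live trapping (Huggins closed-population model)

Per trapped plot-period *i*, encounter histories reduce to (Mᵢ, nᵢ, tᵢ):
unique individuals, total captures, occasions. Capture probability varies on
the logit scale:

    logit pᵢ = μ_p + η_plot + η_year [+ η_month] + ε_i,

all effects Gaussian with their own SDs. The Huggins conditional likelihood

    L_i = p^n (1-p)^(Mt-n) / p*^M,   p* = 1 - (1-p)^t

uses only captured animals; the never-captured count is handled by the
Poisson partition N = M + f with M ~ Poisson(λ p*), f ~ Poisson(λ(1-p*)),
λ = D̄·A. The effective trapped area A adds a boundary strip of half a
home-range diameter d to the grid: A = (L² + 4L·d/2 + π(d/2)²)·10⁻⁴ ha.
The diameter d is itself a parameter with a truncated-normal prior centred
on the empirical mean of per-individual maximum inter-trap distances
(defaults 11.52 ± 1.04 m short, 20.19 ± 1.42 m long, L = 37.5 m); a
`freeze_homerange` switch holds it fixed. The printed diameter SDs are
treated as uncertainty in the *mean* diameter (they are far smaller than a
plausible between-individual spread), and the estimator in
`estimate_homerange_diameter` accordingly reports the standard error of the
mean of individual maxima.

### Occupancy from track tubes (single-season model, finite population)

Per tube-surveyed plot-period, detection summaries reduce to
(sᵢ, sᵢ*, dᵢ, kᵢ): subplots surveyed, subplots with ≥1 detection, total
detections, checks per subplot. Both detection ρ and occupancy ψ get logit
hierarchies like p, plus a coefficient β·X for the binary plot-selection
covariate (X = 1 for non-randomly chosen plots). The observed-data
likelihood pools detections over detected subplots (sᵢ*kᵢ trials):

    ψ^s* ρ^d (1-ρ)^(s*k-d) [1 - ψ(1-(1-ρ)^k)]^(s-s*).

Because a known, large fraction of the 64 (or 32) subplots is surveyed, the
realized **proportion of subplots occupied** (PSO) is the estimand:
Ψ = (s* + u)/s with u ~ Binomial(s - s*, ψᶜ), where ψᶜ is occupancy
conditional on no detection. The undetected-subplot exponent is read as
sᵢ - sᵢ* (per-plot subplot count).

### The hyper model

The core regression ties expected log density to the square roots of PSO
and per-check detection:

    log D̄ᵢ = β₀ + β₁√Ψᵢ + β₂√ρᵢ + εᵢ,  εᵢ ~ N(0, σ_ε²).

The radicals make the marginal effect of either predictor taper as it
approaches 1 (∂logD̄/∂Ψ = β₁/(2√Ψ)) and stabilise variance; the intercept
keeps density positive even at Ψ = ρ = 0. A `transform="identity"` switch
preserves the untransformed reading. The single-check ρ, not its cumulative
version, enters the regression.

### Priors (normal distributions given mean and variance)

β₀ ~ N(−3, 1); β₁, β₂ ~ N(0, 4); μ_p ~ N(−1, 1); μ_ρ, μ_ψ ~ N(0, 1);
β_ρ, β_ψ ~ N(0, 0.25); every SD (hierarchy σ's and σ_ε) ~
TruncNormal(0, 0.5625, [0, 1.5]) — small variance components more likely a
priori, with an ecological upper bound on the logit/log scale.

## Inference

The joint posterior sums the scalar priors, the Gaussian random-effect
densities, the Huggins + Poisson capture terms, the occupancy terms, the
latent-u binomial terms and the hyper-model normal terms; the observed-data
likelihoods are evaluated directly in the log domain (mathematically
equivalent to a state-space formulation, without the Bernoulli "ones"
device some BUGS/JAGS implementations use). log D̄ᵢ at paired plot-periods
is an explicit (centred) parameter with the hyper-model normal as its prior.

Sampling is component-wise adaptive random-walk Metropolis with four
augmentations chosen for the posterior's known pathologies:

* **element-wise vector updates** — every random-effect vector's full
  conditional factorises across levels (each data row touches exactly one
  element), so all elements are proposed at once and accepted independently
  using per-group log-likelihood deltas (`np.bincount` over rows);
* **enumerated Gibbs for u** — the latent undetected-occupied count at each
  paired plot-period is drawn exactly from its full conditional over
  0..(s−s*), which couples the occupancy side to the hyper model;
* **scale moves** (σ, η) → (cσ, cη) per hierarchy (and (σ_ε, logD) around
  the current hyper mean), the standard cure for funnel geometry; the
  Metropolis ratio reduces to Δlikelihood + Δprior(σ) + log c;
* **translation moves** (μ + δ, η − δ) per hierarchy, plus (β₀ + δ,
  logD + δ) and (β_X + δ, η_plot[X=1] − δ), which break exact or
  near-likelihood-invariant directions;
* a **joint adaptive-covariance block** for (β₀, β₁, β₂), whose posterior
  is strongly collinear because √Ψ and √ρ vary little between occupied
  plots (Haario-style empirical covariance accumulated during burn-in).

Proposal scales adapt by Robbins–Monro toward 44% acceptance (23% for the
3-d block) during burn-in and are frozen afterwards. Defaults mirror the
published configuration — 3 chains, 30,000 unthinned iterations (short) or
300,000 thinned by 10 (long) — with burn-in not reported in the source
material and set to the first 50% of iterations (configurable).
Initial states are prior means jittered by seed-controlled noise; a
non-finite initial posterior raises with the offending component named.
Convergence is judged by the classic split-chain Gelman–Rubin statistic
(< 1.1 treated as converged); the implementation is the plain
between/within-variance formula, cross-checked against `arviz.rhat`
(method="split") in the test suite.

Numerical choices: probabilities from `expit` are clamped to
[10⁻¹², 1−10⁻¹²] inside likelihoods; sampled SDs are floored at 10⁻⁴ to
keep the effect-vector Gaussians proper; impossible data yield −∞ rather
than exceptions; posterior quantiles use linear interpolation of order
statistics.

## Prediction

Every registry plot-period is classified from data availability alone:
PAIRED (both data types; its own posterior logD draws are used),
TUBES_ONLY (posterior Ψ and ρ draws pushed through the hyper model with a
fresh N(0, σ_ε²) residual per draw), or UNSAMPLED (a representative sampled
plot-period with the same selection method, subpopulation and period is
resampled uniformly per draw, falling back to any method with a warning).
Plot abundance is Poisson with mean equal to the drawn density; totals sum
over every hectare of a subpopulation (defaults 411/474/105 ha). The exact
algebra for scaling plot draws to subpopulation totals was an open design
point: the default treats unsampled hectares as independent draws (keeping
totals additive); `correlated=True` instead shares one representative draw
per subpopulation-draw, which induces positive correlation and widens the
intervals. For annual comparison at the short timescale the reporter
selects July (month 7), the end of the monitoring season.

## Synthetic data

Real capture and detection histories for this monitoring programme are
restricted, so `occabund.simulate` generates worlds with the statistical
structure the model assumes, plus a full `SyntheticTruth` record for
recovery testing. Defaults emulate the published design and posteriors:
~46 plots across 3 subpopulations, 64 (or 32) subplots per plot, 2 tube
checks/month April–July, 7 non-randomly-selected core plots with multi-
night sessions of 6 trap checks, per-check capture ≈ 0.05, per-check
detection ≈ 0.47, occupancy ≈ 0.59, hyper coefficients (−2.47, 3.15, 3.14),
σ_ε = 0.94. Hierarchy SDs are not published (the relevant appendices depend
on the restricted data); the generator uses 0.3 (plot/year/residual) and
0.2 (month), moderate values well inside the truncated-normal prior's mass.
β_ρ = 0.28 and β_ψ = 0.59 follow the published seasonal-scale estimates.

The generator couples density to *realized* PSO statistically (the same
direction as the model); a `mechanism="placement"` alternative drops
individuals on subplots so occupancy emerges from abundance, for robustness
experiments. Live-trapped plots maintain a year-level individual pool whose
monthly active subset is obtained by Poisson thinning, so monthly on-grid
abundance is exactly Poisson(D̄ₘ·A) while individuals persist across
sessions — which is what makes seasonal (session-level) collation
meaningful. What the generator does **not** emulate: torpor phenology,
spatial autocorrelation between neighbouring plots, habitat covariates, and
any behavioural response to trapping. Passing recovery tests therefore
demonstrates internal consistency of model + fitting, not robustness to
those real-data features.

Presets: `paper_scale` (~46 plots × 11 years), `desk_small`
(8 plots × 2 years, 32 subplots, 3 core plots — sized so a full fit runs in
about a minute), `null_model` (desk_small with β₁ = β₂ = 0).

## Testing and calibration

The suite checks, among others: exact enumeration oracles for both
likelihoods (all capture-history assignments for M ≤ 3, t ≤ 4; all
subplot-level detection histories for s ≤ 3, k ≤ 3 sum to probability 1);
a conjugate normal-mean toy posterior against its closed form; parameter
recovery on a `desk_small` world (generating values of β₁, β₂, μ_ψ, μ_ρ,
μ_p inside 90% intervals, slope signs, all split R-hat < 1.1); and a
reduced simulation-based calibration. The in-suite SBC is a 5-replicate
smoke test requiring ≥ 3/5 coverage per parameter — with five replicates a
two-sided band around 90% is not statistically meaningful (5/5 is the modal
outcome under correct calibration), so the bound is the one-sided limit a
Binomial(5, 0.9) draw violates with probability < 0.01. The full ≥ 20-
replicate calibration with the two-sided [0.75, 0.99] band is
`scripts/sbc.py`, intended as a long-running job.

Fits in the test suite use reduced problem sizes (desk_small; 2–3 chains of
2,500–5,000 iterations), chosen so the whole suite completes in a few
minutes on one CPU while still exercising every sampler component.

## Known limitations

* Identifiability of plot-level effects on both ψ and ρ is weak when a plot
  contributes few periods; the hierarchical priors regularise this, and the
  diagnostics table should be inspected for such plots rather than assuming
  it away.
* The random-walk sampler, even with scale/translation/block moves, mixes
  much more slowly than a gradient-based sampler would at full published
  scale; the defaults (30k/300k iterations) reflect that.
* Representative resampling for unsampled hectares assumes homogeneity
  within (selection method × subpopulation × period) strata.
* The long-timescale season is not demographically closed; its density
  indexes cumulative activity rather than a census, and the generator's
  seasonal aggregate is emergent rather than a separately specified truth.
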