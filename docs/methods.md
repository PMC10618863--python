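# Methods

This note records the models the package implements, the choices made
where the design was genuinely open, and what the synthetic-data tests
do and do not demonstrate.

## Effect sizes

The unit of analysis is one study group's stress-induced change in core
body temperature, expressed as a log response ratio

    lRR = ln(T_b1 / T_b0)

with `T_b1` the extreme (minimum or maximum) post-stress body
temperature and `T_b0` the pre-stress baseline; for designs with an
unstressed control arm the ratio is stressed over control at the
matched time point. Temperatures enter in degrees Celsius: the
convention the downstream conversion relies on, since
`dT = 38 * (exp(lRR) - 1)` maps an intercept-scale lRR of 1.67e-2 to
+0.64 deg C at the 38 deg C baseline. A Kelvin scale would not
reproduce that correspondence and is not offered.

Uncertainty is a pooled standard error, by default the **sum** of the
two SE-to-mean ratios (`se_num/T_num + se_den/T_den`). This is the form
the analysis design prints; the familiar delta-method quadrature form
`sqrt((se1/T1)^2 + (se0/T0)^2)` is available via `se_form="quadrature"`
as a sensitivity switch, and a reported pooled SE always passes through
unchanged. Record dispersions are stored as standard deviations and
converted to standard errors with the record's single group size
(`sd/sqrt(n)`); observations carry one `n`, so both arms share it.

The small-sample-corrected variant ("RR-delta") adds
`(sd1^2/(n T1^2) - sd0^2/(n T0^2)) / 2`, the second-order Taylor
correction of the log-ratio's expectation; it vanishes for symmetric
arms and as `n -> inf`.

## Inclusion rules

Three screens, each logged per record with a rule id so the filter log
plus the retained records always reconstruct the input exactly:

* latency between baseline and response measurement > 28 800 s (8 h);
* pharmacological manipulation other than saline;
* effect-size outliers: |lRR - mean| > 3.5 sample s.d. **and** the
  implied |dT| > 10 deg C. The two descriptors are treated as a
  conjunction (both were stated of the same excluded records); an
  either-or reading is exposed as `outlier_rule="or"`. The screen is
  iterated to a fixed point within one call — removing an outlier
  shrinks the sample s.d., which could flag further records on a second
  pass — so filtering is exactly idempotent, as the API promises. The
  |dT| arm uses each record's own baseline by default; a fixed
  convention (e.g. 38 deg C) can be supplied for control-arm designs.

Imputation follows the data-harvest conventions: a reported mass range
becomes its midpoint with s.d. = width/4; a missing air-temperature
s.d. becomes the mean of observed ones; a missing mass s.d. becomes the
mean observed CV of mass times the record's mass.

## Allometric classification of resting expenditure

Metabolic rates are converted to watts (oxyjoule equivalent 20.1 J per
mL O2 by default, configurable; 86.4 kJ/day = 1 W; kcal = 4.184 kJ) and
regressed as `ln W ~ ln mass + measurement type` with a Normal(0.67,
0.1) slope prior reflecting classical surface-law/Kleiber expectations.
The fit is the closed-form MAP of that Gaussian model (two passes: an
OLS residual-scale estimate calibrates the penalty, then the penalized
solve); the intercept prior is flat so residuals sum exactly to zero.
Residual sign classifies each species as relatively high (positive) or
low (negative) resting expenditure — the inverse proxy for surplus
energy. A residual of exactly zero classifies as "low", an arbitrary
but deterministic tie-break that is always reported in the warning
list. Phylogeny is deliberately excluded here: relatedness enters the
meta-regression itself, and including it twice would double-count.

## Phylogenetic relatedness

For each class a rooted, branch-length tree gives the Brownian-motion
trait covariance: entry (i, j) is the root-to-MRCA distance, the
diagonal the root-to-tip distance. Bird and mammal matrices are
assembled block-diagonally with exact zeros between classes. By default
each block is rescaled to correlation form (unit diagonal) before
assembly so that class-specific tree heights cannot leak into the
variance partitioning; the unscaled path is available
(`normalize=False`) for sensitivity.

## The meta-regression

The central model is a hierarchical Bayesian meta-regression:

    lrr_i ~ Normal(mu_i, se_i^2 + sigma^2)
    mu_i  = x_i' beta + u_species[s(i)] + u_phylo[s(i)] + u_study[k(i)]

`se_i` is the known sampling SE; `sigma` is free residual heterogeneity
(a random-effects meta-regression). The design comprises an intercept,
mean-centred air temperature (deg C), mean-centred ln mass (g), the
binary relative-RMR category, the two air-temperature interactions, a
standardized second-order latency polynomial, technique, and age class
(-1/0/1). Species and phylogeny are both species-indexed intercepts —
an i.i.d. term plus a term correlated by the relatedness matrix —
mirroring the listed group structure.

**Latency scaling.** Latency is standardized (centred, unit s.d.), not
merely centred: with raw seconds (sample mean ~3.5e3 s) the reported
latency coefficients (~1e-2 scale) and their Normal(0, 0.1) priors are
only mutually consistent on a standardized scale. Centring constants
are stored on the fit for back-transformation.

**Latent covariates.** Air temperature and ln mass are modelled as
latent with Gaussian measurement error (`x_obs ~ N(x_true, x_sd)`; the
ln-mass error is the mass CV by the delta method). The latent
hyperprior is an empirical-Bayes plug-in, `x_true ~ N(0, sd(x_obs))` on
the centred scale — the common default for measurement-error models
when the true-score distribution is unmodelled. A measurement s.d. of
exactly zero pins the latent to the observation.

**Priors.** Continuous slopes Normal(0, 0.1); interactions Normal(0,
0.05); age and quadratic latency Normal(0, 0.25); the two binary-factor
effects SkewNormal(xi = 0, omega = 0.1, alpha = -2.5) in the direct
parameterization (the left skew encodes that large negative lRRs are
more plausible than equally large positive ones); group-level s.d.s
Gamma(1.5, 1); sigma Gamma(1, 1). The intercept prior is Normal(0,
0.25), chosen to sit between the slope and age scales and to keep the
prior-predictive response at average covariates inside the stated lRR
plausibility window of roughly [-1, 0.5]; a Normal(0, 0.1) sensitivity
variant is one config line.

**Sampler.** The posterior is explored by a blocked
Gibbs/Metropolis-within-Gibbs scheme built on the model's conditionally
Gaussian structure rather than by generic gradient-based MCMC — with
the group effects marginalized the awkward conditionals are low
dimensional, and the remaining blocks are exact conjugate draws:

1. *Variance components* (three group s.d.s and sigma): random-walk
   Metropolis on the log scale against the marginal likelihood
   `resid ~ N(0, M)`, `M = D + sd_sp^2 ZZ' + sd_ph^2 ZCZ' + sd_st^2 ZZ'`,
   with the group effects integrated out analytically. Three
   sub-updates per sweep; the proposal uses a scalar step adapted to
   ~30% acceptance during warmup plus a per-coordinate diagonal
   preconditioner from warmup variances (Welford). M's Cholesky factor
   depends only on the variance components and is cached across sweeps.
2. *Fixed effects*: a joint conjugate Gaussian draw, also collapsed
   over the group effects (this removes the intercept/group-mean random
   walk a naive scan suffers), with an independence-Metropolis
   correction for the two skew-normal priors: the proposal is the
   conjugate posterior under the Gaussian part (scale omega), accepted
   with the ratio of skewing factors `Phi(alpha * b / omega)`. Two
   refreshes per sweep keep the rejection-induced autocorrelation
   negligible.
3. *Group effects*: exact Gaussian conditionals (study and i.i.d.
   species effects componentwise; phylogenetic effects jointly through
   the relatedness precision).
4. *Latent covariates*: given everything else the latents are
   independent scalar Gaussians (the interaction makes the predictor
   bilinear, but conditional on one latent vector it is linear in the
   other), combining the regression pull, the measurement likelihood
   and the hyperprior.

Because the sampler has no trajectory integrator there are no
divergences to count; Metropolis acceptance rates are reported in their
place. Seeds: one user seed spawns per-chain `SeedSequence` children,
so runs are bit-reproducible per seed and chains are independent.

**Schedules.** The full analysis preset is 4 chains x (2500 warmup +
15 000 draws, thin 10). Routine runs and the test suite use a
desk-scale preset of 4 x (1000 + 2000, thin 4), which the
parameter-recovery suite shows is amply converged for this problem
size.

**Summaries and gates.** Coefficients are summarized by the mode of a
Gaussian KDE (Silverman bandwidth) over pooled thinned draws, with 80%
and 95% highest-posterior-density intervals, per-parameter R-hat and
ESS-to-draws ratios. Gates: R-hat in [0.95, 1.05] for every monitored
parameter and ESS ratio > 0.75 for the fixed effects. The ESS gate is
not applied to the variance parameters: a random-walk update cannot
reach the near-i.i.d. ESS ratios a Hamiltonian sampler reports, and
flagging it would say nothing about the quantities the analysis
reports; their R-hat is still gated and their ESS ratios are published
in the summary. Failures flag the summary (and fail a pipeline run's
exit status); they are never silently passed.

**Marginal effects** are posterior predictions over a grid of raw air
temperature crossed with ln mass or the relative-RMR level, holding
every other covariate at its centred (average) value — so the
prediction at the covariate means is exactly the intercept posterior —
with derived columns (interaction, squared latency) computed from those
held values. Grid points outside the observed covariate range are
flagged as extrapolation, not refused. Predictions convert to deg C at
the 38 deg C baseline on request.

## Biophysical heat-balance model

An animal is a prolate spheroid of flesh with volume mass/density
(1000 kg m-3, i.e. 1 g occupies 1 cm^3) and semi-major axis 1.2x
(birds) or 1.3x (mammals) the semi-minor axes, wrapped in a uniform
insulation layer whose depth in centimetres is log10(mass in grams)
(10 g -> 1 cm, 100 g -> 2 cm), floored at 0.1 cm below ~1.26 g, with
conductivity 0.0272 W m-1 K-1. Flesh conductivity 0.5 W m-1 K-1 and
emissivity 0.95 are standard biophysical-ecology values. Heat leaves by
thermal radiation and by mixed free/forced convection only — no
conduction to substrate, no evaporation, no solar load, and no Q10
dependence of metabolism on body temperature (which makes the energy
estimates conservative).

The steady state solves a series resistance network:

* core-to-surface conduction through the flesh, using the
  distributed-generation sphere form `R = 1/(8 pi k_flesh r_eq)` with
  `r_eq` the volume-equivalent sphere radius (the spheroids here are
  mild, ratio <= 1.3, so the sphere form is accurate to a few percent
  and keeps the resistance closed-form);
* conduction through the insulation shell, `R = d / (k_ins * A_mean)`
  with `A_mean` the mean of the inner and outer spheroid areas;
* surface losses: radiation linearized about the film temperature
  (`h_r = 4 eps sigma T_bar^3`) plus convection with
  `Nu = (Nu_free^3 + Nu_forced^3)^(1/3)`, `Nu_free = 2 + 0.6 Ra^(1/4)`
  and `Nu_forced = 2 + 0.6 Re^(1/2) Pr^(1/3)` (sphere correlations; at
  the default 0.1 m s-1 wind both regimes matter, and the cube-root
  blend is standard; a `max` rule is a config option). Air transport
  properties follow Sutherland viscosity and a linear conductivity law
  at the film temperature.

The surface temperature is found by fixed-point iteration (tolerance
1e-6 deg C, <= 100 iterations; non-convergence raises with the last
iterate) followed by one final consistent solve, so generated heat
equals radiative plus convective losses to < 1e-6 W at the solution.
The tests verify the linearized solution against an independent
full-fourth-power root-finder to within 2% across gradients up to
40 deg C. When the core is colder than the surroundings the required
"generation" is negative; it is reported as such with a
heat-dissipation flag, never clamped, and no basal floor is imposed by
default (an allometric floor can be wired in from the metabolic-rate
module but is off, since results are expressed relative to the model's
own baseline).

The energy consequence of a stress response is
`100 * (q_baseline - q_stress) / q_baseline` — the percentage of
baseline resting expenditure liberated (positive) or incurred
(negative) by shifting core temperature. It is undefined (NaN) when the
baseline budget is zero.

## Synthetic data

The generator draws the full hierarchy the model assumes: pure-birth
unit-height trees per class, species ln-masses ~ N(ln 222 g, 1.5)
truncated to 5–8500 g, relative-RMR categories Bernoulli(1/2),
study-level air-temperature centres ~ N(20.1, 10) truncated to
[-10, 35] deg C with reported measurement s.d. around 2 deg C,
technique and design flags, age classes (70% adult), log-normal
latencies (median ~2000 s, capped at the 8 h screen), group sizes
1 + Poisson(7), and pooled SEs log-normal with median 0.005 (a few
tenths of a degree at the 38 deg C baseline). Observation-level true
air temperatures spread around the study centre with a 6 deg C s.d.
(truncated to the same range): study groups in this literature are
partly defined by air-temperature treatments, so the air slope is
identified within studies as well as between them. Six degrees is a
conservative stand-in for the multi-treatment spans such studies use. True lRRs follow `X beta` plus species, phylogenetic
(MVN over the tree correlation), and study effects plus N(0, sigma)
heterogeneity; observed lRRs add N(0, se_i). Body temperatures are then
back-computed — `Tb0 ~ N(38, 1.7)` (the reported baseline spread),
`Tb1 = Tb0 exp(lrr_obs)` — so the effect-size pipeline reproduces the
intended observed lRR exactly; infeasible draws are resampled and
counted.

The default ("reference") scenario is 165 observations / 68 studies /
24 species with the published coefficient table as the true effect
vector, species and phylogenetic s.d.s at their reported magnitudes
(1.49e-2 and 1.5e-3), and study s.d. 1e-2 / residual sigma 1.5e-2 —
plausible meta-analytic heterogeneity magnitudes, fixed once, where no
value is reported. A null scenario zeroes the effect vector for
calibration checks.

What passing recovery tests show: the estimation machinery is
calibrated and has power under the assumed generative structure at the
study's size. What they do not show: robustness to real-data features
the generator omits — non-Gaussian effect distributions, correlated
missingness, digitization error, seasonal confounding, species
assigned metabolic values borrowed from relatives, or model
misspecification generally.

## Numerical and degenerate-input conventions

* Relatedness matrices must be symmetric and PSD to a 1e-10 x trace
  tolerance; a 1e-10 diagonal jitter stabilizes Cholesky/inverse calls.
* A constant predictor column is reported as non-identifiable in the
  spec warnings (the proper priors keep it sampleable).
* Zero-variance latency degrades to an all-zero polynomial with a
  warning rather than dividing by zero.
* KDE modes fall back to the draw value when a parameter is constant
  (e.g. pinned variance components).
* The species-name join is case-insensitive with underscores equal to
  spaces, and nothing fuzzier: a silent mis-join is worse than an
  error.
* The empty quadrant in report tables prints n = 0 rather than NaN.

## Known limitations

* The skew-normal priors on the two factor effects are informative and
  asymmetric (mean -0.074 at omega = 0.1, alpha = -2.5). For a
  species-level coefficient identified from ~24 species the exact
  posterior is therefore shifted a fraction of a posterior s.d. toward
  negative values, and the frequentist coverage of its HPDIs sits a few
  points below nominal in simulation. This is a property of the prior,
  not of the sampler; users wanting nominal coverage for the factor
  effects should swap in a symmetric prior via the `priors` argument.

* The ESS gate interpretation for variance parameters (above) is a
  deliberate deviation forced by the sampler family; variance-parameter
  ESS ratios are typically 0.05–0.4 at the desk-scale schedule.
* The latent-covariate model assumes Gaussian measurement error with
  known per-record s.d.s; gross dispersion misreporting propagates.
* Borrowing metabolic values from related species is out of scope: the
  metabolic table must provide one value per species (a free-text
  `source` column carries provenance).
* The biophysical model is steady-state; transient responses (and thus
  latency effects on the energy budget) are outside its scope.
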