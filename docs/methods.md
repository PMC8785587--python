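# Methods

`geoprev` implements model-based geostatistics for a binary prevalence
outcome measured on children sampled within geo-located survey clusters —
the setting of national anthropometric surveys, where the motivating
application is childhood stunting.

## The model

For child *i* in cluster *j* (locations known, *J* clusters):

```
y_ij ~ Bernoulli(p_ij)
logit(p_ij) = β0 + Σ_q β_q X_iq + Σ_l γ_l Z_il + s_j + u_j
```

* `X` — continuous covariates, centered on their observed means, so β0 is
  the baseline logit for an average child and each β_q is a per-unit
  log-odds-ratio on the centered scale.
* `Z` — categorical covariates with corner constraints: the lowest-risk
  category is the reference and its coefficient is pinned to 0.
* `s = (s_1..s_J)` — zero-mean Gaussian random field over cluster
  locations, `s ~ MVN(0, Σ)` with isotropic exponential covariance
  `Σ_jk = σ_s² exp(−φ d_jk)`; `d` in kilometres (haversine for lon/lat
  input, Euclidean for planar-km input), so φ is a decay per km and the
  effective range is ≈ 3/φ km.
* `u_j ~ N(0, σ_u²)` — exchangeable cluster noise (non-spatial
  heterogeneity; it also plays the role of a nugget at cluster level).

Model 1 omits `s` (exchangeable effects only); Model 2 carries both random
effects. Everything else — priors, imputation, validation — is shared.

### Priors

Hierarchical normals on the coefficients: `β_q ~ N(0, σ_β²)`,
`γ_l ~ N(0, σ_γ²)`, with uniform SDs `σ_β, σ_γ ~ U(0, 10)`; one σ_β is
shared across the continuous block and one σ_γ across all categorical
contrasts (whether the original analysis shared or split these is unknown;
sharing is this package's choice). The intercept gets an independent vague
`N(0, 10²)`. Spatial parameters: `σ_s ~ U(0, 10)`, `φ ~ U(0, 1)` per km —
with distances in km this admits effective ranges from 3 km up to
(effectively) the whole study region; both bounds are configurable.
`σ_u ~ U(0, 10)`. Imputation-model means get vague normals with precision
0.001 (variance 1000 — the BUGS-style (mean, precision) convention),
imputation SDs `U(0, 10)`.

### Missing covariates

Missingness is treated as MCAR/ignorable. Each covariate with gaps gets a
Bayesian sub-model: continuous `X_i ~ N(μ_X, σ_X²)`; categorical
`Z_i ~ Multinomial(1, π)` with `π_k = softmax(η_k)`, `η_1 = 0`. Missing
cells are random variables updated inside the chain, so imputation
uncertainty propagates into every posterior summary. One deliberate
simplification: the category-level predictors η_k are shared across
individuals (hierarchically `η_k ~ N(μ_Zk, σ_Z²)`). Individual-level η's
would not be identifiable without covariates in the sub-model, and the
collapsed form leaves the implied marginal `π` unchanged.

## Sampling

The posterior is explored by Metropolis-within-Gibbs (the reference
analysis used a general-purpose Gibbs engine; the scheme here is our own):

* fixed effects — univariate adaptive random-walk Metropolis with
  incremental linear-predictor updates (target acceptance 0.44);
* `u` — per-cluster MH proposals, vectorized across clusters (valid because
  the u_j are conditionally independent);
* `s` — elliptical slice sampling under its MVN prior (exact, tuning-free);
* `φ` — RWM on the logit of its uniform support (each proposal refactors
  the correlation Cholesky, which is cached between acceptances);
* `σ_s, σ_u` — two moves each: a conditional RWM on the log scale, and a
  *whitened joint rescale* that multiplies the SD and its whole random
  effect vector by a common factor (acceptance reduces to the likelihood
  ratio times e^ε). The joint move breaks the slow mixing of centered
  parameterisations, where SD and field updates are mutually pinned;
* imputation parameters — RWM against their sub-model densities; missing
  continuous cells by independence MH from the sub-model (acceptance is the
  outcome-likelihood ratio, which is the correct full conditional);
  missing categorical cells exactly from the discrete full conditional
  `∝ π_k · Bernoulli(y | η with category k)` via Gumbel-max sampling.

Step sizes adapt by Robbins–Monro during burn-in only and are frozen
afterwards, so the retained draws come from a fixed, detailed-balanced
kernel. Default protocol is 40,000 iterations / 20,000 burn-in (the
original analysis); the test-suite and examples use 2,000–5,000-iteration
desk profiles, which the recovery experiments show are adequate at J ≤ 100,
n ≤ 3,000. A full run stores per-observation log-likelihoods for the
validation stage (float32, T × n).

Correctness evidence (in the test suite): an intercept-only reduction is
checked against a numerically exact quadrature posterior (the cluster
effects are integrated on a standardized grid, then σ_u over its prior);
parameter-recovery and coverage experiments on synthetic surveys; support
and exchangeability invariants.

### Identifiability note

A single realization of the field leaves only `β0 + mean(s + u)` estimable
— the intercept trades off freely against the field's realized mean. The
coverage tests therefore assess that combination for the intercept. For the
same reason σ_s and φ are individually weakly identified at moderate J
(a classic property of this covariance family); their product-scale effect
on predictions is what the kriging stage consumes.

## Validation and comparison

* CPO (conditional predictive ordinate) per observation by the
  harmonic-mean identity `CPO_i = [T⁻¹ Σ_t 1/Pr(y_i|θ_t)]⁻¹`, avoiding
  n-fold refitting. Entries whose denominator is dominated (> 50%) by one
  draw are flagged unstable. The estimator's variance is finite only when
  the posterior tails temper the inverse likelihood; on very small data
  with vague priors it degrades, which the instability flag surfaces.
* B-p values in Rao-Blackwellized form: the posterior mean
  replicate-match probability `T⁻¹ Σ_t Pr(y_i|θ_t)^{y_i}(1−..)^{1−y_i}`,
  i.e. the analytic expectation of simulating replicates, with no added
  Monte-Carlo noise. (These are posterior-predictive quantities; the
  "cross-validatory" label sometimes attached to them belongs to CPO.)
* Scaled-CPO screen: CPO / max(CPO) < 0.001 flags outliers.
* PsML = Σ log CPO as a pseudo Bayes factor; larger is better. PsML can
  separate the two models only when the spatial field carries predictive
  information beyond what exchangeable cluster effects absorb — with many
  children per cluster, u_j fits each cluster's level and PsML is nearly
  blind to spatial structure; with few children per cluster and strong
  inter-cluster correlation the spatial model wins clearly. The comparison
  tests run in that informative regime.

## Prediction of the residual surface

A regular lattice (default 5 × 5 km) is laid over the region (bounding box
or polygon; outside-boundary centroids are excluded). Per retained draw,
the structured field is interpolated to cell centroids by simple kriging /
the GP conditional mean, `Λ = Σ_oi Σ_jj⁻¹` (the weights depend only on that
draw's φ because σ_s² cancels), which is exact at cluster locations. Only
`s` is interpolated: `u` is cluster-specific noise with no spatial support.
Cells are treated independently (marginal prediction; no joint conditional
covariance), and summaries are reported on the odds-ratio scale: mean and
SD over draws of `exp(s₀)` (SD of `s₀` itself is also stored). An optional
conditional-simulation mode adds per-cell conditional-variance noise, under
which a cell far from all data reverts to the prior lognormal. Weights are
recomputed every 10th retained draw by default (`thin=1` restores the
per-draw scheme at full cost).

## Synthetic data: what it does and does not emulate

The generator draws clusters uniformly in a bounding box (optionally
rejection-sampled against a polygon), the field from its exact MVN, 4–12
children per cluster (mirroring a survey's ~7 measured children per
cluster), covariates from survey-calibrated normal/multinomial marginals,
and MCAR gaps at the survey's observed rates (~61% for the under-two
feeding covariates). Default effect sizes are the survey's adjusted odds
ratios; the default intercept is logit(0.38) minus the mean categorical
effect (0.720), so overall prevalence matches the survey's 38%. Not
emulated: two-stage household sampling and survey weights, the coordinate
displacement procedure, anthropometric measurement (the outcome is
generated directly as binary), and any covariate-covariate or
covariate-space dependence. A green test on this world therefore
establishes correctness of the machinery, not robustness to informative
sampling or to structured missingness.

## Numerical choices

* Covariance factorizations add a 1e-10·σ_s² diagonal jitter (1e-10 on the
  correlation scale) for positive definiteness at near-duplicate locations.
* Bernoulli log-likelihoods via `-log1p(exp(-sign·η))` (logaddexp), stable
  to |η| ≈ 700.
* Centering uses observed-case means computed once before sampling, not
  per-iteration means over imputed values, for reproducibility.
* The linear predictor is maintained incrementally and refreshed from
  scratch every 512 iterations to cap floating-point drift.
* All randomness flows from a single seed through named sub-streams; equal
  config + seed reproduces outputs byte-for-byte, and CSV artifacts are
  written/read at round-trip float precision.

## Known limitations

* Single-chain by default; split R-hat / ESS diagnostics (via arviz) accept
  multiple independently seeded fits, and a warning (not an error) is
  raised above R-hat 1.1.
* Exponential covariance only — no Matérn/spherical options, no
  anisotropy, no nugget beyond the cluster-level u.
* No design-based (survey-weighted) variance estimation in the descriptive
  layer; optional per-child weights only rescale cell totals.
* Grid prediction is marginal per cell; joint simulation of whole-surface
  functionals is out of scope.
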