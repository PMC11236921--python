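# Methods

## The scientific problem

Access to supermarkets and grocery stores in US cities is unevenly
distributed, and two competing explanations — socioeconomic supply/demand
constraints versus racial residential segregation — are usually entangled.
The analysis implemented here disentangles them at census-tract scale: the
outcome is the count of stores per tract, and four nested Bayesian spatial
regressions compare a baseline (spatial effects only), a racial-segregation
covariate block, a socioeconomic block, and their union.  Model comparison
by DIC answers which block better predicts the spatial distribution of
stores; posterior exceedance probabilities of the spatial effect locate
residual hotspots and coldspots.

## Segregation covariates

Racial composition per tract uses four groups (White, Black, Asian,
Hispanic).  Two covariates summarise segregation:

* **Entropy deviation score.**  Tract diversity is the Shannon entropy
  `E_i = -Σ_r p_ir ln p_ir`; citywide diversity `E` is the entropy of the
  pooled composition.  The tract covariate is `h_i = max(0, (E - E_i)/E)`:
  0 when the tract mirrors the city, 1 for a single-group tract, clipped at
  0 for tracts more diverse than the city.  The population-weighted average
  of the unclipped deviations is Theil's multigroup index
  `H = Σ_i t_i (E - E_i) / (E T) ∈ [0, 1]`, reported as the citywide
  segregation summary.  Natural logarithms are used; `h_i` and `H` are
  entropy ratios, so the base cancels.  An alternative reading of the
  tract-level covariate — the normalised diversity `1 - E_i / ln R` — would
  not use the citywide reference and is not implemented.
* **Local G\* clustering.**  Getis–Ord `G_i*` z-scores of the Black and
  White population shares with binary contiguity weights including self
  (`w_ii = 1`):
  `z_i = (Σ_j w_ij x_j - x̄ W_i) / (S sqrt[(n W_i - W_i²)/(n-1)])`
  with `x̄`, `S` the global mean and population standard deviation.  Tracts
  with `z > 0` are "high" clusters, otherwise "low" (a z of exactly 0, or a
  constant surface, classifies low).  When a tract's neighborhood spans the
  whole study area the variance term vanishes; the statistic's limit there
  is 0 and is reported as such.

Covariates are screened with variance inflation factors
`VIF_k = 1/(1 - R²_k)` (regression of covariate k on the rest, with
intercept); VIF ≥ 6 raises a warning but does not abort — screening
mirrors how such models are used in practice.

## The count model

Store counts follow a zero-inflated Poisson BYM regression:

    y_i ~ pi0 * 1{y=0} + (1 - pi0) * Poisson(lambda_i)
    log lambda_i = beta_0 + x_i' beta + u_i + v_i + e_i

* `u` — intrinsic CAR (ICAR) structured effect on the queen-contiguity
  graph: log density `-(tau_u/2) Σ_{i~j} (u_i - u_j)²` (equal to
  `-(tau_u/2) u'(D-A)u` over unordered neighbor pairs), improper, with a
  per-component sum-to-zero constraint; degree-0 areas (islands) have
  their structured effect pinned at 0.
* `v` — iid Normal(0, 1/tau_v) unstructured heterogeneity.
* `e_i` — fixed log-exposure offset.  The default is
  `e_i = log(pop_i / mean pop)`, a population-standardised exposure;
  `log(pop_i)` and no offset are configurable.  (A literal "log of the
  outcome standardised by population" would put the outcome inside its own
  offset and is rejected.)
* `pi0` — one shared zero-inflation weight (type-1 ZIP; no covariates on
  the zero process).

Priors follow the non-informative disease-mapping defaults:
Normal(mean 0, precision 0.001) on every coefficient and on logit(pi0),
and Gamma(shape 1, rate 5e-5) on both precisions (the log-precision then
has the log-Gamma law often quoted for these models).  "Normal(0, 0.001)"
is mean/precision, i.e. variance 1000.

Significance follows the credible-interval rule: a coefficient's rate
ratio `RR = exp(beta)` is significant when the central 95% interval of the
RR draws excludes 1.  Percent changes quoted in text are
`round((RR - 1) · 100)`.

## Inference

Inference is by MCMC (blocked Metropolis-within-Gibbs), not by Laplace
approximation.  Two reparametrizations carry the sampler:

1. **ZIP augmentation.**  Latent indicators `z_i` mark structural zeros,
   with exact conditional `P(z_i=1 | y_i=0) = pi0/(pi0 + (1-pi0)e^{-λ_i})`.
   Given `z`, the count likelihood is Poisson on active sites and `pi0`
   sees a Bernoulli likelihood through its logit.  Structural-zero sites
   feel no likelihood, so their total spatial effect is Gibbs-refreshed
   from its exact prior conditional each sweep — without this, a site
   random-walks very slowly between the two explanations of an observed
   zero ("rate ≈ 0" vs "structural zero"), which is the binding mixing
   bottleneck of this model class.
2. **BYM collapsing.**  The likelihood sees only `s = u + v`.  In the
   eigenbasis of the graph Laplacian the prior of `s` given the precisions
   is diagonal (variance `1/(tau_u w_k) + 1/tau_v` along eigenvalue
   `w_k > 0`, `1/tau_v` along null directions), so `tau_u`, `tau_v` are
   updated by log-scale Metropolis against this *marginal* — with `u`
   integrated out — and `u | s, tau` is then redrawn exactly in the same
   basis (null coordinates zero, which realises the per-component
   sum-to-zero constraint and pins islands).  The textbook alternative,
   conjugate Gibbs on `(tau_u, u)`, is so strongly dependent that
   `tau_u` random-walks to its prior tail while `u` over-smooths; chains
   initialised at the generating truth drift away within hundreds of
   sweeps.  The conjugate full conditionals
   `tau_v | v ~ Gamma(shape + n/2, rate + Σv²/2)` and
   `tau_u | u ~ Gamma(shape + rank/2, rate + energy/2)` remain implemented
   and are verified distributionally in the tests.

Remaining blocks: one random-walk Metropolis update per regression
coefficient (columns centred internally so the intercept mixes; draws are
reported on the original scale), vectorised per-site random-walk updates
of `s`, and a random-walk update of logit(pi0).  Proposal scales adapt
toward ≈0.44 acceptance during burn-in only.  Defaults are 4 chains ×
20,000 iterations with 10,000 burn-in; the replicated experiments below
use shorter chains (stated there) after verifying that doubling the
length moves summaries by less than Monte-Carlo error.  All randomness
derives from one integer seed (numpy `SeedSequence`); reruns are
bit-for-bit identical.  Split-R̂ and bulk ESS (via ArviZ) are attached to
every fit.

Two posterior directions are intrinsically slow/diffuse and are reported
as such rather than "fixed": the precision split between `u` and `v` is
weakly identified at n ≈ 100 (the `tau_u` posterior is close to its vague
prior when the structured fraction is small), and the near-flat prior on
logit(pi0) places roughly half its mass below logit = -3, where the
likelihood flattens, so the `pi0` marginal is legitimately smeared toward
small values.  Coefficient inference is insensitive to both (checked
against a marginal-ML fit of the same ZIP random-effects model).

## Model comparison and hotspots

DIC uses the conditional-deviance focus (deviance given `beta, u, v, pi0`,
the BUGS/INLA reporting convention): `pD = D̄ - D(θ̄)` with `θ̄` the
posterior means (pi0 averaged on the logit scale) and
`DIC = D(θ̄) + 2 pD`.  Negative pD — a known pathology of this focus — is
flagged, not fatal.  Lower DIC is preferred; a ≥ 3-point gap to the
runner-up is graded "substantial".  Exceedance probabilities are
`p_i = P(exp(u_i + v_i) > c | data)` with `c = 1`, i.e. the residual
spatial rate ratio after covariates; `exp(u_i)` alone is available via the
draws archive.  Classification: coldspot `p < 0.2`, neither
`0.2 ≤ p < 0.8`, hotspot `p ≥ 0.8` (half-open boundaries, configurable).

A caveat this package's replicated experiments make explicit: with a ZIP
likelihood and per-area random effects, the conditional-focus DIC is a
weak discriminator between nested covariate blocks.  The two explanations
of an observed zero differ greatly in conditional deviance, so DIC
inherits variance from how the posterior weighs them, and the ~1-point
expected penalty per superfluous covariate is smaller than that noise.
In the selection experiment below the segregation-only model wins most,
but not ≥80%, of replicates; a marginal-likelihood criterion (AIC from a
Laplace-integrated ML fit) separates the same models more cleanly.

## Synthetic data

The generator emulates a highly segregated mid-size city on a 12×8 lattice
of unit-square tracts (96 areas, queen contiguity), mirroring a ~97-tract
study frame:

* **Composition.**  Per group, latent log-odds = group offset + 1.8 ×
  (unit-variance ICAR draw) + 0.6 × iid noise, softmaxed to shares; tract
  populations are log-uniform on [1,000, 8,000] and group counts
  multinomial.  Offsets (White 1.0, Black 1.2, Asian −2.2, Hispanic −0.6)
  give citywide shares of roughly 41/50/2/8% and the smoothing yields
  contiguous Black-majority and White-majority regions.
* **SES covariates.**  Five percentage covariates (poverty, SNAP receipt,
  no vehicle, vacant housing, college education) = mean + sd × (sign ×
  0.6 × standardised Black share + √(1−0.6²) × noise), clipped to
  [0, 100], with means/sds at the scale of a high-poverty urban county
  (36/15, 37/16, 26/15, 22/10, 9.5/7; college negatively signed).  The
  resulting full design passes the VIF < 6 screen.
* **Counts.**  True effects on the log scale: entropy score −0.49, high
  Black clustering −0.14, high White clustering +0.65 (echoing the effect
  directions the analysis is designed to detect), per-percentage-point
  slopes of ±0.005–0.02 for the remaining covariates, intercept 0.3,
  `tau_u = 4`, `tau_v = 16`, `pi0 = 0.2`.  `u` is drawn exactly from the
  constrained intrinsic law via the Laplacian eigendecomposition.  All
  latents are recorded in a truth file for recovery tests.

What the generator deliberately does not emulate: real tract geography
and adjacency irregularities, edge effects at the study boundary (the
pipeline accepts a pre-augmented table instead of implementing buffer
logic), covariate measurement error, and any spatial structure in the
zero-inflation process.  Passing recovery tests therefore demonstrate
internal consistency of model + sampler + summaries under the model's own
assumptions, not robustness to real-data violations of them.

## Replicated experiments (problem sizes)

* **Parameter recovery** — 100 replicate cities from the default truth,
  full-model fits with one chain × 5,000 iterations (2,000 burn-in); many
  moderate fits beat few long ones here because the bias estimator's noise
  is dominated by replicate-to-replicate posterior spread.
  Checks: pooled 95% CI coverage over (coefficient, replicate) pairs
  ≥ 0.9, and |mean posterior-mean error| < 0.1 on the log scale per
  covariate effect.  The intercept is excluded from the bias check: its
  per-replicate posterior sd (~0.5, it trades off against mean(v) and
  pi0) makes a 0.1-bias estimate from 20 replicates uninformative.
* **DIC selection** — 20 replicate cities with a strong segregation block
  (entropy −0.8, Black clustering −0.6, White clustering +0.6), zero SES
  effects and SES–race correlation 0; all four models fitted per
  replicate with a shared sampler seed (paired comparison), 2 chains ×
  10,000 iterations.  Reported as the share of replicates in which the
  segregation-only model attains the minimum DIC (see the caveat above).

## Numerical choices

* Proportions must sum to 1 within 1e-8; group counts are validated
  nonnegative.
* Perfect collinearity reports VIF = ∞ (flagged) rather than erroring.
* `z = 0` classifies "low"; exceedance boundaries are half-open with the
  upper class closed at its cut.
* Ties at the DIC minimum yield no preference and a warning.
* Initialisation: `beta = 0` (intercept jittered by chain), `u = v = 0`,
  `tau = 1`, `pi0` at the observed zero share floored at 0.01 and capped
  at 0.95.
* The deterministic area ordering is the sorted order of area ids; every
  output table carries the id (or coefficient name) column.

## Known limitations

* Inference quality degrades for very sparse graphs or n below a few
  dozen areas (the collapsed tau update needs informative eigenstructure).
* The ZIP zero process carries no covariates and one global weight; a
  spatially varying zero process would confound differently.
* DIC is reported with the conditional focus only; WAIC/LOO are out of
  scope.
* The G* variant is fixed to binary self-inclusive contiguity weights;
  distance-band or row-standardised weights are not offered.
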