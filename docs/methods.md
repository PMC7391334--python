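# Methods

`hoopoeipm` implements a habitat-stratified integrated population model
(IPM) for a hoopoe (*Upupa epops*) breeding population monitored with nest
boxes, together with the two retrospective analyses that diagnose a decline:
a transient life-table response experiment (LTRE) and a leave-one-covariate-
out attribution of population-size variance and trend. This note records the
model, the estimation machinery, the synthetic-data generator that stands in
for the field data, and the design decisions taken where the design was
genuinely open.

## The population model

The population is censused each year just before hatching (prebreeding
census) and is female-based. Each habitat-quality class h ∈ {H, M, L}
(high/medium/low, proxied in the field by ground-water-driven availability
of mole crickets, the dominant nestling prey) holds three stages: local
recruits N¹, experienced adults N², and immigrants Nⁱ. Writing
N^tot = N¹ + N² + Nⁱ, one year of dynamics for destination habitat h is

    N¹_{h,t+1} ~ Poisson( Σ_src R_{src,t} S¹_{src,t} ψ¹_{src,h} N^tot_{src,t} )
    N²_{h,t+1} ~ Σ_src Binomial( N^tot_{src,t}, S²_{src,t} ψ²_{src,h} )
    Nⁱ_{h,t+1} ~ Poisson( ω_{h,t} N^tot_{h,t} )

with apparent first-year survival S¹, apparent adult survival S² (both
confound mortality with permanent emigration), movement probabilities ψ¹
(natal) and ψ² (breeding) between habitat classes, and per-capita
immigration ω. Productivity decomposes as R = ½ · p_succ · μ_fled: the
probability of raising at least one fledgling in the season times the mean
total fledglings of a successful female (double broods included), halved for
a balanced birth sex ratio. The annual count index y (maximum simultaneous
active broods per habitat) observes the totals with Poisson error,
y_{h,t} ~ Poisson(N^tot_{h,t}).

Four data sets enter one joint likelihood under shared parameters:

1. **Counts** — Poisson observation of the latent totals.
2. **Capture–recapture histories** — a multistate model with latent states
   {H, M, L, dead}; transition = survival × movement, both age-specific
   (first interval after a nestling marking uses first-year rates).
   Recapture probability is shared across live states with a logit-normal
   year effect. The per-history likelihood conditions on first capture and
   marginalises latent states by a forward algorithm; an exact
   path-enumeration oracle backs it in the tests.
3. **Reproductive success** — Bernoulli with logit link per female-year.
4. **Fledglings of successful females** — gamma with *identity* link and a
   single shared shape, parameterised by mean and shape (rate = shape/mean).

### Model variants

* **Variant I** — every vital rate gets habitat intercepts plus independent
  year random effects with habitat-specific SDs. Used for the LTRE.
* **Variant II** — year as a continuous standardised covariate
  (habitat-specific slopes in the starting form, shared in the reduced
  form). Used to test for habitat-heterogeneous trends.
* **Variant III** — explanatory covariates replace the year structure on
  fledglings and survival: quadratic standardised spring temperature and
  precipitation (habitat-interacted on fledglings in the starting form),
  quadratic hatching date, clutch size, and the research-activity variables
  (capture method, parental tagging, tagging, and the threshold capture
  delay). Reproductive success keeps its year random effects; immigration
  reduces to habitat intercepts. Movement is time-constant in all variants.

The **capture delay** (days between the mother's capture and hatching of her
last egg) enters through a threshold term: slope fixed to zero for
non-negative delays, linear for negative ones, on the raw day scale —
standardising it would move the biologically meaningful threshold away from
zero days. Record-level covariates reach the population-level rates (and the
survival models) as annual habitat-cell means of the transformed covariate;
linking each capture history to its natal brood record is not attempted.

### Priors and inference

Priors: Normal(0, var 1000) for intercepts and slopes on the link scale;
Uniform(0.01, 15) for the fledgling intercept (identity link);
Uniform(0, 10) for all random-effect SDs and for the gamma shape;
Dirichlet(1,1,1) on movement rows, sampled in additive-log-ratio
coordinates; discrete-uniform [0, 5 × first count] for the initial stage
abundances.

No probabilistic-programming backend is used: inference is an adaptive
Metropolis-within-Gibbs sampler written for this model. Design points:

* Defaults mirror the analysis protocol: 3 chains × 3,000 iterations, first
  1,500 discarded as burn-in, no thinning. Proposal scales adapt only during
  burn-in (Robbins–Monro on the log scale; targets 0.44 scalar / ~0.25
  block). Convergence is checked with the Gelman–Rubin statistic on every
  saved parameter; R̂ ≥ 1.01 raises a warning, not an error.
* The sum of three source-habitat binomials in the adult equation has no
  standard pmf, so the sampler augments the state with latent
  source→destination survivor flows B[src, dest, t] (the node-level
  decomposition a BUGS-family sampler would use). The public `state_loglik`
  evaluates the exact convolution instead, so it needs only a trajectory.
* Latent abundances are integers updated by symmetric integer random walks
  with local likelihood evaluation (a numba kernel); the CMR likelihood
  pools identical histories and runs as a compiled forward pass.
* Intercepts and year random effects are only jointly identified; a
  translation move (a → a+δ, ε → ε−δ, accepted on the prior ratio) keeps the
  intercept at the ridge's prior optimum. Random-effect SDs get a group
  scale move ((σ, ε) → (cσ, cε)) — their non-centred companion — without
  which σ mixes an order of magnitude slower.
* Immigration, its latent counts, and the allocation of birds among stages
  are mutually confounded, and the joint density is much higher at the
  degenerate corner (ω ≈ 0, Nⁱ ≡ 0) than at any single configuration of the
  diffuse truth. Tailored exchange moves shift the immigration intercept
  together with a matched reallocation between immigrants and recruits (or
  same-habitat adult survivors) at fixed totals; bold fixed-scale versions
  cross between the modes. Immigration parameters are additionally held at
  their data-driven initial values for the first fifth of burn-in so the
  rest of the model settles first.

**Known limitation — immigration.** Per-habitat immigration is weakly
identified whenever observed growth can be reproduced by survival and
recruitment within their capture–recapture uncertainty; the vague
logit-scale intercept prior concentrates mass near ω = 0 and the posterior
can put appreciable mass on the near-zero mode, biasing ω low and survival
slightly high. The default scenario therefore includes a colonisation phase
(early λ ≈ 1.3–1.4) that recruitment plus survival cannot produce, which is
also what the real population did after nest boxes were installed.
Survival, success, and fledgling means recover well; immigration estimates
should always be read together with their (wide) intervals.

### Backward simplification of variant III

Interactions between habitat and a covariate are collapsed to a shared
coefficient when the per-habitat coefficients' deviations from their common
mean all have 95% credible intervals overlapping zero; quadratic terms
reduce to linear, and research-activity terms may leave entirely, when their
coefficients overlap zero. "Overlap with 0" is operationalised as the
posterior mass on the minority side of zero (0.5 = centred, < 0.025 = the
95% interval excludes zero); at each step the candidate with the largest
overlap is removed and the model refitted, stopping when every remaining
candidate excludes zero. Clutch size and hatching date are not removable
(they are not research-activity variables), and habitat intercepts are
always protected.

## Transient LTRE

Summing the process expectations over habitats cancels movement, leaving

    λ_t = Σ_h π_{h,t} ( R_{h,t} S¹_{h,t} + S²_{h,t} + ω_{h,t} ),

with π the habitat shares of the population. The decomposition of
var(λ) is first order: contribution of parameter x_i is
Σ_j cov(x_i, x_j) s_i s_j with analytic sensitivities evaluated at the
temporal means. The between-period difference in mean log λ uses direct
terms (mean differences × gradient of log λ at the across-period midpoint)
plus second-order indirect terms from the change in within-period
covariances (with the analytic Hessian of log λ). Both report their
approximation residual, so the adequacy of the expansion is observable
rather than assumed. Structure sensitivities are projected onto the simplex
tangent space (Σ_h δπ_h = 0); a drop-one-habitat parameterisation is
available via `project_pi=False`. The decomposition runs per posterior draw
of a variant-I fit, giving credible intervals for every contribution.

## Variance and trend attribution

The share of population-size variance attributable to covariate v compares
the total variance explained, R²_tot = 1 − var(observed − fitted)/var(observed),
between the full reduced variant-III model and a refit without v:
share_v = (R²_tot − R²_−v)/R²_tot. "Fitted" population sizes are the
deterministic expectation projection from the posterior-mean initial stage
abundances under the *systematic* part of the posterior-mean rates
(intercepts + covariate/trend terms, year random effects excluded). Two
alternatives were rejected: smoothed latent abundances track the observed
counts almost regardless of covariates (state-space filtering), and
projections including the estimated year random effects let those effects
absorb any annual signal — under either choice every covariate looks
redundant. The trend share replaces R² with the least-squares slope of
fitted log λ_t on calendar year from a reference year onward (the year the
growth rate first dropped below zero in the study population, 2005).
Shares of non-orthogonal covariates need not sum to one and can be negative
with noisy refits; raw and normalised shares are both reported.

## The synthetic-data generator

The generator draws from exactly the stochastic structure the model assumes
(same distributions, same link functions), from known "true" parameters, so
simulation–estimation round trips are exact tests of the estimation
machinery. Default scenario (per habitat unless stated):

| quantity | default | note |
|---|---|---|
| years | 16 | annual prebreeding censuses |
| habitats | H, M, L | equal nest-box availability |
| μ_fled (H, M, L) | 6.7, 6.0, 5.9 | habitat-quality gradient in fledglings |
| p_succ | 0.80 | |
| S¹ | 0.20 | scenario default |
| S² | 0.35 | scenario default |
| ω | 0.15 | scenario default |
| gamma shape | 6 | fledgling dispersion |
| mean recapture p | 0.81 | logit-normal year effect, σ = 0.3 |
| ψ¹ diag | 0.75/0.65/0.65 | natal dispersal skews toward higher quality |
| ψ² diag | 0.92/0.87/0.87 | adults mostly faithful to their class |
| initial N (N¹, N², Nⁱ) | (6, 10, 4) | |
| trends (link scale / yr-sd) | fled −0.5, S¹ −0.15, S² −0.08, ω −0.8 | see below |

The default trends emulate the study system's observed shape: fledgling
production declining ~25% and first-year survival ~31% over the period, and
strong early immigration (colonisation after nest-box installation, when the
local population grew several-fold — growth local recruitment cannot supply)
levelling off to a low rate. The population therefore rises steeply, peaks,
and declines, which both exercises the LTRE with genuine temporal variance
and keeps immigration identifiable. Movement defaults keep the three classes
comparably populated, matching the equal split of nest boxes among classes.

Marked cohorts arise at per-capita rates (0.45 ringed female nestlings and
0.12 adult first-captures per censused female per year), giving a
low-thousands marked sample over 16 years. Brood records cover every
censused female by default (`brood_fraction` subsamples them; the census
totals still define the breeding population). Weather covariates are
generated directly as z-scores; the capture delay is generated in raw days
around an annual mean that drifts from +0.5 to −4.5 days by default
(emulating a field protocol that captured mothers progressively earlier),
with SD 3 days among females. Fledgling counts are continuous gamma draws by
default (`round_fledglings=True` rounds to positive integers).

What the generator does *not* emulate: observation-driven heterogeneity
(trap response, individual detection heterogeneity), brood-level within-
season dynamics, density dependence, covariate measurement error, and
correlation between a mother's covariates and her offspring's survival
(survival covariates act through annual habitat means). Passing
simulation–estimation tests therefore demonstrates correctness of the
likelihoods and decompositions under the model's own assumptions, not
robustness to their violation.

## Experiment scales

The validation experiments are sized for a single CPU:

* **Recovery** — 5 replicates of the default 16-year scenario, each fitted
  with the full protocol (3 × 3,000 iterations). Recovery is assessed on the
  mean annual rate per habitat (the identified quantity under year random
  effects) against the realised generating means; errors are averaged over
  replicates and coverage pooled over rate × habitat × replicate.
* **LTRE identities** — exact closed forms are checked to 1e-12; the
  first-order adequacy bound (residual < 15% of var λ) is checked on
  generator output with the default variability.
* **Attribution** — 10 replicates of a dedicated stationary scenario
  (N ≈ 360 per class, brood records subsampled to ~55/year, ~600 marked)
  with fledgling effect magnitudes temp 2.0 > prec 0.7 > del 0.06 and
  reduced-length chains (2 × 600). Ordering of the recovered variance
  shares is the test statistic. With only 15 annual transitions the realised
  low-frequency content of each covariate is itself random (roughly two
  effective degrees of freedom), so effect magnitudes must be well separated
  for the ordering to be recoverable at all — a real limit of
  trajectory-variance attribution on short series, not an artefact of the
  implementation.

## Numerical choices

Tolerances: movement rows must sum to 1 within 1e-8 (inputs) and the
transition matrix rows within 1e-12 (outputs); the forward algorithm
rescales at every occasion, and −∞ is a legal likelihood value (impossible
history), never an exception. Ties in the simplification overlap are broken
by candidate enumeration order (fledglings before survival). Degenerate
inputs: empty data components contribute likelihood 0 (a prior-only run
samples the priors); zero totals make growth rates undefined and are
rejected in the LTRE; a constant observed count series makes R² undefined
and is rejected. All randomness descends from a single integer seed through
`numpy` SeedSequences (chain c of seed s uses SeedSequence([s, c])), and
equal seeds give bit-identical output.
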