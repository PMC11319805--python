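# Methods

`lookstack` implements a multi-hypothesis ("looking framework") analysis of
focal-sampling data on animal visual behaviour, together with a synthetic-data
generator that reproduces the statistical structure such studies assume. This
note documents the models, the generator, the numerical choices, and what the
package's tests do and do not demonstrate.

## The observable and the two responses

The unit of data is a 30-second continuous focal observation of one
individual. Two responses summarise its looking behaviour:

- **frequency** — the number of looking bouts begun during the focal;
- **duration** — the total seconds spent looking.

Both are conditioned on the *in-view exposure* `E ∈ (0, 30]`: the seconds for
which at least half the animal's face was visible. Total looking duration can
never exceed `E`, so records with `duration = E` are right-censored — the
true value may be larger.

## Likelihoods

**Frequency** models are Poisson GLMMs with a log link and a log-exposure
offset:

    y_i ~ Poisson(λ_i),   log λ_i = x_i'β + u_date(i) + u_id(i) + log E_i.

**Duration** models are Gaussian on the identity link, truncated below at
zero (durations cannot be negative) and right-censored at the exposure. The
offset enters untransformed with a unit coefficient:

    latent_i ~ Normal(μ_i, σ) truncated at 0,
    μ_i = x_i'β + u_date(i) + u_id(i) + E_i,
    observed_i = min(latent_i, E_i),  censored_i = [latent_i ≥ E_i].

The censored-record log-likelihood is `log[1 − Φ((E−μ)/σ)] − log Φ(μ/σ)`; the
uncensored one is the truncated-normal density with the same normaliser. A
quadrature test confirms density plus censor mass integrate to one.

Because the identity-link offset adds the full exposure (~25–30 s) to μ, a
realistic mean duration of 7–8 s requires a strongly negative intercept; the
generator's duration defaults use `Intercept ≈ −20`, giving partial
censoring at plausible rates.

**Random effects.** Observation date and individual identity enter as crossed
Gaussian random intercepts in every model.

**Priors.** All location parameters get Student-t(3, 0, 10); random-effect
standard deviations and the residual σ get half-Student-t(3, 0, 10). These are
weakly informative at the scale of the raw (uncentred, unscaled) predictors.

## The hypothesis set

Twenty-one models per response encode competing explanations of looking:
an intercept-only baseline (1); a minimal model with age-sex class and a
behaviour covariate (2); group geometry/cohesion (3); feeding rate and food
items (4); individual behaviour durations (5); nine reactionary
time-since-event models (6–14); within-group social threats (15); five
pre-emptive spatial-risk models with risk × (cohesion + position + behaviour)
interactions (16–20); and observer tolerance × observer behaviour (21).

The behaviour covariate is response-specific: time spent in *engaged*
behaviours (requiring eyes and hands: grooming another, self-grooming,
digging, searching substrate, picking, aggression/play) for frequency, and
time spent *not engaged* (resting, chewing, biting, handling, movement, …)
for duration. Model 5 uses the individual behaviour durations as separate
covariates; resting is excluded there for collinearity (the behaviour budget
is nearly closed), and a separate resting-only specification is provided.
Model 5's "posture" term is carried as a not-engaged behaviour duration in
the controlled vocabulary.

Categorical terms are treatment-coded against fixed references (age-sex:
adult-male; habitat: forest; time-since: no-event; position: central;
food item: none; familiarity: core). Variables are never centred or scaled.
The model set serialises to YAML so hypotheses can be added or disabled
without code changes.

## Derived predictors

- **Time since event** — per event type, each focal is exactly one of
  {no event that day, ongoing, 0–5, 5–10, 10–15, >15 min post event}. Bins
  are half-open `[0,5), [5,10), [10,15), [15,∞)` measured from the end of the
  most recent event to focal start; an ongoing event dominates.
- **Dominance rank** — I&SI ordering of the directed win matrix: minimise the
  number of inconsistent dyads `I`, then their summed rank distance `SI`.
  Exhaustive search up to 8 individuals; beyond that a seeded hill climb with
  10 random restarts, started from the net-wins order. The climb uses both
  pairwise swaps and single-element insertions — swaps alone stall in local
  optima on a few percent of random matrices, and insertions are the stronger
  neighbourhood for linear-ordering problems. Tests verify the heuristic
  equals the exhaustive optimum on random 6- and 7-individual matrices.
- **Grooming cliques** — community detection on the weighted grooming graph.
  Default: greedy modularity maximisation; a spin-glass method is available
  behind the same interface. Partitions with non-positive modularity collapse
  to a single clique.
- **Within-group threats** — higher-ranked neighbours within 5 m minus
  higher-ranked neighbours of the focal's own clique, floored at zero.
- **Spatial layers** — utilisation distribution (UD), predator
  resource-selection surface, and extra-group encounter surface, each
  linearly stretched to [0, 1] (`(v−min)/(max−min)`; a constant layer is
  defined to stretch to all zeros). Familiarity is the inverted UD. Encounter
  risk is the stretched encounter surface divided cellwise by the stretched
  UD (cells of zero range use are masked) and re-stretched. Familiarity
  *classes* (core / frequent / boundary) are terciles of cumulative
  utilisation mass — isopleth logic — not terciles of raw cell value. Scale
  integration of two RSF orders is pluggable: cellwise product (default) or
  mean, re-stretched either way.

## Inference

The sampler is an adaptive random-walk Metropolis-within-Gibbs scheme run
vectorised across chains:

1. all fixed-effect coefficients jointly, with a Haario-style empirical
   covariance proposal learned during warmup (target acceptance 0.27);
2. date intercepts coordinate-wise — their full conditional factorises
   because each observation belongs to one date (target 0.44);
3. individual intercepts likewise;
4. log-scale parameters (random-effect sds, σ) as one small block;
5. translation moves that shift mass between the intercept and the mean of
   each random-intercept block. These leave the likelihood invariant, are
   accepted on the prior ratio alone, and decorrelate the intercept from the
   random effects — without them the chains cross that ridge very slowly.

Scale parameters are sampled on the log scale with the Jacobian applied;
draws are reported on the natural scale. Duration models initialise every
parameter at zero, which is always a finite point of the censored/truncated
posterior; frequency models add a small seeded jitter. Defaults are 4 chains
× 1000 iterations (500 warmup); `FitSettings.full_scale()` gives the full
4 × 2000/1000 schedule. Convergence is summarised by split-R-hat and bulk
ESS per parameter.

Conditional quantities (pointwise log-likelihood, conditional predictions)
include the sampled random intercepts; marginal quantities set them to zero.

## Model comparison

**PSIS-LOO.** Per observation, raw importance ratios `1/p(y_i|θ_s)` are
Pareto-smoothed: the `M = min(0.2 S, 3 √S)` largest log-ratios are replaced by
expected order statistics of a generalized Pareto distribution fitted to the
tail by the Zhang–Stephens profile estimator (with the usual weak
regularisation of the shape toward 0.5), then truncated at the raw maximum.
The fitted shape k̂ is the per-observation reliability diagnostic; values
above 0.7 are flagged. An exact-LOO oracle (n refits, scoring each held-out
observation against grouping levels fixed from the full table) validates the
approximation in tests.

**Stacking.** Weights maximise `Σ_i log Σ_k w_k exp(elpd_ik)` over the
simplex. The problem is concave; the solver uses a softmax parameterisation
(last logit pinned) with L-BFGS from several seeded starts, tolerance 1e-10,
and is checked against a 1e-4-step grid search for two models. A second stage
re-stacks the models retained at a configurable weight threshold (default
0.001 — the package honours both published phrasings, "non-zero" and "at
least 0.001", via this config), separating weight genuinely earned from
weight shared among similar models. Weights render at 3 decimals with an
"accurate" flag at ≥ 0.1.

**LOO-R².** Per posterior draw, `R² = Var(pred) / (Var(pred) + Var(e))`,
where `e` are LOO residuals: observed responses minus PSIS-weighted
leave-one-out predictive means. Marginal R² zeroes the random intercepts in
the predictor; conditional R² keeps them. Under this ratio form R² lies in
[0, 1]; implementations that instead use `1 − Var(e)/Var(y)` can go slightly
negative for useless models — the two agree in ordering and in the
"near zero for the null model" regime the tests check. Point estimate is the
mean over draws with 2.5/97.5% quantile intervals. For duration models the
predictions are the latent means, so R² is on the latent (uncensored) scale.

## The synthetic-data generator

The generator emulates the study conditions end to end:

- **Roster** — unique ids, age-sex classes (15/35/20/30% adult-male /
  adult-female / subadult / juvenile), a latent rank permutation, balanced
  grooming cliques (sizes within one), and observer-tolerance scores drawn
  centred at zero.
- **Sampling rules** — each observation day is a nominal 12 h split into four
  equal time periods (the field protocol's seasonally adjusted quarters are
  approximated by fixed quarters); an individual is sampled at most twice per
  day and at most once per period.
- **Events** — per event type, homogeneous Poisson starts (default rates
  0.1–1.5 per hour by type) with exponential durations (mean 2 min). The
  time-since category of a focal follows from the simulated event log; the
  stationary fraction of "ongoing" focals matches the M/G/∞ occupancy
  `1 − exp(−rate × mean duration)` in tests.
- **Context** — in-view exposure `30 − 5·Beta(1,4)` (mostly near 30 s, ≥25 s
  as successful focals require); neighbour counts Poisson(2.5) capped at
  group size; visibility as the mean of start/end assessments; behaviour
  budgets Dirichlet(0.3) over the 17-behaviour vocabulary scaled to 30 s;
  locations drawn proportional to the UD.
- **Responses** — generated from the named hypothesis model's design with
  user-named coefficients (unnamed columns are zero), crossed random
  intercepts, and the exact likelihoods above.
- **Interaction data** — agonistic outcomes with
  `P(i beats j) = logistic(steepness × rank advantage)` (total count
  preserved, e.g. 638 to match a season of ad libitum records); grooming
  weights Poisson with higher within-clique than between-clique rates.
- **Landscape** — UD from smoothed visit counts around a few core areas (a
  grid stand-in for a home-range estimator; only the downstream [0,1] surface
  is consumed), a smooth predator-selection field, an encounter surface whose
  total mass is configurable (default 240 encounters), and a habitat layer
  quantised from a smooth field over eight types.

One master seed drives deterministic per-component streams
(`SeedSequence.spawn`), so identical configs give byte-identical datasets,
fits, and report tables.

**What the generator does not emulate:** real movement ecology (locations are
iid draws from the UD, not trajectories), seasonal daylength changes, weather,
demography (no births, deaths, or migration mid-study), observer-choice bias
in focal selection, and any dependence of behaviour budgets on location or
events. Passing tests therefore demonstrate that the *analysis machinery* is
correct and well calibrated under the assumed data-generating process, not
that the process matches any particular field system.

## Validation experiments and problem sizes

Simulation studies in `lookstack.calibration` use desk-scale defaults chosen
to keep a full validation run in minutes while leaving clear statistical
margins:

- **Generative recovery** — 15 individuals × 10 days × 30 focals/day
  (300 focals; the two-per-individual-per-day sampling rule caps daily
  output at twice the group size, so smaller groups cannot reach this rate). Data are simulated from the feeding-rate hypothesis
  (frequency) or the within-group-threat hypothesis (duration) with strong
  coefficients; the generating model must take the top stacking weight
  against the intercept-only and minimal models in at least 15 of 20 seeded
  replicates. Observed: the true model typically takes ≥ 0.9 of the weight.
- **Interval coverage** — same size; pooled over replicates and generating
  coefficients, 95% intervals must cover at least 85% of the time
  (20 replicates × 5 coefficients; a per-replicate "all coefficients covered"
  reading would be mis-calibrated by construction, since even exact 95%
  intervals jointly miss ~23% of the time with five coefficients).
- **PSIS versus exact LOO** — a 30-observation Poisson regression with 2000
  posterior draws; mean pointwise gap under 0.1 with all k̂ < 0.7.

## Known limitations

- The random-walk sampler needs more iterations than a gradient-based sampler
  would for the same effective sample size; R-hat and ESS are reported so
  under-mixed fits are visible. Very high-dimensional designs (e.g. model 17
  with many habitat levels plus interactions) mix the slowest.
- Exact LOO refits n times and is only practical at oracle scale.
- The duration R² is computed on the latent scale; censored observations
  contribute their capped values to the residuals.
- The spin-glass community method requires a connected graph per component
  and is slower than the default greedy modularity.
- `ingest_dataset` validates row invariants but trusts the supplied schema
  map; it cannot detect semantically wrong columns with plausible values.
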