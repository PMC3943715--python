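# Methods

This note records the modelling conventions, default parameters and
numerical choices in rodentcam, and what the synthetic validation does and
does not establish about real surveys.

## Events and survey nights

- **Survey night**: noon-to-noon in local time, counted from the noon at
  or before the deployment start.  A nocturnal rodent's activity bout then
  falls within a single night rather than being split at midnight.
- **15-minute bins**: clock-aligned (:00/:15/:30/:45) by default, which is
  deterministic and invariant to record order; an alternative anchored at
  each site's deployment start is available
  (`assign_survey_nights(..., bin_anchor="deployment")`).  One *event* is
  one occupied (site, species, night, bin) cell however many triggers fell
  in it; no further deduplication below the bin (the camera's own idle
  period is treated as upstream hardware behaviour).
- **Nights observed**: deployment duration in days (fractional, so partial
  first/last nights count proportionally).  An integer "camera nights"
  mode counts intersected night windows instead
  (`nights_observed(..., mode="integer")`).
- Rows with unparseable timestamps are excluded and counted, never
  silently dropped; records outside the deployment window are flagged and
  removed.  Species labels are case-folded and passed through an optional
  alias map before any counting.

## Occupancy and detection

- Likelihood: zero-inflated Bernoulli per site, ragged histories allowed —
  each site contributes only its surveyed nights, and the number of nights
  T is inferred from the data, never hard-coded.
- Fitting: BFGS with an analytic gradient on logit(ψ), logit(p)
  (gradient tolerance 1e-8), 5 starts (naive estimates; 0.5; random),
  best log-likelihood wins, ties broken toward fewer parameters in the
  comparison table.  K = 2 (constant p) or T + 1 (night-varying).
- Uncertainty: observed information at the MLE on the logit scale, delta
  method to the probability scale, Wald 95% intervals back-transformed so
  they always lie in [0, 1] (the convention of standard occupancy
  software).
- Degenerate data sit on the boundary and are returned exactly there with
  a `boundary` flag and undefined SEs: no detections at all (ψ
  unidentifiable, reported as ψ = 0) and saturated detection (ψ = p = 1,
  log-likelihood 0).  Non-convergence is flagged, never silent.
- `nights_to_confidence`: scalar p uses the closed form
  ⌈log(1−level)/log(1−p)⌉; a fitted night-varying vector is scanned in
  night order and may return "not reached" with the achieved cumulative
  probability.  Cumulative-detection CIs propagate the per-night interval
  endpoints through the monotone product formula.

## Habitat covariates

- **PCQ density**: default estimator D = 10⁴/μ² burrows/ha with μ the mean
  of the four quadrant distances.  With only four distances per point this
  classic form is biased upward by roughly +20–27% on a homogeneous Poisson
  field (delta-method prediction confirmed by simulation); the per-point
  unbiased Pollard form 4(4n−1)/(π Σd²) is available via
  `method="pollard"`, and `pooled_pcq_density` pools distances across
  sites for a consistent survey-level estimate.  Consistency tests
  therefore validate the Pollard and pooled forms; the default remains
  the classic estimator because it is the form used in field practice for
  site-level covariates, and all candidate-model comparisons are invariant
  to a monotone rescaling of a covariate's bias.
- **Empty quadrants** (no burrow within the 40 m truncation): the
  truncation distance is substituted into μ — conservative, biasing
  density downward — and the site is flagged.  Sites with no burrow in any
  quadrant get density 0.
- Burrow types are kept separate (penguin → Emden, shearwater → Atden)
  and summed into BD afterwards, matching the candidate models' use of the
  covariates.
- **Structural complexity**: mean over the 8 poles of summed touches in
  the chosen 100-mm bands; default band 100–400 mm (near-ground cover that
  shelters small rodents).  Cover above 1 m (C_gt1m) is a visual percent
  estimate, not a pole measure.
- Covariates are used unstandardized by default so coefficients are per
  raw unit (percent cover, touches, burrows/ha); z-scoring is opt-in and
  recorded in the table's metadata.  A collinearity screen reports the
  maximum |r| and all pairs above 0.55.

## Activity GLMs and model selection

- **Response**: per-site total event count with offset log(nights
  observed).  This keeps the NB likelihood on genuine integers while
  adjusting for unequal effort; a per-night-row layout can be fit by
  passing those rows and offsets directly.
- **Fitting**: IRLS for the coefficients at fixed θ (statsmodels GLM,
  NB2 family) alternated with univariate ML for θ on log scale
  (bounded at e^±18 so a Poisson-like fit cannot overflow), declared
  converged when the relative log-likelihood change is below 1e-9.
  K counts the dispersion parameter.  `fixed_theta` holds dispersion at a
  known value (very large θ reduces the model to Poisson, which is how the
  Poisson-limit oracle test works).
- **Criteria**: AIC = −2ℓ + 2K and AICc = AIC + 2K(K+1)/(n−K−1) are both
  reported in every table; AICc (n = number of sites) drives the activity
  candidate sets, plain AIC the two-model detection comparison.  Akaike
  weights are invariant to rebasing of the criterion column.
- **Candidate sets**: fixed a-priori lists (12 models for the black rat,
  13 for the house mouse, which adds black-rat activity RR as a
  covariate); every interaction model contains its main effects.
- **Averaging**: full model averaging with shrinkage (a model excluding a
  term contributes β = 0), unconditional SE
  Σ ω_i √(SE_i² + (β_i − β̄)²), 95% CI = β̄ ± 1.96 SE, importance = summed
  weight of models containing the term.  Conditional averaging is a flag.
  Averaging is triggered when the top model's weight falls below 0.9
  (configurable) — "selection uncertainty" has no canonical definition, so
  the threshold is explicit.

## The synthetic study generator

The generator emulates a systematic island survey: 276 sites surveyed in
blocks of 50 cameras for 8 nights each, two introduced rodents, habitat
covariates with realistic ranges.  Its layered structure makes the
occupancy parameters exact by construction: occupancy z ~ Bernoulli(ψ);
nightly activity y_t ~ Bernoulli(z·p_t); given activity, events per night
are zero-truncated NB(λ_s, θ) with log λ_s linear in the site covariates;
each event yields 1–3 triggers uniformly placed inside its 15-minute bin.
P(≥1 event on night t | occupied) = p_t exactly, so detection histories
derived from the simulated triggers follow the fitted occupancy model
with the configured (ψ, p).

Defaults (one species parameter set per rodent):

| parameter | black rat | house mouse | meaning |
|---|---|---|---|
| ψ | 0.90 | 0.58 | site occupancy probability |
| p (8 nights) | 0.62…0.30 (peak 0.79) | 0.45…0.29 (peak 0.59) | nightly detection, spanning the ranges typical of baited horizontal cameras; imply 3 / 5 nights to 95% confident absence |
| intercept | 1.77 | −0.12 | log events per active night at covariate 0 |
| betas | C_gt1m +0.012 | C_gt1m −0.006, Rhag +0.012, C10_40 +0.04 | per-unit log-rate effects |
| θ | 1.0 | 0.3 | NB dispersion (smaller = more clumped) |

These give mean activity among detected sites of ≈5.4 (rat) and ≈1.4
(mouse) events per night.  Covariates: covers from a symmetric Dirichlet
scaled to 100; overstorey percent Beta(1.5, 3)·100; pole touches
Binomial(10, site-complexity × height-decaying band weight); burrow fields
homogeneous Poisson within a colony (colony membership Bernoulli,
intensity Gamma), with quadrant nearest-distances drawn from the exact
quarter-plane distribution P(D > d) = exp(−λπd²/4).

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: site-to-site heterogeneity in
detection probability (a homogeneous-p generator cannot reproduce the
extremely skewed activity medians real mouse surveys show), camera
failures and memory-card truncation, weather- or moon-driven nightly
covariance, species misidentification, movement-induced spatial
autocorrelation between neighbouring sites, and burrow-field clustering.
Estimator behaviour under those violations is untested here.

## Validation problem sizes

The test suite and the acceptance script size their simulations as: 200
replicates of 276 sites × 8 nights for occupancy recovery (mean ψ̂ within
±0.02 of truth, CI coverage 92–98%); 5 000 sites for PCQ consistency
(mean within 10% of the generating intensity); 1 000 random vectors for
cumulative-detection monotonicity; a 10⁻³ grid for the two-parameter MLE
oracle; 200 replicates for GLM Wald coverage.  These sizes give
Monte-Carlo error comfortably below the asserted tolerances.

## Known limitations

- No covariates on ψ or p, no multi-season dynamics, no abundance-from-
  detection models: the occupancy layer is deliberately the simple
  single-season form.
- The activity index assumes activity is monotone in local density;
  converting it to absolute density requires calibration data this
  package does not model.
- Model averaging assumes the candidate set is the hypothesis space;
  weights say nothing about models not in the set.
- The PCQ estimator assumes burrows form a locally homogeneous field;
  strong clustering inflates site-level variance beyond what the
  truncation flagging reveals.
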