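# rodentcam

Statistical pipeline for monitoring invasive rodents (black rat *Rattus
rattus*, house mouse *Mus musculus*) with motion-triggered camera traps in
high conservation-value ecosystems, where live trapping under-detects
trap-adverse species and endangers non-targets such as burrow-nesting
seabirds.  It is written for ecologists who run grid surveys of baited,
horizontally mounted cameras and need to answer three questions:

1. **Is the species there?** — single-season occupancy models with nightly
   detection probabilities, and the survey effort needed to call an
   absence with confidence.
2. **How active is it?** — a discrete-event activity index from
   trigger-level records.
3. **What habitat drives the activity?** — negative binomial GLMs over an
   a-priori candidate set, ranked by AICc with model averaging.

## The models

**Events and the activity index.**  Each survey night (noon-to-noon local
time) is divided into 96 clock-aligned 15-minute intervals; a species
present in an interval is one *event* regardless of how many camera
triggers it produced.  The activity index of a site is events per 24 h of
survey, a relative-abundance proxy.

**Occupancy / detection.**  With ψ the probability a site is occupied and
p_t the probability an occupied site is detected on night t, the site
likelihood of a binary detection history y is

    L = ψ ∏_t p_t^{y_t} (1 − p_t)^{1 − y_t}  +  (1 − ψ) · 1[all y_t = 0],

maximised on the logit scale (constant-p model, K = 2, or night-varying
model, K = T + 1).  The cumulative detection probability over n nights is
P_n = 1 − ∏_{t ≤ n}(1 − p_t); the smallest n with P_n ≥ 0.95 is the number
of empty nights needed to be 95% confident a site is truly unoccupied.

**Habitat covariates.**  Seabird burrow density per site by the
point-centre-quarter method (D = 10⁴/μ² burrows/ha, μ the mean of the four
quadrant nearest-burrow distances, truncated at 40 m); near-ground
structural complexity as mean vegetation touches at 100–400 mm on a
structure pole; percent covers of the dominant plants and of vegetation
above 1 m.

**Activity GLMs.**  Per-site event totals are modelled as NB2 (variance
μ + μ²/θ) with log link and offset log(nights observed).  Candidate models
are compared by AICc = −2ℓ + 2K + 2K(K+1)/(n−K−1); Akaike weights
ω_i ∝ exp(−Δ_i/2) quantify support, and coefficients are averaged across
the set (full averaging with shrinkage, unconditional standard errors).

A synthetic-study generator (`rodentcam.synthetic`) produces trigger
records, deployment logs and habitat surveys with exactly this structure
plus a truth record, so every estimator is validated by parameter
recovery.

## Worked example

`examples/02_occupancy_confidence.py` simulates the default 276-site,
8-night survey, fits both detection models for the black rat and prints:

```
Detection-model comparison (psi constant in both):
         Model  K  minus2LL     AIC  delta  weight
psi(.)p(night)  9   2712.50 2730.50   0.00     1.0
    psi(.)p(.)  2   2883.89 2887.89 157.39     0.0

Best model: psi(.)p(night); occupancy psi = 0.896 (95% CI 0.853-0.927)
Nightly detection probabilities: [0.61, 0.7, 0.81, 0.66, 0.57, 0.46, 0.38, 0.38]
...
3 consecutive non-detection nights give 97.7% confidence the site is unoccupied.
```

Night-varying detection is decisively preferred (all Akaike weight), the
occupancy estimate recovers the generating ψ = 0.90, and the fitted
nightly detection probabilities imply that three silent nights are enough
to call a black-rat absence at 95% confidence.  The other examples cover
event reduction and occurrence tables (`01`), the point-centre-quarter and
complexity covariates (`03`), and NB candidate-model selection with model
averaging (`04`).

A thin CLI wraps the same functions:

```bash
rodentcam simulate --seed 1 --out study/
rodentcam events --triggers study/triggers.csv --deployments study/deployments.csv --out out/
rodentcam occupancy --histories out/histories_black_rat.csv --out out/
rodentcam habitat --pcq study/pcq.csv --poles study/poles.csv --covers study/covers.csv --out out/covariates.csv
rodentcam glm --activity out/activity.csv --covariates out/covariates.csv --species black_rat --out out/
rodentcam run --config pipeline.yaml
```

## Layout

- `src/rodentcam/synthetic.py` — study generator with truth record
- `src/rodentcam/events.py` — triggers → events, activity, histories
- `src/rodentcam/occupancy.py` — ψ/p MLE, detection curves, confident absence
- `src/rodentcam/habitat.py` — PCQ density, structural complexity, covers
- `src/rodentcam/model_selection.py` — NB GLMs, AIC/AICc, weights, averaging
- `src/rodentcam/pipeline.py`, `cli.py`, `plots.py` — orchestration, shell, figures
- `docs/methods.md` — modelling conventions, defaults and limitations
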