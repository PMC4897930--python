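# Methods

`microprev` estimates the prevalence of behavioural risk factors (current
smoking, excess bodyweight) for *micro areas* — census units of roughly
400–700 residents — from pooled cycles of a complex health survey, and flags
areas whose prevalence credibly exceeds the regional average.  Because the
survey microdata such pipelines consume are confidential, the package ships a
synthetic-data generator with known ground truth; every stage is validated
against that truth.

## The model

For respondent *i* of one sex stratum living in micro area *j(i)*, the binary
outcome is modelled as

    y_i ~ Bernoulli(p_i)
    logit p_i = β₀ + β_cycle[c_i] + β_age[a_i] + γ·x_{j(i)} + u_{j(i)} + v_{j(i)}

with survey cycle (reference: cycle 1) and eight age bands (reference: 50–59)
as categorical fixed effects, and — in *model 2* — the area's median
household income `x_j`, centred at the study mean and scaled per $10,000.
*Model 1* omits income.  Models are fitted separately by sex.

The area effects follow the Besag–York–Mollié decomposition:

* `u` — intrinsic conditional autoregressive (ICAR) effect over the adjacency
  graph, pairwise-difference form `p(u|τ_u) ∝ τ_u^{(J−k)/2} exp(−τ_u/2 Σ_{i~j}(u_i−u_j)²)`
  (J areas, k connected components), identified by a sum-to-zero constraint;
* `v` — exchangeable Normal(0, σ_v²) effect.

Priors: Normal(0, 10) on all fixed effects; on the scales either
Gamma(0.5, rate 0.0005) hyperpriors on the precisions (default) or
Uniform(0, 10) on the standard deviations — the two arms of the
prior-sensitivity check.  These are conventional vague choices for this model
family; `prior_sensitivity` refits with both and reports the largest shift in
area-level posterior means.

Areas with suppressed income are dropped from model-2 fits (recorded in
`CellData.dropped_area_ids`); no prevalence is reported for them under
model 2.  Islands (areas without neighbours) are removed when the adjacency
graph is built, since an unsmoothed estimate would not be comparable.

## Sampling

Inference is Metropolis-within-Gibbs.  Respondents are aggregated to
(area, cycle, age band) binomial cells — an exact reformulation of the
Bernoulli likelihood that makes each sweep a handful of vectorised passes:

* scalar random-walk updates for β₀ and γ; one-pass per-level updates for the
  cycle and age effects (levels occupy disjoint cells, so simultaneous
  per-level accept/reject is a sequence of valid scalar updates);
* a joint per-area proposal for `u`, accepted colour class by colour class of
  a greedy graph colouring — areas of one colour are mutually non-adjacent,
  so their ICAR full conditionals do not interact — followed by re-centring
  `u` to sum to zero with a compensating shift of β₀;
* a one-block independent per-area update for `v`;
* conjugate Gamma draws for both precisions (for the uniform-sd prior, the
  induced Gamma conditional truncated at σ < 10).

Proposal scales adapt towards ~44 % acceptance during burn-in (Robbins–Monro
style, every 50 sweeps) and are frozen afterwards, so the retained draws come
from a fixed transition kernel.  Runs are reproducible: one seed drives
per-chain `SeedSequence` streams.

Two presets are provided.  The production protocol (`production` preset) runs
3 chains with 500,000 burn-in sweeps and 50,000 further sweeps keeping every
10th draw — 15,000 saved draws.  The default `desk` preset (3 chains,
2,000 + 2,000 sweeps, thin 2; 3,000 saved draws) is sized for interactive
work and the test suite; on the 100-area study design it runs in seconds and
yields stable prevalence summaries.  Potential scale reduction (split-R̂) and
autocorrelation diagnostics are computed per parameter.  Note that σ_u and
σ_v individually mix slowly — the BYM decomposition only weakly identifies
the split between structured and unstructured variance — while their sum
(the area effects u+v), the fixed effects and all prevalence summaries mix
well; diagnostics should be read with that in mind.

Deviance is `−2·log L` under the Bernoulli likelihood (no binomial
coefficient, matching a product of per-respondent densities).  DIC is
`D̄ + pD` with `pD = D̄ − D(θ̄)` evaluated at the posterior means of all
parameters including both sets of area effects; differences above 7 are
treated as meaningful when comparing models 1 and 2.

## Post-stratification and validation

Each saved draw yields a probability for every (area, sex, cycle, age band)
cell through the inverse-logit of the linear predictor.  Cells are averaged
over cycles with equal weight (the pooled sample treats cycles as equally
informative; weighting by cycle share is available via `cycle_weights`) and
then weighted by the census age-band counts of the area.  The resulting
per-draw area prevalences give posterior means, standard deviations and
percentile intervals; county and regional summaries are census-population-
weighted combinations of the per-draw area values, so regional uncertainty is
propagated jointly.  Area prevalence refers to the 12+ population, matching
survey coverage.

Design-based comparators use the pooled weights: after K cycles are pooled,
design weights and bootstrap replicate weights are divided by K, which makes
the pooled weighted total the mean of the per-cycle totals while preserving
cycle-relative sizes (scaling by each cycle's population share is available
as `method="population_share"`).  The design-based group prevalence is the
weighted proportion, with variance the mean squared deviation of the
replicate-weight estimates and a normal 95 % interval.  `validate_model_vs_design`
reports, per county and sex, whether the model aggregate falls inside that
interval.

## Surveillance

An area is *flagged* when ≥ 95 % of posterior draws put its prevalence above
the regional average *of the same draw* — a joint-posterior exceedance
probability, not a comparison to a fixed point estimate.  Precision is graded
by the coefficient of variation (100·sd/mean) with the standard
survey-release bands: acceptable < 16.6 %, marginal 16.6–33.3 % (both
boundary values inclusive to the marginal band), low above 33.3 %.  Pearson
correlation between exceedance probabilities and CVs quantifies the expected
inverse relation (precisely estimated areas can reach decisive exceedance).
Temporal trend is tested by refitting with cycle as an integer covariate and
declaring the slope significant when the central 95 % credible interval
strictly excludes zero.

## Spatial autocorrelation screen

Before fitting the spatial model, Moran's I of the observed minus expected
area case counts (expected = overall proportion × area respondents, binary
contiguity weights) is referred to a parametric bootstrap: replicate counts
are simulated from a negative binomial with the expected counts as means and
a single dispersion fitted to the observed counts by the method of moments,
falling back to Poisson when the observed counts are underdispersed.  The
one-tailed p-value is `(1 + #{I_sim ≥ I_obs}) / (n_sim + 1)`.  Because the
null replicates absorb non-spatial overdispersion, the test responds to the
*arrangement* of excesses, not their mere presence; for binomial-type counts
it is mildly conservative (the simulated counts are more dispersed than the
data by a near-constant factor, which largely cancels in I).

## Bernoulli elliptical scan

Candidate windows are grown around every point for each axis ratio
(default 1, 1.5, 2, 3, 4, 5) and orientation (12 evenly spaced over 180°),
absorbing points in order of elliptical distance up to a population cap
(default 10 % of the population at risk).  Points at exactly tied distance
enter together, so every window is realisable as an ellipse — this also makes
the scan identical whether respondents are supplied as unit points or
aggregated to area centroids with case/population counts.  Windows are scored
by the one-sided Bernoulli log-likelihood ratio; no eccentricity penalty is
applied.  Significance comes from replicates that redistribute the observed
number of cases at random over the population (multivariate hypergeometric —
for unit points, a label permutation), with
`p = (1 + #{replicate max ≥ observed}) / (n_mc + 1)`; secondary clusters are
reported greedily after overlap removal and scored against the same
replicate-max distribution.

## The synthetic generator

The generator emulates the structure such a study consumes, with defaults
chosen as the study conditions:

* **Geography** — an `n_rows × n_cols` lattice with rook or queen adjacency
  and jittered centroids, partitioned into four quadrant counties.  The study
  design used throughout testing is 10 × 10 = 100 areas (a scaled-down stand-in
  for a ~1,000-area region).
* **Census** — area totals Normal(550, sd 12 %) (so means sit inside the
  400–700 band), split over sex × age cells with an age pyramid that is
  deliberately non-uniform (heavier 40–69 mass) so post-stratification and
  weighting errors are detectable.
* **Income** — base $60,000 + optional north–south gradient + Normal noise
  (sd $8,000), floored at $10,000; a chosen fraction of areas has the
  *observed* value suppressed while the latent value keeps driving outcomes.
* **Survey** — per cycle, each census person is included with probability
  `sampling_rate × age factor` (older people over-represented, factors
  0.60–1.40), design weight = inverse inclusion probability; five cycles at
  `sampling_rate = 0.055` yield ~15,000 respondents (~150 per area, i.e. a
  data-rich scaled-down analogue of ~13 per area across ~1,000 areas).
  Outcomes are Bernoulli with intercept logit(0.25), a gentle cycle decline,
  an age profile peaking in mid-adulthood, an income odds ratio of 0.88 per
  $10,000, and BYM effects with σ_u = 0.25, σ_v = 0.10 (together spanning
  roughly the 15-percentage-point prevalence range seen across real micro
  areas).  ICAR ground truth is drawn exactly through the graph Laplacian's
  eigenstructure and recentred.  Raw questionnaire fields (smoking response,
  height/weight, pregnancy/lactation) are synthesised consistently with the
  binary outcome so the classification stage is exercised; ~2 % of raw
  responses are missing.
* **Bootstrap weights** — with-replacement (Rao–Wu style) resampling within
  cycle, n−1 draws with the n/(n−1) correction.  Real survey bootstrap
  designs are more intricate (strata, clusters, weight adjustments); any
  valid replicate scheme supports the variance-estimation contract being
  tested.
* **Cluster implants** — `implant_cluster` re-draws outcomes in chosen areas
  with multiplied odds, giving a known target for the exceedance flags and
  the scan.

What the generator does *not* emulate: household clustering and multi-frame
telephone sampling, non-response and its weight adjustments, self-report
bias in height/weight/smoking, geocoding error, and realistic boundary
geometry.  Passing tests therefore demonstrate the statistical machinery is
correct under a faithful but idealised design, not that a real survey's
design complexities are handled.

## Numerical and design choices

* BMI classification embeds the published IOTF age/sex thresholds
  (half-yearly, ages 12–18) and uses the nearest half-year for fractional
  ages; heights above 3 m are rejected as unit errors.  Adults use
  BMI ≥ 25; pregnant or lactating respondents are excluded explicitly.
* Excess-bodyweight and smoking classifications are pure functions with
  explicit `missing`/`excluded` states; no record is silently dropped.
* `compare_models_dic` refuses to compare fits whose data fingerprints
  (outcome, stratum, respondent totals) differ.
* Moran's I uses binary weights by default (row-standardised optional);
  ties in the scan's elliptical distances are grouped; `0·log 0 ≡ 0`
  throughout the scan likelihood ratio; Monte-Carlo p-values can never fall
  below `1/(n_sim+1)`.
* Split-R̂ of chains whose draws are all identical is defined as 1.0
  (degenerate but converged); otherwise the standard split-chain
  variance-ratio formula is used.
* Problem sizes in the test suite and acceptance script (100 areas, ~15,000
  respondents, desk MCMC preset, 199–999 Monte-Carlo replicates, 10–20
  replicate studies) are the package's scaled-down study design; the production
  preset is provided for production runs.

## Known limitations

* The sum-to-zero re-centring with intercept compensation is the standard
  practical device for ICAR identification; it is exact for a flat intercept
  prior and a negligible approximation under the vague Normal(0, 10) prior
  (verified against an independent ensemble-sampler oracle in the tests).
* σ_u/σ_v are reported but weakly identified individually (see above).
* The scan reports at most a handful of non-overlapping clusters and does not
  adjust the exceedance flags for multiple testing (none is applied upstream
  either; the 95 % exceedance rule is already conservative).
* Model 2 drops income-suppressed areas rather than imputing income.
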