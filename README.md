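# microprev

Micro-area prevalence estimation for behavioural risk factors from pooled
complex-survey data.

Health surveys report smoking and excess-bodyweight prevalence reliably at
the region or health-unit level, but public-health programmes are planned for
much smaller communities, where direct survey estimates are too sparse to
release.  `microprev` implements the full small-area estimation pipeline for
this problem, aimed at epidemiologists and public-health analysts:

1. **Cohort construction** — classify current smoking (daily/occasional) and
   excess bodyweight (BMI ≥ 25 kg/m², IOTF age/sex thresholds for ages
   12–17, pregnancy/lactation exclusions) and rescale design and bootstrap
   replicate weights for pooled multi-cycle analysis.
2. **Spatial screen** — Moran's *I* on observed vs expected area counts with
   a negative-binomial parametric-bootstrap null.
3. **Hierarchical spatial model** — a sex-stratified Bayesian logistic model
   with Besag–York–Mollié area effects, fitted by MCMC:

       logit p_i = β₀ + β_cycle[c_i] + β_age[a_i] + γ·income_j/10,000 + u_j + v_j

   with `u` an intrinsic CAR (ICAR) spatial effect on the adjacency graph
   (sum-to-zero) and `v` an iid normal effect.  Model 1 omits the income
   covariate, model 2 includes it; DIC (differences > 7 meaningful) compares
   them, and Gamma-precision vs uniform-sd hyperpriors provide a
   prior-sensitivity check.
4. **Post-stratification** — posterior draws are converted to per-area
   prevalence weighted by census age–sex counts, aggregated to counties and
   the region, and validated against design-based (bootstrap-weighted)
   survey estimates.
5. **Surveillance** — areas where ≥ 95 % of draws exceed the regional
   average are flagged; estimate precision is graded by coefficient of
   variation (acceptable < 16.6 %, marginal 16.6–33.3 %, low > 33.3 %); a
   Bernoulli elliptical spatial scan statistic with Monte-Carlo inference
   independently corroborates flagged clusters.

Because the survey microdata this pipeline is designed for are confidential,
the package includes a first-class synthetic-data generator
(`microprev.synthetic`) producing geography, census structure, incomes, and
pooled survey respondents with known ground truth; all validation runs
against it.

## Worked example

```python
import numpy as np
import microprev as mp

# synthetic study: 100 micro areas, 5 pooled survey cycles
areas = mp.make_geography(10, 10, "queen", seed=1)
mp.simulate_census(areas, seed=2)
mp.simulate_income(areas, missing_fraction=0.0, seed=3)
truth = mp.make_ground_truth(areas, seed=4)        # income OR 0.88 per $10k
resp = mp.simulate_survey(areas, truth, n_cycles=5,
                          sampling_rate=0.055, n_bootstrap=0, seed=5)

spec = mp.ModelSpec(outcome="current_smoking", sex_stratum="M",
                    include_income=True)            # model 2
data = mp.build_cell_data(resp, areas, spec)
draws = mp.fit_bym(data, spec, mp.MCMCConfig.desk_preset(seed=7))

print(len(resp), "respondents")
print("income OR per $10k:", np.exp(draws.gamma).mean().round(3))
print("95% CI:", np.exp(np.quantile(draws.gamma, [0.025, 0.975])).round(3))

cells = mp.cell_prevalence_draws(draws)
ad = mp.area_prevalence_draws(cells, areas)
region = mp.aggregate_prevalence(ad, areas, "region", sex="M")
rep = mp.surveillance_report(ad, region.loc["region", "draws"])
print("flagged areas:", int(rep.per_area["flagged"].sum()))
```

Output:

```
15256 respondents
income OR per $10k: 0.902
95% CI: [0.823 0.981]
flagged areas: 4
```

The generating odds ratio (0.88 per $10,000) is recovered inside the 95 %
credible interval; with no implanted cluster, only the few areas whose true
random effects are largest are flagged.  A thin CLI mirrors this flow
(`microprev simulate | fit | poststratify | report | scan`).

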