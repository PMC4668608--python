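# sharedcar

Bayesian **shared spatial-component modelling** of correlated binary outcomes
over areal units, with intrinsic conditional autoregressive (CAR) random
fields, Pólya–Gamma Gibbs inference, and the full small-area diagnostic
toolkit (DIC, posterior predictive coverage, Gelman–Rubin, exceedance maps,
relative weights).

## The problem

Small-area studies of treatment choice — the motivating application is
women's intended use of three adjuvant breast-cancer therapies
(radiotherapy, chemotherapy, hormonal therapy) across several hundred
statistical local areas — face two coupled difficulties: the three binary
outcomes per patient are correlated, and residual geographic variation is
spatially structured.  A shared-component model separates the spatial signal
common to all outcomes (e.g. ease of access to treatment facilities) from
outcome-specific spatial residuals.

For individual *j* in area *i* and treatment *k* ∈ {1, 2, 3}:

```
Y_ijk ~ Bernoulli(p_ijk)
logit(p_ijk) = α_k + β_k' X_ij + u_ik + η_ik,      η_ik = δ_k φ_i + s_ik
```

* `φ` — the **shared spatial component**, one intrinsic-CAR field common to
  all treatments; `exp(φ_i)` is the shared spatial odds ratio of area *i*.
* `δ_k` — positive treatment weights, constrained to `δ_1 δ_2 δ_3 = 1`; the
  ratios `δ_k/δ_l` measure the relative influence of the shared component.
* `s_ik` — treatment-specific intrinsic-CAR fields (sum-to-zero per
  connected map component, like `φ`).
* `u_ik` — spatially unstructured trivariate effects with a
  Wishart(I₃, 5)-prior precision, allowing correlation between treatments.
* `α_k, β_k` — intercepts and fixed effects for ten categorical covariates,
  with hierarchical Gaussian priors (Gamma(0.005, 0.5) precision
  hyperpriors); CAR precisions carry Gamma(0.5, 0.005) hyperpriors and free
  log-weights a Gaussian(0, precision 5.9) prior.

Eight model variants are built in (`A0` baseline; `A1` independent-Gaussian
`u`; `A2`–`A4` a second shared component for one treatment pair; `A5` no
`u`; `A6` no `s`; `A7` flat fixed-effect priors).

Because the motivating linked registry cohort is restricted, the package
ships a first-class **synthetic cohort generator** that reproduces the
study's structure: 478 areas (a trimmed rook-adjacency grid) of which ~61
receive no patients, 6,357 individuals, the published covariate category
frequencies and treatment-combination margins, and the published posterior
odds ratios as true effect sizes.

## Worked example

```python
from sharedcar import (grid_graph, default_schema, TruthConfig, generate_cohort,
                       ModelSpec, McmcSettings, run_mcmc, dic, ppc_coverage,
                       summarize_effects, relative_weights, shared_effect_summary)

graph = grid_graph(8, 8)                      # 64 areas, rook adjacency
schema = default_schema()
truth = TruthConfig.default(graph, schema, n_individuals=2000, seed=1)
cohort, latent = generate_cohort(truth, schema, graph)

spec = ModelSpec.from_variant("A0")
settings = McmcSettings(n_chains=2, n_iterations=1500, burn_in=750, thin=1, seed=1)
samples = run_mcmc(spec, cohort, graph, settings, schema=schema)

effects = summarize_effects(samples)
print(effects[effects.coefficient == "tract=4-<6h"].to_string(index=False))
```

```
coefficient    treatment  or_median  cri_low  cri_high  substantive
tract=4-<6h radiotherapy   0.609456 0.355482  1.066403        False
tract=4-<6h chemotherapy   0.568751 0.336683  0.996828         True
tract=4-<6h     hormonal   0.885901 0.611211  1.248274        False
```

The generator's true odds ratios for the 4–<6 h travel band are 0.41, 0.44
and 0.74; at n = 2,000 the posterior medians recover them to within
posterior uncertainty (the 95 % credible intervals cover the truth).
Continuing:

```python
print(relative_weights(samples).to_string(index=False))
d, dbar, pd_ = dic(samples, spec, cohort, graph, schema=schema)
print(f"DIC = {d:.1f}  (Dbar = {dbar:.1f}, pD = {pd_:.1f})")
print(f"PPC coverage = {ppc_coverage(samples, spec, cohort, graph, schema=schema):.4f}")
print(shared_effect_summary(samples).exceed_class.value_counts().to_dict())
```

```
                                ratio   median  cri_low  cri_high  substantive
delta_chemotherapy/delta_radiotherapy 0.929405 0.287034  2.348251        False
    delta_hormonal/delta_radiotherapy 1.253454 0.258836  4.587958        False
    delta_hormonal/delta_chemotherapy 1.383895 0.248479  3.886044        False

DIC = 6009.9  (Dbar = 5862.6, pD = 147.3)
PPC coverage = 0.9998
{'uncertain': 34, 'low': 17, 'high': 13}
```

The relative-weight table summarises how strongly each treatment loads on
the shared field (δ ratios with 95 % credible intervals); DIC = Dbar + pD is
the fit criterion (smaller is better); the PPC is the fraction of observed
outcomes inside the central 95 % of their posterior predictive replicates;
the last line counts areas by exceedance class — posterior probability that
the shared spatial odds ratio exceeds 1, classified low (< 0.2), high
(> 0.8) or uncertain.

A command-line interface wraps the same pipeline:

```
sharedcar simulate --out data --seed 1 --n-individuals 6357 --n-areas 478
sharedcar fit --cohort data/cohort.csv --adjacency data/adjacency.gal \
              --out run_a0 --variant A0 --seed 1
sharedcar diagnose run_a0
sharedcar compare run_a0 run_a5 ...
```

Inputs are plain text: cohort CSV, GAL-dialect adjacency files, JSON run
configurations.  Every run writes per-parameter sample CSVs, fit reports,
per-area summary tables and a checksummed manifest; a rerun with the same
configuration and seed is byte-identical.

## Layout

```
src/sharedcar/spatial_graph.py   adjacency, GAL I/O, intrinsic-CAR maths
src/sharedcar/synthetic.py       cohort generator, schema, combination tables
src/sharedcar/model.py           likelihood, priors, variants A0-A7, constraints
src/sharedcar/polyagamma.py      exact PG(1, z) sampler (Devroye)
src/sharedcar/inference.py       Pólya-Gamma Gibbs sampler, chain schedules
src/sharedcar/diagnostics.py     DIC, PPC, Gelman-Rubin, effect summaries
src/sharedcar/summaries.py       exceedance maps, bins, box-plot summaries
src/sharedcar/pipeline.py        run orchestration, manifests, DIC ranking
src/sharedcar/cli.py             command-line interface
docs/methods.md                  modelling and implementation notes
```
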