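# Methods notes

## Model

Three binary treatment-intention outcomes per individual are modelled
jointly with a logistic shared spatial-component model:

    Y_ijk ~ Bernoulli(p_ijk),    k = 1 (radiotherapy), 2 (chemotherapy), 3 (hormonal)
    logit(p_ijk) = alpha_k + beta_k' X_ij + u_ik + delta_k * phi_i + s_ik

over areal units i connected by shared boundaries (rook adjacency on the
synthetic grid maps).  The shared field `phi` and the per-treatment fields
`s_k` carry intrinsic CAR priors

    log p(x | tau) = (rank/2) log tau - (tau/2) * sum_{i~j} (x_i - x_j)^2,

with each unordered adjacent pair contributing once and
`rank = n_areas - n_components`.  Using the rank rather than `n_areas` in
the normalising term keeps the conjugate precision updates correct on
disconnected maps (islands); the constraint space of the improper prior is
exactly the per-component constant directions, so sum-to-zero is imposed
**per connected component** — a single global constraint would leave
component-wise levels unidentified.

Priors (shape/rate Gamma convention throughout):

| block                        | prior                                            |
|------------------------------|--------------------------------------------------|
| alpha_k, beta_k              | Gaussian(0, 1/tau); tau ~ Gamma(0.005, 0.5)      |
| alpha_k, beta_k (variant A7) | Gaussian(0, 1/0.0001), fixed                     |
| u_i (rows)                   | MVN(0, P^-1); P ~ Wishart(I3, 5)                 |
| u_ik (variant A1)            | Gaussian(0, 1/tau_k); tau_k ~ Gamma(0.5, 0.005)  |
| phi, s_k (CAR precisions)    | Gamma(0.5, 0.005)                                |
| free log-weights             | Gaussian(0, precision 5.9)                       |

The asymmetry between the fixed-effect Gamma(0.005, 0.5) and the CAR
Gamma(0.5, 0.005) hyperpriors is deliberate here: it is carried exactly as
stated in the model definition, and the built-in sensitivity presets
(Gamma(0.5, 0.5), Gamma(0.5, 0.05), log-weight precision 2.9) let a user
verify that posterior summaries are insensitive to this choice.

The hierarchical fixed-effect precision is blocked as one `tau_alpha` for
the three intercepts and one `tau_beta_k` per treatment's coefficient
vector — the minimal reading of "a Gamma hyperprior for the precision" that
still adapts to the very different coefficient scales of the three
outcomes.  A1's independent-Gaussian prior on `u` does not come with a
stated hyperprior; we use Gamma(0.5, 0.005), matching the other
random-effect precisions.

Identifiability of the weights: the product constraint
`delta_1 delta_2 delta_3 = 1` is mechanised as a hard parameterisation —
two free log-weights carry the Gaussian prior and the third is their
negative sum (one free log-weight with its negation for a second shared
component between a pair).  Projection is idempotent and every retained
draw satisfies `|sum log delta| < 1e-12`.

## Inference

Posterior sampling uses Pólya–Gamma data augmentation: conditional on
per-cell PG(1, psi) variables, the Bernoulli likelihood is Gaussian in every
location block, giving closed-form Gibbs updates for (alpha_k, beta_k), the
`u` rows (batched 3×3 solves), and the CAR fields, plus conjugate
Gamma/Wishart updates for all precisions.  The two free log-weights (and the
second component's one) are updated by an adaptive random-walk Metropolis
step against their PG-conditional target; the step size is tuned toward a
0.4 acceptance rate during burn-in only, so the retained chain is a fixed
Markov kernel.

PG(1, z) draws use Devroye's exact alternating-series rejection sampler for
the tilted Jacobi distribution (implemented vectorised over the full
individual-by-treatment array; `polyagamma.py`).  No approximate truncation
is involved; the sampler is validated against the closed-form moments
`E = tanh(z/2)/(2z)`, `Var(z=0) = 1/24`, and the whole chain against a dense
numerical-integration oracle in the no-spatial-terms limit.

CAR fields are sampled **exactly under the hard constraints** by
conditioning-by-kriging: the full conditional has canonical precision
`tau*L + diag(w)` (positive definite on the constraint space); a small
rank-correction along the per-component constant directions makes the
Cholesky factorisation well posed without changing the constrained law, and
the draw is then conditioned on `Cx = 0` exactly.  Constraint residuals of
retained draws are at machine precision (asserted < 1e-9 in tests).

Chains are initialised from inflated Gaussians with a chain-specific spread
factor (over-dispersed starts); all randomness descends from one master
seed through `numpy.random.SeedSequence.spawn`, one generator per chain, so
a rerun with the same seed is byte-identical.

Default schedules: full-cohort runs use 2 chains × 17,500 iterations with
10,000 burn-in and thinning 3 (2,500 retained per chain, 5,000 pooled —
both counts are logged and recorded in run manifests); sub-cohort runs use
2 × 37,500 with 30,000 burn-in.  Because the PG Gibbs sampler mixes nearly
iid on these models (effective sample sizes close to the draw count), the
test suite and the acceptance script use much shorter schedules
(1,000–4,000 iterations) — chosen as adequate for the Monte Carlo error
they need, with convergence checked by the Gelman–Rubin statistic.

## Synthetic data

The generator emulates the motivating cohort's structure:

* **Map**: a rook-adjacency grid trimmed to the requested area count
  (default 22 × 22 trimmed to 478); the real adjacency is not distributable.
* **Allocation**: areas receive patients with Dirichlet(0.8)-perturbed
  uniform shares; at the default size (6,357 individuals, 478 areas) this
  leaves roughly 60 areas empty, matching the study's 61 patient-free
  units.  Empty areas stay in the graph and receive smoothed effects.
* **Covariates**: ten categorical covariates sampled independently with the
  published category frequencies; reference levels as published.  An
  optional `tract_spatial_tilt` links the travel-time band to the realised
  spatial surface (phi plus the mean of the s fields), injecting the
  geography–covariate confounding needed to reproduce the qualitative
  behaviour of the no-structured-effects variant; it is off by default.
* **Truth**: default effect sizes are the published posterior odds ratios;
  intercepts are calibrated by Monte Carlo root-finding so the cohort-wide
  intention frequencies match the published treatment margins
  (61.5 % / 24.6 % / 58.8 %); the default weights are the published relative
  weights (1 : 0.57 : 0.90) renormalised to product 1.
* **Fields**: CAR precisions are set from target marginal SDs via
  `tau = mean(diag(pinv(L)))/sd^2` (defaults: SD 0.3 shared, 0.2 specific,
  0.1 unstructured).

What the generator does **not** emulate: the real joint covariate
distribution (covariates are independent), screening dynamics, survival
follow-up, or the true study-region adjacency.  Passing recovery tests
therefore demonstrate correctness of the inferential machinery under the
model's own assumptions, not robustness to real-data misspecification.

## Diagnostics and summaries

* **DIC**: `Dbar + pD` with `pD = Dbar - D(plug-in)`; the plug-in deviance
  is evaluated at the posterior mean of the linear predictor, the natural
  focus level since the likelihood depends on the parameters only through
  it.  The decomposition identity is exact by construction and asserted.
* **PPC**: for every individual × treatment cell, outcomes are simulated
  under a random subsample of posterior draws; the observation counts as
  covered when it lies within the 2.5th–97.5th percentile range of its
  replicate set.  For binary replicates this is a coarse statistic — most
  reasonable constructions give values near 1 for an adequate model — so
  only order-of-magnitude comparisons are meaningful.
* **Gelman–Rubin**: the classic between/within construction on whole
  chains, floored at 1.0 (values below 1 are estimation noise; the floor
  makes duplicated chains return exactly 1.0).
* **Effect summaries**: odds ratios are exp(draw) summarised by median and
  central 95 % credible interval; an effect is "substantive" when the
  interval excludes unity, with the conservative convention that an
  interval touching 1 exactly includes it.  No multiplicity correction is
  applied, matching the per-coefficient reporting convention of the field.
* **Maps**: shared-effect odds ratios `exp(phi_i)` and treatment-specific
  surfaces `exp(u_ik + s_ik)` (only the sum of the two residual fields is
  identified) are binned at the fixed cutpoints 0.77 / 0.91 / 1.10 / 1.30
  with `[low, high)` edges — the published legend prints cutpoints without
  an edge rule, so the half-open convention is a package choice.
  Exceedance probabilities P(OR > 1) are computed on the log scale
  (`phi > 0`) and classified with the 0.2/0.8 threshold rule.  Output is
  geography-free (per-area tables keyed by area id); no choropleth
  rendering is included.

## Numerical and degenerate-input choices

* Categories absent from a (sub-)cohort are dropped from the design with a
  logged warning; the generator keeps the full schema coding since its
  coefficient matrix is fixed a priori.
* Sub-cohort analyses filter rows and drop the filter covariate from the
  design, mirroring the unadjusted-for-the-stratifier convention.
* An empty cohort is valid input to the sampler, which then returns prior
  draws (used to verify the log-weight prior variance 1/5.9).
* Ranked area summaries sort stably by median OR with ties broken by area
  order; area ordering everywhere follows the adjacency-file order.

## Known limitations

* The sampler's per-iteration cost is dominated by the dense Cholesky
  factorisations of the CAR full conditionals (O(n_areas^3)); fine to a few
  hundred areas, not intended for thousands.
* Only intrinsic (not proper) CAR structures, at most two shared
  components, and binary outcomes are supported.
* DIC is reported because it is the comparison criterion of this model
  family's literature; WAIC/LOO are deliberately out of scope.
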