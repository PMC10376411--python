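# Methods

## Generating model

The synthetic panel generator draws latent wave-1 symptom vectors
x⁽¹⁾ ~ N(0, Σ) with Σ exchangeable (unit diagonal, constant off-diagonal
ρ, default 0.3) and forms wave-2 latents by a one-step VAR:

  x⁽²⁾ = x⁽¹⁾ (B + diag(a)) + g_age·age_z + g_gender·gender + ε,

with ε ~ N(0, σ²I). B is the sparse cross-lagged matrix (zero diagonal)
built by `make_true_clpn`; a holds autoregressive coefficients drawn
uniformly from `autoregressive_range`. Generation refuses any combined
lag matrix with spectral radius ≥ 1 (the implied process would be
non-stationary, and regression recovery would be ill-posed).

Both waves are discretized to 1..L Likert categories by fixed per-item
thresholds placed at equal-probability quantiles of each item's
theoretical marginal (wave-2 variances are computed exactly from
Σ, B, a, the covariate effects and σ, so thresholds do not depend on the
realized sample). The exchangeable Σ was chosen over an arbitrary
Gaussian graphical model because it makes the ground truth interpretable
with a single parameter; the cost is that wave-1 *partial* correlations
are uniformly ρ/(1+(p−2)ρ) ≈ 0.05 at defaults — see "Cross-sectional
networks" below for two consequences.

### Planted hubs

`make_true_clpn(p, n_hub_out, n_hub_in, density, hub_scale, seed)` gives
every row `round(density·(p−1))` nonzero positive entries with
magnitudes U(0.05, 0.15). The first `n_hub_out` rows are out-influence
hubs and the last `n_hub_in` columns in-influence hubs: hub entries are
pinned at `hub_scale × 0.15` and hub-in columns are filled to twice the
per-row count, so hub rows dominate every other row's absolute sum by
construction. Positive weights reflect the empirically predominant sign
of symptom-network edges.

### Screener

A PHQ-9-like screener (9 ordinal items, scores 0–3) loads on the mean
symptom latent through a single factor. Because discretizing both sides
attenuates correlations, the latent loading is inflated by a closed-form
attenuation factor (sums of normal survival functions for the
total-vs-factor side; Stein-lemma linearization for the
mean-score-vs-mean-latent side), so that the *observed* correlation
between screener total and mean symptom score lands on
`screener_loading` (default 0.6, within ±0.03 in practice). Screener
item thresholds are staggered over ±0.6 SD in severity and calibrated so
that roughly 14% of participants exceed the conventional cutoff of 8 at
baseline — the subgroup prevalence the generator is meant to emulate.

### What the generator does not emulate

Real Likert data show item-specific skew, floor effects, measurement
non-invariance across waves, attrition correlated with severity, and
far stronger cross-sectional dependence than the exchangeable latent
model provides (the generator's Cronbach's alpha is ≈ 0.75–0.88 versus
≈ 0.94 typical of a 20-item addiction scale). Passing tests therefore
demonstrate that the estimators recover the structures this model
plants at these sample sizes — not that any empirical network is
correct.

## CLPN estimation

Each wave-2 item is regressed on all p wave-1 items plus covariates.
Choices that the literature leaves open, fixed here:

- **Standardization.** Predictors *and* outcome are z-scored on the
  analysis sample, so edges are standardized coefficients; centrality
  sums are then comparable across nodes. Constant columns are zeroed
  with a warning rather than failing the whole fit.
- **Penalty selection.** Per node, 100 log-spaced λ values from λ_max
  (= max_j |x_jᵀy|/n, the smallest penalty that empties the model) down
  to 10⁻⁴λ_max; 10-fold CV with seeded fold assignment; λ at minimum
  mean held-out MSE (λ_min, the most common CLPN practice). A
  `fixed_lambda` escape hatch skips CV — used by resampling loops and
  the demo config, where thousands of re-fits are needed; 0 gives
  node-wise OLS.
- **Solver.** Cyclic coordinate descent with warm starts along the
  decreasing grid (scikit-learn's path solver), duality-gap tolerance
  10⁻⁹. Within CV folds, predictors and outcome are re-centered on the
  training fold before the path solve.
- **Seeding.** `estimate_clpn` spawns one child seed per node, so any
  single node's fit can be reproduced in isolation and results do not
  depend on fit order.
- Ordinal scores are treated as continuous (no polychoric step),
  matching the regression-on-raw-scores convention of the analysis this
  pipeline automates.

Covariate coefficients (age z-scored, gender 0/1) are estimated per node
but held outside the weight matrix; no centrality or comparison ever
sees them.

## Centralities

OEI_i = Σ_{j≠i} w_ij, IEI_j = Σ_{i≠j} w_ij — signed sums, autoregressive
diagonal excluded (it is reported as its own vector, following the
convention of plotting self-loops separately). ΣOEI = ΣIEI holds exactly
since both sum the same off-diagonal entries. Rankings break ties by
item order (stable sort) so reports are deterministic.

## Cross-sectional networks

Per-wave undirected networks are regularized partial correlations:
graphical lasso over 100 log-spaced penalties (from the largest absolute
marginal correlation down to 1% of it), selected by EBIC with γ = 0.5,
E = nonzero upper-triangle edges; precision Θ is converted via
ρ_ij = −Θ_ij/√(Θ_ii Θ_jj). Non-PSD inputs are rejected with a pointer to
nearest-PSD repair; penalties where the solver fails are skipped.

Two consequences of the exchangeable synthetic ground truth:

1. At n ≈ 300 the uniform ≈0.05 true partial correlations sit below
   EBIC's detection threshold, so the selected network is legitimately
   *empty*. The pipeline therefore exposes an unregularized
   partial-correlation estimator (`pcor`, straight precision inversion)
   as the NCT/sensitivity alternative, and the sensitivity stage falls
   back to it deterministically when a regularized network comes back
   empty.
2. The wave-1 *sensitivity* correlation (edge vector of the matched
   panel's network vs the unmatched rows' network) is structurally ≈ 0:
   with all true edges equal there is no heterogeneity to correlate,
   only estimation noise. Wave 2, whose covariance inherits the
   cross-lagged heterogeneity, yields r ≈ 0.76 at the default sizes.

## Network comparison test

The two waves come from the same participants, so the null is built by
a *paired* scheme: independently per participant, swap the wave-1 and
wave-2 item vectors with probability ½ and re-estimate both networks
(an unpaired group-relabeling variant exists for independent samples).
Statistics: S = |Δ global strength| (global strength = sum of absolute
upper-triangle weights), M = max absolute edge difference, and per-edge
absolute differences. P-values use the add-one estimator
(1+#{null ≥ observed})/(1+B), hence never exactly zero; B defaults to
1000 and fewer than 20 is refused. An estimator failure inside a
permutation is retried with a fresh swap pattern and counted; per-edge
p-values are unadjusted unless the Holm flag is set.

## Resampling

- Case-dropping grid: 0.05–0.75 in steps of 0.05 (the conventional
  maximum of 75% removal); 1000 replicates per proportion by default.
  The CS coefficient is the largest grid proportion whose empirical 5th
  percentile of correlations is ≥ 0.7 (plug-in quantile, no smoothing).
- Edge CIs: percentile method, 2.5th/97.5th of 1000 row-resamples (no
  BCa). Difference tests flag a pair when the percentile CI of the
  difference excludes zero; the significance matrix is symmetric with
  an all-false diagonal.
- Replicate b at grid point q uses child stream [seed, q-index, b], so
  results are reproducible from one master seed and enlarging `n_boot`
  leaves earlier replicates unchanged.
- Coverage checks target the estimator's own large-sample value (its
  estimate on a 10⁵-row panel) rather than the latent-scale planted
  coefficient: discretization attenuates coefficients, and percentile
  bootstrap coverage is a statement about the estimator's sampling
  distribution, not about the latent truth.

## Problem sizes used by the test suite

Recovery runs use the default conditions (n = 2000, p = 20, 20 seeds);
NCT calibration uses 100 replicates of n = 300, p = 8 with 200
permutations and the `pcor` estimator; stability and coverage
simulations use p = 4–6 panels with a fixed small penalty or OLS so that
thousands of re-estimations stay cheap. The demo pipeline config runs a
600-person panel with 200 permutations and 200 bootstrap replicates.

## Known limitations

- λ selection by minimum-MSE CV overselects on pure noise (median
  support is empty, but ~20% of seeds keep a few tiny coefficients);
  the 1-SE rule would be sparser but is not the common CLPN default.
- The paired NCT assumes exchangeability of waves under the null;
  marginal mean shifts between waves (present in real data) violate it,
  which is one reason the per-wave networks are compared on
  correlation-based weights rather than raw scores.
- CS coefficients are reported on the discrete drop grid; no
  interpolation between grid points is attempted.
- The generator models matched completers only: no missingness or
  attrition mechanisms.
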