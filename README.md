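# clpnet

Cross-lagged panel network (CLPN) analysis of two-wave symptom
questionnaire data, built for studies that screen a cohort with a
depression questionnaire and ask how Internet-addiction-type symptoms
predict each other over time.

## The problem and the model

Symptom-network psychometrics treats a disorder as a system of
interacting symptoms rather than a latent disease entity. With two
assessment waves of the same participants, the natural directed model is
the **cross-lagged panel network**: for each symptom *j*, regress its
wave-2 score on *all* wave-1 symptom scores (plus covariates),

  x_j^(2) = β_0j + Σ_i β_ij · x_i^(1) + γ_j' c + ε_j,

with an L1 (LASSO) penalty on the β's so small coefficients shrink
exactly to zero. The edge i→j of the network is β_ij, estimated from
z-scored predictors and outcome; the diagonal β_jj is the
*autoregressive* effect (a symptom predicting itself), and off-diagonal
entries are *cross-lagged* effects. Per-node penalties are selected by
seeded 10-fold cross-validation (minimum held-out MSE). Age and gender
enter each regression as covariates but never appear in the network.

On top of the network the package computes:

- **out / in expected influence** (OEI/IEI): the signed sum of a node's
  outgoing / incoming cross-lagged edges — how strongly a symptom
  predicts the rest of the system, and how strongly it is predicted;
- **permutation network-comparison test** (NCT) between the per-wave
  regularized partial-correlation networks: global strength invariance
  (S = |Δ Σ|edge||), structure invariance (M = max |edge difference|),
  and per-edge tests, with paired within-person wave swapping;
- **case-dropping bootstrap stability** (CS coefficient: the largest
  share of the sample that can be dropped while re-estimated
  centralities stay correlated ≥ 0.7 with the full-sample ones with
  95% probability) and percentile bootstrap CIs for every edge, with
  CI-exclusion difference tests;
- **sensitivity correlations** between the edge vectors of networks
  built from the analysis sample and from the rows lost in matching.

A bundled synthetic-data generator produces matched two-wave Likert
panels from a latent vector-autoregression with a *known* sparse
cross-lagged matrix, planted high-OEI / high-IEI hub symptoms, covariate
effects, and a correlated PHQ-9-style screener with a cutoff subgroup —
so every stage of the pipeline is testable end to end without any data
download.

## Worked example

```python
import numpy as np
from clpnet import (GeneratorConfig, generate_panel, screen, estimate_clpn,
                    centrality_table, rank_report)

panel, truth = generate_panel(GeneratorConfig(n_participants=2415, seed=11))
depressed, prev1, prev2 = screen(panel, cutoff=8)
print(f"screened subgroup: n={depressed.n} "
      f"(prevalence {prev1}% at wave 1, {prev2}% at wave 2)")

net = estimate_clpn(depressed, seed=11)
print(f"nonzero edges: {np.count_nonzero(net.weights)}/400 "
      f"({100 * net.density():.0f}% density)")

top = rank_report(centrality_table(net), k=3)
print("top OEI:", [(i, round(v, 2)) for i, v in top["oei"]])
print("top IEI:", [(i, round(v, 2)) for i, v in top["iei"]])
```

prints

```
screened subgroup: n=357 (prevalence 14.78% at wave 1, 15.28% at wave 2)
nonzero edges: 184/400 (46% density)
top OEI: [('item1', 0.76), ('item19', 0.57), ('item2', 0.46)]
top IEI: [('item20', 1.24), ('item17', 0.7), ('item6', 0.61)]
```

About 15% of the simulated cohort crosses the screener cutoff of 8 at
baseline; the CLPN on that subgroup keeps 184 of the 400 possible
directed edges; and the planted hub symptoms — item 1 (the
out-influence hub) and item 20 (the in-influence hub) — are correctly
ranked first on OEI and IEI.

The same analysis runs from the shell:

```bash
clpn run-all --config examples/demo.yaml --out demo_out
```

writing the descriptives table, screening summary, network matrix and
edge list, centrality table, NCT results, stability/accuracy outputs,
sensitivity correlations, and a summary JSON that reproduces the run.

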