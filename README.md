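# ggmclust

Model-based clustering of symptom-score data with **Gaussian graphical
mixture models** (GGMM), plus the downstream network workflow used in
transdiagnostic psychopathology research: a regularized
partial-correlation network and node/bridge centrality tables for every
cluster.

## The problem and the model

Patients with depressive and anxiety disorders are heavily comorbid, and
clusters found by conventional latent-profile methods say little about
which symptoms interact *within* each cluster. A GGMM addresses both at
once. It models subjects-by-variables data x ∈ ℝᵖ as a finite mixture

> f(x | Θ, 𝒢) = Σₖ τₖ Φ(x | μₖ, Σₖ),  Σₖ ∈ C⁺(Gₖ),

where Φ is the multivariate Gaussian density, τₖ the mixing proportions,
and each component covariance Σₖ is constrained to an undirected graph
Gₖ: the precision matrix Σₖ⁻¹ must be zero wherever Gₖ has no edge. The
graphs are learned during fitting by **structural EM** — the usual E/M
steps interleaved with a per-component graph search under a penalized
likelihood (per-edge cost (1+β)·log(n_eff)/2, β = 0 by default). The
number of clusters is chosen by BIC (minimized); component counts whose
covariances degenerate are reported as typed failures and excluded from
the comparison. Each cluster's symptom interplay is then re-estimated as
a partial-correlation network via the graphical lasso with EBIC tuning
(−ω̂ᵢⱼ/√(ω̂ᵢᵢω̂ⱼⱼ) from the penalized precision ω̂), and summarized by
strength, closeness, betweenness, expected influence, and bridge
centrality (cross-disorder edges only), raw and z-standardized.

The package is organised as scikit-learn-style estimators —
`GraphicalGaussianMixture` (fit/predict, `labels_`, `bic_`, `graphs_`)
and `EBICGraphicalLasso` (fit, `precision_`, `network_`) — with
module-level functions (`fit_ggmm`, `select_model`, `select_network`,
`centrality_table`, …) as thin wrappers, and a CLI
(`ggmclust simulate | fit | networks | centrality`) over text artifacts
(CSV/TSV/JSON).

## Worked example

The synthetic-data module ships a 12-variable, 4-cluster fixture that
emulates a comorbid depression/anxiety sample (variables MDD1–2, PD1–3,
SAD, OCD1–6; cluster shares 15.5 / 23.5 / 9.1 / 52.0 %):

```python
import numpy as np
import ggmclust as g

data, labels, truth, communities = g.psychopathology_fixture(n=1500, seed=1)
best, failures = g.select_model(data, [1, 2, 3, 4, 5],
                                g.FitConfig(n_restarts=4, seed=1))
print(best.n_components, round(best.bic_, 1), np.round(best.weights_, 3))
```

prints

```
4 44196.9 [0.09  0.518 0.245 0.147]
```

— BIC selects the true four components, and the mixing proportions
recover the generating shares (order is arbitrary; the adjusted Rand
index of the MAP labels against the truth is 0.985). Each fitted
component carries its learned graph (`best.graphs_`, here 13–22 edges)
and graph-constrained covariance. The per-cluster network stage:

```python
k = int(np.argmax(best.weights_))               # largest cluster, n = 777
rows = data.values[best.labels_ == k]
est = g.EBICGraphicalLasso(gamma=0.5).fit(
    g.DataMatrix(rows, data.variable_names))
table = g.centrality_table(est.network_, communities)
print(table[["community", "strength", "strength_z", "bridge_strength"]].round(3).head(6))
```

```
     community  strength  strength_z  bridge_strength
node
MDD1       MDD     0.182      -1.127            0.000
MDD2       MDD     0.314      -0.544            0.133
PD1         PD     0.264      -0.763            0.133
PD2         PD     0.275      -0.717            0.000
PD3         PD     0.204      -1.026            0.061
SAD        SAD     0.070      -1.614            0.070
```

The EBIC selected λ = 0.424 for this cluster; `strength` is the sum of
absolute partial correlations at each node, `strength_z` its z-score
across the network's nodes, and `bridge_strength` the part of that sum
crossing disorder boundaries. The same pipeline runs from the shell:

```sh
ggmclust simulate --n 1500 --seed 1 --out sim/
ggmclust fit --input sim/data.csv --k-min 1 --k-max 5 --seed 1 --out run/
ggmclust networks --input sim/data.csv --community-map sim/communities.tsv --out run/
```

See `docs/methods.md` for the estimation details (structural EM,
iterative proportional scaling, the refit-EBIC selection rule) and the
design choices behind them.

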