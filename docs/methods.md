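# Methods

## The model

`ggmclust` clusters continuous multivariate scores (in the motivating
application, symptom factor scores of psychiatric patients) with a finite
mixture of multivariate Gaussians whose component covariances are
graph-constrained:

    f(x | Θ, G) = Σ_k τ_k Φ(x | μ_k, Σ_k),    Σ_k ∈ C⁺(G_k),

where G_k is an undirected graph on the variables and C⁺(G_k) is the cone
of positive-definite matrices whose inverse vanishes off the edges of
G_k. Each cluster therefore carries its own conditional-independence
network: an absent edge (i, j) in G_k means variables i and j are
conditionally independent given the rest, within that cluster. Clustering
and per-cluster network estimation are a single estimation problem, not
two stages.

## Structural EM

`GraphicalGaussianMixture.fit` alternates:

1. **E step** — responsibilities r_ik ∝ τ_k Φ(x_i | μ_k, Σ_k), in log
   space.
2. **M step** — weighted proportions, means and per-component weighted
   sample covariances S_k (denominator Σ_i r_ik).
3. **Structure step** — per component, a greedy stepwise search over
   graphs maximizing the penalized profile likelihood
   ℓ(S_k, G) − (1 + β)·(log n_k)/2·|E(G)|, where ℓ is the Gaussian
   log-likelihood at the graph-constrained MLE and n_k = Σ_i r_ik is the
   component's effective sample size. With the default β = 0 this is a
   BIC-type per-edge penalty at the component's own weight of data.
4. **Covariance step** — the graph-constrained MLE Σ̂_k ∈ C⁺(G_k) of S_k.

The first structure search of a fit starts from the empty graph; later
iterations restart the greedy search from the component's current graph.
Once no component's graph changes between iterations, the fit switches to
cheap parametric EM at fixed graphs; when the penalized log-likelihood has
converged (relative change < 1e−6, up to 500 iterations) the structure is
re-confirmed by one more search pass before the fit is accepted.
Initialization is a seeded k-means hard partition converted to one-hot
responsibilities; `n_init` independent starts (default 10) are run and
the best penalized fit kept. All randomness flows from a single integer
seed recorded on the fitted model.

At fixed graphs each EM iteration cannot decrease the observed-data
log-likelihood; the per-iteration trace is kept in `history_` so tests
assert this directly. The penalty term uses the evolving n_k, so the
*penalized* objective is monotone up to O(Δlog n_k) wiggle near
convergence; the suite allows 1e−6 relative slack for this.

### Failure semantics

A component covariance whose smallest eigenvalue falls to 1e−8, or (for
K ≥ 2) a component whose responsibility mass drops below p + 1
observations, aborts the fit for that K with a typed `FailureRecord`
(`not_positive_definite` / `empty_component`) instead of silently
regularizing. `select_model` fits an ascending K range, skips failed K,
and returns the minimum-BIC fit (BIC = −2·logL + ν·log n with
ν = (K−1) + K·p + Σ_k (p + |E_k|)) together with the failure records.
This is deliberate: with too many components a weighted sample covariance
can genuinely degenerate, and model selection must see that as evidence
against that K, not have it papered over. The starvation guard is not
applied at K = 1 because a lone component always holds the full sample;
it can still fail through the MLE itself.

## Graph-constrained covariance MLE

For a sample covariance S and graph G the constrained MLE matches S on
the diagonal and on every edge of G while its inverse is exactly zero off
G. It is computed by iterative proportional scaling: sweeping the edges,
each update matches one 2×2 marginal by a rank-2 precision update, with
the covariance iterate maintained through a Woodbury identity (compiled
with numba; a sweep costs O(|E|·p²)). Convergence is declared when every
constrained entry agrees with S within 1e−8 (up to 10 000 sweeps). When a
clique marginal of S is near-singular the pairwise sweeps converge slowly;
the solver then falls back to IPS over maximal cliques, which matches
whole clique blocks at once and is immune to that slowdown. On
decomposable graphs the result coincides with the clique-marginal closed
form (the 3-variable chain example Σ̂₁₃ = S₁₂S₂₃/S₂₂ is a frozen test).

## Structure search

`greedy_stepwise` starts from the empty graph (or a warm start inside
EM) and repeatedly applies the single edge addition or removal that most
improves the penalized profile likelihood, warm-starting each candidate
MLE from the current precision, until no toggle improves the score.
`exhaustive` (p ≤ 5) enumerates all 2^(p(p−1)/2) graphs. Ties resolve
toward fewer edges, then the lexicographically smallest edge set; a
relative tolerance of 1e−7 separates genuine improvements from numerical
noise. Greedy is a local search: on heavily collinear inputs it can stop
in a local optimum, which is why the oracle-equivalence test draws its
instances from graph-structured Gaussians — the model class the search is
built for — where it attains the exhaustive optimum on ~99 of 100
seed-fixed instances.

## Per-cluster partial-correlation networks

`EBICGraphicalLasso` estimates, for the rows of one (hard, MAP-assigned)
cluster, the L1-penalized precision

    Ω̂(λ) = argmax log det Ω − tr(SΩ) − λ Σ_{i≠j} |Ω_ij|,

along a descending grid of 100 log-spaced λ from λ_max = max|S_off| down
to 0.01·λ_max, and tunes λ by the extended BIC
EBIC = −2·logL + |E|·log n + 4γ|E|·log p with γ = 0.5 by default. The
log-likelihood entering the EBIC is **unpenalized**: the graph-constrained
MLE refit of each candidate's support. Scoring the shrunk estimate's own
likelihood systematically favors denser supports (the shrinkage deficit of
the true edges is repaid by lowering λ, dragging spurious edges along);
with refit scoring the selection recovers a true chain support in 10/10
simulation seeds where shrunk-likelihood scoring recovered it in 0/10.
Ties keep the larger (sparser) λ. The reported network is the regularized
partial-correlation matrix −ω̂_ij/√(ω̂_ii ω̂_jj) at the selected λ.

The inner solve uses scikit-learn's graphical lasso only to propose an
active set, then polishes it: on its support, the solution is exactly the
graph-constrained MLE of the sign-shifted target S + λ·sign(Ω), which the
IPS kernel solves to 1e−8; the active set is refreshed from the KKT
conditions until stable. This yields exact zeros and KKT residuals at the
1e−8 level, where the off-the-shelf solver alone plateaus around 1e−2 on
ill-conditioned cluster covariances. Sample covariances use denominator n
(the MLE), consistent with the likelihood in the EBIC.

## Centrality

On a weighted signed network: strength = Σ_j |w_ij|, expected influence
= Σ_j w_ij; geodesic indexes use edge lengths 1/|w_ij| (strong
associations are short), with closeness = 1/Σ_j d(i, j) set to 0 when any
node is unreachable, and betweenness by Brandes' algorithm with tied
geodesics counted fractionally and endpoints excluded. Bridge strength
and bridge expected influence are the same one-step sums restricted to
edges whose endpoints lie in different communities (disorders). All
indexes are reported raw and z-standardized (population SD) across the
nodes of that network; a constant index has no z-score and the column is
omitted rather than fabricated.

## Synthetic data

The generator produces Erdős–Rényi graphs, precisions exactly supported
on them (edge magnitudes uniform in a given range with random signs,
diagonal set to the row's absolute sum + 0.1, hence strictly diagonally
dominant and positive definite), and mixture samples with ground-truth
labels, all bit-reproducible per seed.

`psychopathology_fixture` emulates a 12-variable, 4-cluster comorbid
depression/anxiety dataset: variables MDD1–2, PD1–3, SAD, OCD1–6 with
communities {MDD, PD, SAD, OCD}; cluster profiles *strong everything*,
*weak everything*, *strong OCD+PD / moderate MDD+SAD*, and *moderate
MDD+PD+SAD / weak OCD*; mixing proportions (235, 357, 138, 791)/1521,
the published cluster shares. Severity levels are 0 / 3 / 6 in
within-cluster SD units (within-cluster variances are rescaled to exactly
1), so every pair of cluster means is at least 3 SD apart — the
separation regime in which near-perfect label recovery is the correct
expectation; at gap 2 even the Bayes-optimal classifier's ARI is ≈ 0.93.
The OCD variables form a clique in every cluster's graph; a handful of
additional edges give each cluster a distinct topology. All numeric
profiles are invented package constants chosen for recoverability; the
fixture does not attempt to match any real dataset's moments, and passing
recovery tests says nothing about ordinal items, missing data, or
weakly-separated real-world clusters.

## Problem sizes

The test suite and `scripts/acceptance.py` run the recovery study at
n = 1500, p = 12, K ∈ 1..5, 10 data seeds, 4 EM restarts per K (about
15–20 s per seed on one core). Four restarts is the package's choice for
this well-separated fixture — with 2 restarts roughly one seed in ten
lands in a local optimum at K = 4 and BIC then prefers K = 5; with 4 the
selection is stable. The oracle-equivalence study uses 100 instances at
p ≤ 4, where exhaustive enumeration (≤ 64 graphs) is exact.

## Known limitations

- Continuous inputs only; ordinal or discrete indicators are out of scope
  by design, and missing values are rejected, not imputed.
- Greedy structure search is a local method; its optimality guarantee is
  empirical and distribution-dependent.
- Networks are estimated on hard cluster subsets; responsibility-weighted
  variants are not implemented.
- No bootstrap stability analysis for edges or centrality.
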