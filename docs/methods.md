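# Methods

## Model and score

The data are a genes × samples matrix of log-scale expression values
D = {x¹, …, xᵐ}. The model is the triple (G, Θ, M): a directed graph G from
candidate regulators to target genes, conditional-distribution parameters Θ,
and a partition M of the genes into modules. The score is the posterior
of (G, Θ) up to a constant: data pseudo-likelihood times a structure prior,
with a uniform prior on M.

**Likelihood.** For each gene the joint Gaussian over (regulators, target)
is estimated by maximum likelihood (covariance divided by m) and converted
to its conditional form: coefficients a = Σ_RR⁻¹ Σ_RT, intercept
μ_T − aᵀμ_R, conditional variance Σ_TT − Σ_TR Σ_RR⁻¹ Σ_RT. Because every
gene is modelled given its own regulators and cycles are allowed, the
product of conditionals is a pseudo-likelihood (a dependency network), not a
joint density. Using the joint-Gaussian conversion rather than raw linear
regression matters only in how the covariance among regulators is handled;
on full-rank data the coefficients coincide with ordinary least squares, and
the test suite holds the implementation to that equivalence at 1e-8.

**Graph prior.** Each candidate edge (r → i) carries an independent logistic
prior P(present) = σ(sparsity + module_weight · f), where f is the fraction
of r's predicted targets (in the graph at the start of the current learning
iteration) that lie in gene i's module. The full prior is the product over
present-edge and absent-edge terms across the candidate universe
(regulators × genes, no self-loops), so adding one edge changes the log
prior by exactly the edge's log-odds. A regulator with no targets yet has
f = 0 (the 0/0 convention): it pays the bare sparsity penalty everywhere.

## Learning

Each iteration first revisits the modules (from the second iteration
onward), then re-selects regulators for every gene with the module features
frozen at the graph produced by the previous sweep:

1. **Module step.** Gene–gene distance = mean of the co-expression distance
   (1 − ρ)/2 and the regulatory distance 1 − s, where s is a sign- and
   magnitude-aware Jaccard similarity of the two genes' regression weight
   vectors: matching-sign shared weights contribute min(|wᵢ|, |wⱼ|), and the
   denominator is ‖wᵢ‖₁ + ‖wⱼ‖₁ minus that numerator. Two genes with no
   regulators at all get s = 0, not 1: an empty program carries no evidence
   of co-regulation. Modules come from average-linkage (UPGMA)
   agglomerative clustering that merges while the smallest inter-cluster
   distance is ≤ the threshold h, implemented with a lazy-deletion min-heap;
   ties break lexicographically on the clusters' smallest gene ids so the
   partition is deterministic.
2. **Regulator step.** Per gene, greedy forward selection from the empty
   set: each step adds the candidate with the largest gain in
   pseudo-likelihood plus prior log-odds, stopping when the best gain falls
   to the score tolerance or at the per-gene cap. The freshly grown program
   replaces the previous one only if it improves that gene's
   likelihood-plus-prior under the iteration's frozen features; this "accept
   only improving moves" rule, together with stopping the loop on any
   score-lowering iteration, keeps the recorded score trajectory
   non-decreasing even though the prior's features move between iterations.

Convergence: edges and modules unchanged, score gain below tolerance, or the
iteration cap. Everything is deterministic for a fixed input; the only
randomness in the package flows through explicit seeds (simulator, stability
subsets, restart perturbation).

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `sparsity` | −5 | log-odds offset of the edge prior; each edge must buy ≈5 nats of likelihood. More negative → sparser networks. |
| `module_weight` | 4 | slope on the module feature; 0 reduces the method to per-gene regression, values past ≈8 add little. |
| `cluster_threshold` | 0.6 | stop height of the module clustering in the [0, 1] distance; smaller → many small modules. |
| `score_tolerance` | 1e-4 · n_genes | minimum gain counted as progress, for both greedy steps and iterations. |
| `max_regulators_per_gene` | 10 | cap on program size; bounds runtime, the sparsity prior does most of the work. |
| `ridge` | 1e-6 | added to the regulator covariance diagonal before inversion; conditional variances are floored at 1e-8. |
| `max_iterations` | 30 | outer-loop cap; runs typically converge in 2–4 iterations. |

Defaults for sparsity, module weight and threshold sit in the middle of the
ranges that recover simulated structure well; all are exposed in the API,
the CLI and the YAML config echo.

## Simulator

The simulator emulates a genome-wide single-knockout steady-state design at
desk scale. Genes are partitioned uniformly at random into n/10 modules;
11% of genes are designated regulators, allocated to modules proportionally
(largest remainder, at least one each). Each target draws indegree
1 + Poisson(0.75) (mean 1.75, in the range of curated transcriptional
networks); each edge's source comes from the target's own module's
regulators with probability q and from another module otherwise, so q dials
the regulatory modularity of the truth. Signed strengths are uniform on
±[0.5, 1.5], and the weight matrix W is rescaled to spectral radius 0.8 so
the linear system x = b + Wx has a unique stable steady state; basal levels
b are standard normal. In the sample for gene g, that gene is clamped to −3
(strong depletion on log scale) and dropped from its own update; the others
solve the clamped linear system exactly, with N(0, noise_sd²) noise added to
b (default sd 0.1).

This linear-Gaussian steady state deliberately replaces nonlinear stochastic
kinetics: it is analytically checkable (the tests verify the noise-free
steady state against a dense solve at 1e-10) and preserves the
knockout-perturbation logic of the benchmark design. What it does **not**
emulate: saturating/nonlinear regulation, mRNA–protein dynamics, measurement
models of arrays or RNA-seq counts, and condition-dependent regulation.
Passing recovery tests on these data therefore shows the learner does what
it claims on its own model class, not that it resolves real expression
compendia at the same accuracy.

## Evaluation conventions

- Edge metrics restrict the universe to regulator and target nodes common to
  both networks, excluding self-pairs; fold enrichment is precision over
  background edge density on that universe.
- Precision–recall curves put tied confidences into one block (one PR point
  per distinct confidence) and integrate by trapezoid over recall; the AUPR
  confidences come from 100 random-subset stability runs (fraction 0.5),
  the confidence of an edge being the fraction of subsets whose network
  contains it.
- Hypergeometric tests are upper tails; multiple testing uses
  Benjamini–Hochberg, threshold 0.05 throughout. Regulator–target overlap
  uses the intersection of the two networks' node sets as background;
  regulator–module maps test only modules with ≥ 5 genes and correct across
  all regulator × module tests jointly.
- Regulatory modularity of a module is mean within-module minus mean
  between-module regulator-sharing similarity, with the Dice normalisation
  2c/(nᵢ + nⱼ) (0 when both genes are unregulated), hence bounded in
  [−1, 1]; singleton modules score 0.
- Silhouette uses (1 − ρ)/2 distance; constant genes get ρ = 0 against
  everything.

## Benchmark problem sizes

The shipped tests and the acceptance script run the 100-gene / 11-regulator
instance (one knockout sample per gene), three simulation seeds for recovery
checks, 100 stability subsets for AUPR, 200 permutations for the fold-
enrichment null and 50 repeats for the FDR-calibration null. These sizes
give stable estimates (Monte-Carlo error well inside the asserted margins)
while a full run of suite plus script stays in the minutes range on one
core.

## Known limitations

- Gaussian conditionals only; count models (negative binomial/Poisson),
  regression trees and temporal dynamics are out of scope.
- The greedy sweep is a local optimiser: regulator swaps that only pay off
  jointly are missed, and heavily correlated regulators within a module can
  substitute for one another (the stability confidences are the intended
  remedy).
- The module feature is frozen within an iteration, so very strong module
  weights can lag one iteration behind the current modules.
- With `module_weight` at 0 the module machinery still runs (modules are
  reported) but cannot influence the network — useful as a baseline, not as
  a clustering method in its own right.
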