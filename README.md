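# merlin — module-constrained gene regulatory network inference

Infers a directed regulatory network (transcription factors and signaling
proteins → target genes) from a genes × samples expression matrix, together
with a set of expression *modules* whose member genes are encouraged — but
not forced — to share regulators.

## The model

Each gene *i* gets a **regulatory program**: a conditional Gaussian

&nbsp;&nbsp;&nbsp;&nbsp;X<sub>i</sub> | X<sub>R<sub>i</sub></sub> ~ N(b<sub>i</sub> + **a**<sub>i</sub><sup>T</sup> X<sub>R<sub>i</sub></sub>, σ<sub>i</sub>²)

derived from the joint multivariate Gaussian of the gene and its regulators
R<sub>i</sub> (a = Σ<sub>RR</sub><sup>−1</sup>Σ<sub>RT</sub>). The product of
these per-gene conditionals scores a possibly cyclic graph G — a dependency
network with a pseudo-likelihood. The graph carries a logistic prior per
candidate edge (r → i):

&nbsp;&nbsp;&nbsp;&nbsp;P(edge present) = σ(β<sub>0</sub> + β<sub>1</sub> · f<sub>ri</sub>)

where f<sub>ri</sub> is the fraction of r's currently predicted targets that
lie in gene i's module. β<sub>0</sub> (`sparsity`, default −5) controls how
many edges enter the network; β<sub>1</sub> (`module_weight`, default 4)
controls how strongly modules attract a regulator's remaining edges. With
`module_weight = 0` the method reduces exactly to independent per-gene
greedy regression.

Learning alternates two steps until neither the edges nor the modules move:

1. **Regulator selection** — for every gene, grow the regulator set (the
   Markov blanket, restricted to a candidate-regulator list) greedily from
   empty, adding the regulator with the largest pseudo-likelihood gain plus
   edge-prior log-odds, with module features frozen at the iteration's
   starting graph.
2. **Module re-clustering** — threshold-stopped average-linkage clustering
   of a gene–gene distance mixing co-expression, (1 − ρ)/2, with a sign- and
   magnitude-aware Jaccard distance between the genes' inferred regression
   weight vectors.

A built-in simulator generates modular ground-truth networks and
steady-state single-knockout expression, so the full pipeline runs with no
external data; evaluation covers AUPR, fold enrichment of true edges,
per-regulator target overlap (hypergeometric + Benjamini-Hochberg),
regulator-module maps, regulatory modularity and silhouette diagnostics, and
gene-set (GMT) enrichment of modules.

## Worked example

```python
import merlin

# 100 genes, 11 regulators, one knockout sample per gene
truth, expr = merlin.simulate_dataset(n_genes=100, q=0.8, seed=1)

model = merlin.Merlin(expr, list(truth.regulators))   # defaults: -5 / 4 / 0.6
result = model.fit()
print(result.summary())
```

prints

```
Module-constrained regulatory network fit
==============================================
genes:                100
samples:              100
candidate regulators: 11
edges inferred:       182
modules:              21 (10 with >= 5 genes, coverage 0.71)
mean reg. modularity: 0.449
iterations:           3 (converged: True)
final score:          -1345.492
sparsity / module weight / threshold: -5 / 4 / 0.6
```

182 edges against 192 true edges; comparing them,

```python
from merlin import evaluation as ev
c = ev.edge_confusion(result.network, truth.network)
print(ev.edge_fscore(c), ev.fold_enrichment(c))
```

gives precision 0.79, recall 0.77 (F = 0.78) and a 4.5-fold enrichment of
true edges over the background edge density. The mean regulatory modularity
of 0.45 says genes inside a module share far more regulators with each other
than with outside genes.

The same pipeline is available from the shell:

```sh
merlin simulate --n-genes 100 --q 0.8 --seed 1 --out sim/
merlin learn --expr sim/expression.tsv --regulators sim/regulators.txt --out run/
merlin evaluate --inferred run/network.tsv --truth sim/truth_network.tsv \
    --modules run/modules.tsv --true-modules sim/truth_modules.tsv --out report.json
```

plus `stability` (edge confidences over random sample subsets), `consensus`
(support-filtered combination of runs), `enrich` (GMT gene-set enrichment of
modules) and `sweep` (hyperparameter grids with F-score and module
statistics).

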