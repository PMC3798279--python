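"""Model/results interface over the learner.

``Merlin`` holds the data and hyperparameters; ``fit()`` runs the iterative
algorithm and returns a ``MerlinResults`` carrying the network, the per-gene
conditional-Gaussian programs, the module assignment and the score
trajectory, with convenience methods for prediction, edge confidence
scoring, summaries and plotting.
"""

from __future__ import annotations

from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import core, learner
from .datatypes import (ExpressionMatrix, GeneRegulatoryProgram,
                        Hyperparameters, ModuleAssignment, RegulatoryNetwork,
                        RegulatorSet)
from .evaluation import module_stats, regulatory_modularity

__all__ = ["Merlin", "MerlinResults"]


class Merlin:
    """Module-constrained regulatory network model for one expression matrix.

    Parameters
    ----------
    expr
        Preprocessed genes x samples expression (no missing values).
    regulators
        Candidate regulator ids (must be rows of ``expr``).
    init_modules
        Optional starting partition; by default genes are clustered on
        expression distance alone at the clustering threshold.
    hyper
        ``Hyperparameters``; keyword overrides may be passed instead.
    """

    def __init__(self, expr: ExpressionMatrix,
                 regulators: Sequence[str] | RegulatorSet,
                 init_modules: Optional[ModuleAssignment] = None,
                 hyper: Optional[Hyperparameters] = None,
                 **overrides) -> None:
        self.expr = expr
        self.regulators = (regulators if isinstance(regulators, RegulatorSet)
                           else RegulatorSet(regulators))
        self.regulators.validate_against(expr)
        if hyper is None:
            hyper = Hyperparameters(**overrides)
        elif overrides:
            raise TypeError("pass either hyper or keyword overrides, not both")
        self.hyper = hyper
        self.init_modules = init_modules

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       regulators: Sequence[str], **kwargs) -> "Merlin":
        return cls(ExpressionMatrix.from_dataframe(df), regulators, **kwargs)

    def fit(self, perturb_seed: Optional[int] = None) -> "MerlinResults":
        """Run the learner to convergence.

        ``perturb_seed`` switches on the random-restart initialisation: the
        initial modules are clustered on a random 90% subset of the samples.
        """
        rng = (np.random.default_rng(perturb_seed)
               if perturb_seed is not None else None)
        fit = learner.run_merlin(self.expr, self.regulators,
                                 init_modules=self.init_modules,
                                 hyper=self.hyper, rng=rng)
        return MerlinResults(self, fit)

    def fit_restarts(self, n_restarts: int = 5, seed: int = 0,
                     min_support: int = 3,
                     ) -> Tuple["RegulatoryNetwork", List["MerlinResults"]]:
        """Random restarts plus the support-based consensus network."""
        results = [self.fit(perturb_seed=seed * 1000 + i)
                   for i in range(n_restarts)]
        consensus = learner.consensus_network([r.network for r in results],
                                              min_support=min_support)
        return consensus, results


class MerlinResults:
    """Converged (network, programs, modules) triple with diagnostics."""

    def __init__(self, model: Merlin, fit: learner.MerlinFit) -> None:
        self.model = model
        self.network: RegulatoryNetwork = fit.network
        self.programs: Dict[str, GeneRegulatoryProgram] = fit.programs
        self.modules: ModuleAssignment = fit.modules
        self.score_trajectory: List[float] = fit.score_trajectory
        self.hyper: Hyperparameters = fit.hyper
        self.n_iterations: int = fit.n_iterations
        self.converged: bool = fit.converged

    # -- prediction ------------------------------------------------------

    def predict(self, expr: Optional[ExpressionMatrix] = None) -> pd.DataFrame:
        """Predicted expression of every gene from its regulators' values."""
        if expr is None:
            expr = self.model.expr
        out = np.zeros((len(expr.gene_ids), expr.n_samples))
        for i, g in enumerate(expr.gene_ids):
            prog = self.programs[g]
            row = np.full(expr.n_samples, prog.intercept)
            if prog.regulator_ids:
                X = np.stack([expr.row(r) for r in prog.regulator_ids])
                row = row + prog.coefficients @ X
            out[i] = row
        return pd.DataFrame(out, index=list(expr.gene_ids),
                            columns=list(expr.sample_ids))

    def edge_confidences(self) -> List[Tuple[str, str, float]]:
        """Per-edge log-likelihood drop when the edge is removed.

        A large drop means the regulator explains variance no other selected
        regulator can absorb; used to rank edges for precision-recall.
        """
        expr = self.model.expr
        scored: List[Tuple[str, str, float]] = []
        for g in sorted(self.programs):
            prog = self.programs[g]
            if not prog.regulator_ids:
                continue
            scorer = learner._GeneScorer(expr, g, list(prog.regulator_ids),
                                         self.hyper.ridge)
            _, ll_full = scorer.fit(list(prog.regulator_ids))
            for r in prog.regulator_ids:
                rest = [x for x in prog.regulator_ids if x != r]
                _, ll_rest = scorer.fit(rest)
                scored.append((r, g, ll_full - ll_rest))
        return scored

    # -- diagnostics -----------------------------------------------------

    def total_score(self) -> float:
        return self.score_trajectory[-1] if self.score_trajectory else float("nan")

    def regulatory_modularity(self) -> Dict[int, float]:
        return regulatory_modularity(self.network, self.modules)

    def summary(self) -> str:
        good, coverage = module_stats(self.modules)
        mod = self.regulatory_modularity()
        mean_mod = float(np.mean(list(mod.values()))) if mod else float("nan")
        lines = [
            "Module-constrained regulatory network fit",
            "=" * 46,
            f"genes:                {self.model.expr.n_genes}",
            f"samples:              {self.model.expr.n_samples}",
            f"candidate regulators: {len(self.model.regulators)}",
            f"edges inferred:       {len(self.network)}",
            f"modules:              {self.modules.n_modules}"
            f" ({good} with >= 5 genes, coverage {coverage:.2f})",
            f"mean reg. modularity: {mean_mod:.3f}",
            f"iterations:           {self.n_iterations}"
            f" (converged: {self.converged})",
            f"final score:          {self.total_score():.3f}",
            f"sparsity / module weight / threshold: "
            f"{self.hyper.sparsity:g} / {self.hyper.module_weight:g} / "
            f"{self.hyper.cluster_threshold:g}",
        ]
        return "\n".join(lines)

    def plot_score_trajectory(self, ax=None):
        """Score per iteration; returns the matplotlib axes."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(range(1, len(self.score_trajectory) + 1),
                self.score_trajectory, marker="o")
        ax.set_xlabel("iteration")
        ax.set_ylabel("total score")
        return ax
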