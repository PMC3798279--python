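"""Scoring machinery: conditional-Gaussian likelihood and the modular prior.

The score of a candidate network decomposes per gene into a pseudo-likelihood
term (the Gaussian log-density of the gene given its regulators) and a graph
prior term.  The prior is logistic in an edge feature ``f`` that measures how
strongly a regulator already acts inside the candidate target's module, so
that edges consolidating existing modules are cheaper than edges scattering a
regulator across modules.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .datatypes import (VARIANCE_FLOOR, EdgeFeature, ExpressionMatrix,
                        GeneRegulatoryProgram, Hyperparameters,
                        ModuleAssignment, RegulatoryNetwork, RegulatorSet,
                        SingularCovarianceError)

__all__ = [
    "fit_conditional_gaussian", "log_pseudo_likelihood", "edge_feature",
    "edge_prior_log_odds", "graph_prior_log_score", "total_score",
    "predict_expression", "log_sigmoid",
]


def log_sigmoid(x: float) -> float:
    """Numerically stable log of the logistic function."""
    return -np.logaddexp(0.0, -x)


# ---------------------------------------------------------------------------
# Conditional Gaussian
# ---------------------------------------------------------------------------

def fit_conditional_gaussian(expr: ExpressionMatrix, target: str,
                             regulators: Sequence[str],
                             ridge: float = 1e-6,
                             var_floor: float = VARIANCE_FLOOR,
                             ) -> GeneRegulatoryProgram:
    """Fit the Gaussian of ``target`` conditional on ``regulators``.

    The joint (k+1)-dimensional Gaussian over the target and its regulators
    is estimated by maximum likelihood (covariance divided by m), then
    converted to the conditional form: coefficients ``a = S_RR^-1 S_RT``,
    intercept ``mu_T - a' mu_R`` and conditional variance
    ``S_TT - S_TR S_RR^-1 S_RT`` (floored at ``var_floor``).  ``ridge`` is
    added to the diagonal of ``S_RR`` before inversion.
    """
    regulators = list(regulators)
    if target in regulators:
        raise ValueError(f"target {target!r} cannot be its own regulator")
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples to fit a Gaussian")
    y = expr.row(target)
    mu_t = float(y.mean())
    if not regulators:
        var = max(float(y.var()), var_floor)
        return GeneRegulatoryProgram(target, (), np.empty(0), mu_t, var)
    X = np.stack([expr.row(r) for r in regulators])  # k x m
    mu_r = X.mean(axis=1)
    Xc = X - mu_r[:, None]
    yc = y - mu_t
    m = expr.n_samples
    s_rr = Xc @ Xc.T / m
    s_rt = Xc @ yc / m
    s_tt = float(yc @ yc) / m
    a = _solve_regulator_system(s_rr, s_rt, ridge)
    var = max(s_tt - float(a @ s_rt), var_floor)
    intercept = mu_t - float(a @ mu_r)
    return GeneRegulatoryProgram(target, tuple(regulators), a, intercept, var)


def _solve_regulator_system(s_rr: np.ndarray, s_rt: np.ndarray,
                            ridge: float) -> np.ndarray:
    A = s_rr + ridge * np.eye(s_rr.shape[0])
    try:
        a = np.linalg.solve(A, s_rt)
    except np.linalg.LinAlgError as exc:
        if ridge == 0:
            raise SingularCovarianceError(
                "regulator covariance is singular; use ridge > 0") from exc
        raise
    if not np.all(np.isfinite(a)):
        raise SingularCovarianceError(
            "regulator covariance is numerically singular; use ridge > 0")
    return a


def log_pseudo_likelihood(expr: ExpressionMatrix,
                          program: GeneRegulatoryProgram) -> float:
    """Sum over samples of the conditional Gaussian log-density of the target."""
    var = program.conditional_variance
    if var < VARIANCE_FLOOR:
        raise ValueError("conditional variance below floor; refit the program")
    y = expr.row(program.target_id)
    pred = np.full(expr.n_samples, program.intercept)
    if program.regulator_ids:
        X = np.stack([expr.row(r) for r in program.regulator_ids])
        pred = pred + program.coefficients @ X
    resid = y - pred
    m = expr.n_samples
    return float(-0.5 * m * math.log(2.0 * math.pi * var)
                 - float(resid @ resid) / (2.0 * var))


def predict_expression(program: GeneRegulatoryProgram,
                       regulator_values: Sequence[float]) -> float:
    """Linear prediction ``intercept + a' x_R`` for one sample."""
    values = np.asarray(regulator_values, dtype=float).ravel()
    if len(values) != len(program.regulator_ids):
        raise ValueError(
            f"expected {len(program.regulator_ids)} regulator values, "
            f"got {len(values)}")
    return float(program.intercept + program.coefficients @ values)


# ---------------------------------------------------------------------------
# Modular graph prior
# ---------------------------------------------------------------------------

def edge_feature(prev_graph: RegulatoryNetwork, modules: ModuleAssignment,
                 regulator: str, target: str) -> EdgeFeature:
    """Fraction of the regulator's previous-iteration targets that lie in the
    candidate target's module; 0 when the regulator has no targets yet."""
    targets = prev_graph.targets_of(regulator)
    if not targets:
        return EdgeFeature(0.0)
    mod = modules.module_of(target)
    n_in = sum(1 for t in targets if modules.module_of(t) == mod)
    return EdgeFeature(n_in / len(targets))


def edge_prior_log_odds(feature: EdgeFeature,
                        hyper: Hyperparameters) -> float:
    """Log-odds of edge presence: ``sparsity + module_weight * f``."""
    f = feature.value if isinstance(feature, EdgeFeature) else float(feature)
    return hyper.sparsity + hyper.module_weight * f


def compute_feature_table(prev_graph: RegulatoryNetwork,
                          modules: ModuleAssignment,
                          regulators: Iterable[str],
                          genes: Sequence[str]) -> Dict[str, Dict[str, float]]:
    """Feature f for every candidate (regulator, target) pair, computed once
    per learning iteration from the previous-iteration graph."""
    targets_map = prev_graph.targets_map()
    table: Dict[str, Dict[str, float]] = {}
    module_ids = {g: modules.module_of(g) for g in genes}
    for r in regulators:
        targets = targets_map.get(r, [])
        row: Dict[str, float] = {}
        if targets:
            counts: Dict[int, int] = {}
            for t in targets:
                mod = modules.module_of(t)
                counts[mod] = counts.get(mod, 0) + 1
            n = len(targets)
            for g in genes:
                if g == r:
                    continue
                row[g] = counts.get(module_ids[g], 0) / n
        else:
            for g in genes:
                if g == r:
                    continue
                row[g] = 0.0
        table[r] = row
    return table


def graph_prior_log_score(graph: RegulatoryNetwork,
                          prev_graph: RegulatoryNetwork,
                          modules: ModuleAssignment,
                          regulators: RegulatorSet,
                          hyper: Hyperparameters,
                          genes: Optional[Sequence[str]] = None) -> float:
    """Log prior of the graph: sum of log P(present) over edges in ``graph``
    and log P(absent) over all remaining candidate pairs.

    Candidate pairs are all (regulator, gene) pairs excluding self-loops;
    features come from ``prev_graph`` (frozen within a learning iteration).
    """
    if genes is None:
        genes = modules.genes
    table = compute_feature_table(prev_graph, modules, regulators, genes)
    total = 0.0
    for r in regulators:
        row = table[r]
        for g in genes:
            if g == r:
                continue
            lo = hyper.sparsity + hyper.module_weight * row[g]
            if (r, g) in graph:
                total += log_sigmoid(lo)
            else:
                total += log_sigmoid(-lo)
    return total


def total_score(expr: ExpressionMatrix, graph: RegulatoryNetwork,
                programs: Mapping[str, GeneRegulatoryProgram],
                prev_graph: RegulatoryNetwork, modules: ModuleAssignment,
                regulators: RegulatorSet, hyper: Hyperparameters) -> float:
    """Pseudo-likelihood of all genes plus the graph prior.

    The score decomposes additively over genes; ``programs`` must be
    structurally consistent with ``graph`` (same regulator sets per target).
    """
    for gene in expr.gene_ids:
        prog = programs.get(gene)
        if prog is None:
            raise ValueError(f"no program for gene {gene!r}")
        prog_regs = set(prog.regulator_ids)
        graph_regs = set(graph.regulators_of(gene))
        if prog_regs != graph_regs:
            raise ValueError(
                f"graph and programs disagree for gene {gene!r}: "
                f"{sorted(graph_regs)} vs {sorted(prog_regs)}")
    ll = sum(log_pseudo_likelihood(expr, programs[g]) for g in expr.gene_ids)
    prior = graph_prior_log_score(graph, prev_graph, modules, regulators,
                                  hyper, genes=expr.gene_ids)
    return ll + prior
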