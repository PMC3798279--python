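"""The iterative learner: greedy per-gene regulator selection under the
module prior, alternating with regulatory-similarity-aware re-clustering.

Each iteration (a) grows the regulator set of every gene greedily, scoring a
candidate addition by its pseudo-likelihood gain plus the logistic prior
log-odds of the new edge (with the module feature frozen at the graph from
the start of the iteration), then (b) re-derives the modules by agglomerative
clustering of a distance that mixes co-expression with similarity of the
inferred regression weight vectors.  Greedy acceptance rules keep the total
score non-decreasing; the loop stops when neither the edges nor the modules
move, when the score improvement falls below tolerance, or at the iteration
cap.
"""

from __future__ import annotations

import heapq
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from . import core
from .datatypes import (VARIANCE_FLOOR, ExpressionMatrix,
                        GeneRegulatoryProgram, Hyperparameters,
                        ModuleAssignment, RegulatoryNetwork, RegulatorSet)

logger = logging.getLogger(__name__)

__all__ = [
    "select_regulators_for_gene", "regulatory_similarity", "gene_distance",
    "gene_distance_matrix", "hierarchical_cluster", "run_merlin",
    "consensus_network", "stability_confidence", "linear_regression_network",
    "initial_modules", "MerlinFit",
]


# ---------------------------------------------------------------------------
# Fast conditional-Gaussian fits from precomputed moments
# ---------------------------------------------------------------------------

class _GeneScorer:
    """Moment-based conditional-Gaussian fits for one target gene.

    All subset fits reuse the ML covariance of (candidates, target), so a
    greedy sweep costs one small linear solve per candidate evaluation.  The
    log-likelihood uses the algebraic identity
    ``RSS/m = S_TT - 2 a'S_RT + a'S_RR a`` and agrees with the direct
    residual computation to machine precision.
    """

    def __init__(self, expr: ExpressionMatrix, target: str,
                 candidates: Sequence[str], ridge: float) -> None:
        self.target = target
        self.candidates = list(candidates)
        self.ridge = ridge
        self.m = expr.n_samples
        rows = [expr.index_of(c) for c in self.candidates]
        X = expr.values[rows]  # k x m
        y = expr.row(target)
        self.mu_r = X.mean(axis=1) if rows else np.empty(0)
        self.mu_t = float(y.mean())
        Xc = X - self.mu_r[:, None] if rows else X
        yc = y - self.mu_t
        self.s_rr = Xc @ Xc.T / self.m if rows else np.empty((0, 0))
        self.s_rt = Xc @ yc / self.m if rows else np.empty(0)
        self.s_tt = float(yc @ yc) / self.m
        self._pos = {c: i for i, c in enumerate(self.candidates)}

    def fit(self, regs: Sequence[str]) -> Tuple[GeneRegulatoryProgram, float]:
        """Return (program, log pseudo-likelihood) for a regulator subset."""
        if not regs:
            var = max(self.s_tt, VARIANCE_FLOOR)
            prog = GeneRegulatoryProgram(self.target, (), np.empty(0),
                                         self.mu_t, var)
            return prog, self._loglik(var, self.s_tt)
        idx = [self._pos[r] for r in regs]
        s_rr = self.s_rr[np.ix_(idx, idx)]
        s_rt = self.s_rt[idx]
        a = core._solve_regulator_system(s_rr, s_rt, self.ridge)
        var = max(self.s_tt - float(a @ s_rt), VARIANCE_FLOOR)
        rss_mean = max(self.s_tt - 2.0 * float(a @ s_rt)
                       + float(a @ (s_rr @ a)), 0.0)
        intercept = self.mu_t - float(a @ self.mu_r[idx])
        prog = GeneRegulatoryProgram(self.target, tuple(regs), a,
                                     intercept, var)
        return prog, self._loglik(var, rss_mean)

    def _loglik(self, var: float, rss_mean: float) -> float:
        return float(-0.5 * self.m * math.log(2.0 * math.pi * var)
                     - self.m * rss_mean / (2.0 * var))


def _gene_prior(regs: Iterable[str], log_odds: Mapping[str, float]) -> float:
    """Prior contribution of one gene: present/absent terms over candidates."""
    total = 0.0
    present = set(regs)
    for c, lo in log_odds.items():
        total += core.log_sigmoid(lo if c in present else -lo)
    return total


def select_regulators_for_gene(expr: ExpressionMatrix, target: str,
                               candidates: RegulatorSet,
                               prev_graph: RegulatoryNetwork,
                               modules: ModuleAssignment,
                               hyper: Hyperparameters,
                               ) -> GeneRegulatoryProgram:
    """Greedily grow the regulator set of ``target`` from empty.

    Each step adds the candidate with the largest gain in pseudo-likelihood
    plus edge-prior log-odds; selection stops when the best gain drops to the
    score tolerance or the per-gene cap is reached.  Ties break
    lexicographically by regulator id.  Module features are computed from
    ``prev_graph`` and frozen for the whole selection.
    """
    cand = sorted(set(candidates.regulator_ids) - {target})
    log_odds = {
        c: core.edge_prior_log_odds(
            core.edge_feature(prev_graph, modules, c, target), hyper)
        for c in cand}
    scorer = _GeneScorer(expr, target, cand, hyper.ridge)
    program, _ = _greedy_select(scorer, cand, log_odds, hyper,
                                hyper.resolved_tolerance(expr.n_genes))
    return program


def _greedy_select(scorer: _GeneScorer, cand: Sequence[str],
                   log_odds: Mapping[str, float], hyper: Hyperparameters,
                   tol: float) -> Tuple[GeneRegulatoryProgram, float]:
    """Greedy forward selection; returns the program and its log-likelihood."""
    cap = hyper.max_regulators_per_gene
    selected: List[str] = []
    program, cur_ll = scorer.fit(())
    remaining = sorted(cand)  # kept sorted -> lexicographic tie-break
    while remaining and (cap is None or len(selected) < cap):
        best = None
        for c in remaining:
            trial = sorted(selected + [c])
            try:
                prog_c, ll_c = scorer.fit(trial)
            except np.linalg.LinAlgError:
                continue
            delta = (ll_c - cur_ll) + log_odds[c]
            if best is None or delta > best[0]:
                best = (delta, c, prog_c, ll_c)
        if best is None or best[0] <= tol:
            break
        _, chosen, program, cur_ll = best
        selected = sorted(selected + [chosen])
        remaining.remove(chosen)
    return program, cur_ll


# ---------------------------------------------------------------------------
# Gene distance and module clustering
# ---------------------------------------------------------------------------

def regulatory_similarity(w_i: Mapping[str, float],
                          w_j: Mapping[str, float]) -> float:
    """Sign- and magnitude-aware Jaccard similarity of two weight vectors.

    Numerator: sum over shared regulators with matching coefficient sign of
    min(|w_i|, |w_j|); denominator: ||w_i||_1 + ||w_j||_1 - numerator.
    Returns 0 when both vectors are empty.
    """
    num = 0.0
    for r, a in w_i.items():
        b = w_j.get(r)
        if b is None or a == 0.0 or b == 0.0:
            continue
        if (a > 0) == (b > 0):
            num += min(abs(a), abs(b))
    l1 = sum(abs(v) for v in w_i.values()) + sum(abs(v) for v in w_j.values())
    denom = l1 - num
    if denom <= 0.0:
        return 0.0
    return num / denom


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; 0 for constant vectors."""
    xc = x - x.mean()
    yc = y - y.mean()
    nx = float(xc @ xc)
    ny = float(yc @ yc)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(xc @ yc) / math.sqrt(nx * ny)


def gene_distance(expr: ExpressionMatrix, w_i: Mapping[str, float],
                  w_j: Mapping[str, float], gene_i: str,
                  gene_j: str) -> float:
    """Mean of expression distance (1 - rho)/2 and regulatory distance
    (1 - similarity); lies in [0, 1]."""
    rho = _pearson(expr.row(gene_i), expr.row(gene_j))
    sim = regulatory_similarity(w_i, w_j)
    return 0.5 * ((1.0 - rho) / 2.0 + (1.0 - sim))


def gene_distance_matrix(expr: ExpressionMatrix,
                         weights: Optional[Mapping[str, Mapping[str, float]]]
                         = None) -> np.ndarray:
    """All-pairs gene distance; expression-only when ``weights`` is None.

    With ``weights`` the distance is the mean of the correlation distance and
    the regulatory distance; without, it is the correlation distance alone
    (used for the initial, pre-network clustering).  Diagonal is zero.
    """
    X = expr.values
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt((Xc ** 2).sum(axis=1))
    safe = np.where(norms == 0.0, 1.0, norms)
    Z = Xc / safe[:, None]
    corr = Z @ Z.T
    corr[norms == 0.0, :] = 0.0
    corr[:, norms == 0.0] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    expr_dist = (1.0 - corr) / 2.0
    if weights is None:
        dist = expr_dist.copy()
    else:
        n = expr.n_genes
        reg_dist = np.ones((n, n))
        wlist = [weights.get(g, {}) for g in expr.gene_ids]
        for i in range(n):
            for j in range(i + 1, n):
                s = regulatory_similarity(wlist[i], wlist[j])
                reg_dist[i, j] = reg_dist[j, i] = 1.0 - s
        dist = 0.5 * (expr_dist + reg_dist)
    np.fill_diagonal(dist, 0.0)
    return dist


def _key(a: int, b: int) -> Tuple[int, int]:
    return (a, b) if a < b else (b, a)


def hierarchical_cluster(dist: np.ndarray, threshold: float,
                         gene_ids: Sequence[str]) -> ModuleAssignment:
    """Threshold-stopped average-linkage (UPGMA) agglomerative clustering.

    Clusters merge while the smallest inter-cluster distance is <= threshold
    and halt as soon as it exceeds the threshold.  A lazy-deletion min-heap
    keeps the sweep near O(n^2 log n); ties break lexicographically on the
    clusters' smallest gene ids, so the partition is deterministic.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(gene_ids)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match gene ids")
    if n == 1:
        return ModuleAssignment({gene_ids[0]: 1})
    members: Dict[int, List[int]] = {i: [i] for i in range(n)}
    rep: Dict[int, str] = {i: str(gene_ids[i]) for i in range(n)}
    d: Dict[Tuple[int, int], float] = {}
    heap: List[Tuple[float, str, str, int, int]] = []
    for i in range(n):
        for j in range(i + 1, n):
            val = float(dist[i, j])
            d[(i, j)] = val
            ra, rb = sorted((rep[i], rep[j]))
            heap.append((val, ra, rb, i, j))
    heapq.heapify(heap)
    alive = set(range(n))
    next_id = n
    while heap and len(alive) > 1:
        dd, _, _, i, j = heapq.heappop(heap)
        if i not in alive or j not in alive:
            continue  # lazy deletion of entries whose clusters were merged
        if dd > threshold:
            break
        ni, nj = len(members[i]), len(members[j])
        alive.discard(i)
        alive.discard(j)
        d.pop(_key(i, j), None)
        cid = next_id
        next_id += 1
        new_dists: Dict[int, float] = {}
        for k in alive:
            dik = d.pop(_key(i, k))
            djk = d.pop(_key(j, k))
            new_dists[k] = (ni * dik + nj * djk) / (ni + nj)
        members[cid] = members.pop(i) + members.pop(j)
        rep[cid] = min(rep[i], rep[j])
        for k, val in new_dists.items():
            d[_key(cid, k)] = val
            ra, rb = sorted((rep[cid], rep[k]))
            heapq.heappush(heap, (val, ra, rb, *_key(cid, k)))
        alive.add(cid)
    membership = {}
    for label, c in enumerate(sorted(alive, key=lambda c: rep[c]), start=1):
        for gi in members[c]:
            membership[str(gene_ids[gi])] = label
    return ModuleAssignment(membership)


def initial_modules(expr: ExpressionMatrix, cluster_threshold: float,
                    rng: Optional[np.random.Generator] = None,
                    sample_fraction: float = 0.9) -> ModuleAssignment:
    """Initial modules from expression distance alone.

    With ``rng`` the clustering is run on a random ``sample_fraction`` subset
    of the samples, giving the seed-controlled perturbation used for random
    restarts; without, it is deterministic.
    """
    view = expr
    if rng is not None:
        k = max(2, int(round(sample_fraction * expr.n_samples)))
        idx = sorted(rng.choice(expr.n_samples, size=min(k, expr.n_samples),
                                replace=False).tolist())
        view = expr.subset_samples(idx)
    dist = gene_distance_matrix(view, weights=None)
    return hierarchical_cluster(dist, cluster_threshold, expr.gene_ids)


# ---------------------------------------------------------------------------
# The main loop
# ---------------------------------------------------------------------------

@dataclass
class MerlinFit:
    """Converged state of a learning run: the (G, Theta, M) triple."""

    network: RegulatoryNetwork
    programs: Dict[str, GeneRegulatoryProgram]
    modules: ModuleAssignment
    score_trajectory: List[float]
    hyper: Hyperparameters
    n_iterations: int
    converged: bool


def _network_from_programs(
        programs: Mapping[str, GeneRegulatoryProgram]) -> RegulatoryNetwork:
    net = RegulatoryNetwork()
    for gene in sorted(programs):
        prog = programs[gene]
        for r, w in zip(prog.regulator_ids, prog.coefficients):
            net.add_edge(r, gene, float(w))
    return net


def run_merlin(expr: ExpressionMatrix, candidates: RegulatorSet,
               init_modules: Optional[ModuleAssignment] = None,
               hyper: Optional[Hyperparameters] = None,
               rng: Optional[np.random.Generator] = None) -> MerlinFit:
    """Alternate regulator selection and module re-clustering to convergence.

    The recorded score per iteration is the self-consistent total score
    (pseudo-likelihood plus graph prior with features computed from the
    iteration's own output graph).  Moves are accepted only when they do not
    lower the score, so the trajectory is non-decreasing.
    """
    if hyper is None:
        hyper = Hyperparameters()
    if expr.has_missing():
        raise ValueError("expression matrix contains missing values; "
                         "run preprocessing first")
    candidates.validate_against(expr)
    genes = list(expr.gene_ids)
    if init_modules is None:
        modules = initial_modules(expr, hyper.cluster_threshold, rng=rng)
    else:
        unassigned = sorted(set(genes) - set(init_modules.membership))
        if unassigned:
            raise ValueError(f"genes without initial module: {unassigned}")
        modules = init_modules
    tol = hyper.resolved_tolerance(len(genes))
    order = sorted(genes)
    scorers = {g: _GeneScorer(expr, g,
                              sorted(set(candidates.regulator_ids) - {g}),
                              hyper.ridge)
               for g in order}
    programs: Dict[str, GeneRegulatoryProgram] = {}
    loglik: Dict[str, float] = {}
    for g in order:
        programs[g], loglik[g] = scorers[g].fit(())
    graph = RegulatoryNetwork()
    trajectory: List[float] = []
    converged = False
    n_iter = 0
    reg_set = RegulatorSet(candidates.regulator_ids)
    for n_iter in range(1, hyper.max_iterations + 1):
        prev_modules = modules
        if n_iter > 1:
            # revisit module memberships using co-expression plus the
            # regulatory similarity of the previous sweep's weight vectors
            wmap = {g: programs[g].weights for g in order}
            dmat = gene_distance_matrix(expr, wmap)
            modules = hierarchical_cluster(dmat, hyper.cluster_threshold,
                                           expr.gene_ids)
        feats = core.compute_feature_table(graph, modules,
                                           candidates.regulator_ids, genes)
        new_programs: Dict[str, GeneRegulatoryProgram] = {}
        new_loglik: Dict[str, float] = {}
        for g in order:
            log_odds = {c: hyper.sparsity + hyper.module_weight * feats[c][g]
                        for c in scorers[g].candidates}
            prog, ll = _greedy_select(scorers[g], scorers[g].candidates,
                                      log_odds, hyper, tol)
            # keep the previous program when the fresh greedy result does not
            # improve this gene's likelihood + prior under the frozen features
            obj_new = ll + _gene_prior(prog.regulator_ids, log_odds)
            obj_old = (loglik[g]
                       + _gene_prior(programs[g].regulator_ids, log_odds))
            if obj_new > obj_old + 1e-12:
                new_programs[g], new_loglik[g] = prog, ll
            else:
                new_programs[g], new_loglik[g] = programs[g], loglik[g]
        new_graph = _network_from_programs(new_programs)
        score = (sum(new_loglik[g] for g in order)
                 + core.graph_prior_log_score(new_graph, graph, modules,
                                              reg_set, hyper, genes=genes))
        if trajectory and score < trajectory[-1] - 1e-9:
            # no move improves the score; keep the previous state
            modules = prev_modules
            n_iter -= 1
            converged = True
            break
        unchanged = (new_graph.edge_keys() == graph.edge_keys()
                     and modules == prev_modules)
        small_gain = bool(trajectory) and (score - trajectory[-1]) < tol
        trajectory.append(score)
        programs, loglik = new_programs, new_loglik
        graph = new_graph
        if unchanged or small_gain:
            converged = True
            break
    return MerlinFit(network=graph, programs=programs, modules=modules,
                     score_trajectory=trajectory, hyper=hyper,
                     n_iterations=n_iter, converged=converged)


def linear_regression_network(expr: ExpressionMatrix,
                              candidates: RegulatorSet,
                              hyper: Optional[Hyperparameters] = None,
                              ) -> Tuple[RegulatoryNetwork,
                                         Dict[str, GeneRegulatoryProgram]]:
    """Pure per-gene greedy regression baseline (no module prior).

    One greedy sweep per gene under the sparsity-only prior; this is the
    special case of the full learner with the module weight set to zero.
    """
    if hyper is None:
        hyper = Hyperparameters()
    base = Hyperparameters(sparsity=hyper.sparsity, module_weight=0.0,
                           cluster_threshold=hyper.cluster_threshold,
                           max_iterations=hyper.max_iterations,
                           score_tolerance=hyper.score_tolerance,
                           max_regulators_per_gene=hyper.max_regulators_per_gene,
                           ridge=hyper.ridge, seed=hyper.seed)
    tol = base.resolved_tolerance(expr.n_genes)
    programs: Dict[str, GeneRegulatoryProgram] = {}
    for g in sorted(expr.gene_ids):
        cand = sorted(set(candidates.regulator_ids) - {g})
        scorer = _GeneScorer(expr, g, cand, base.ridge)
        log_odds = {c: base.sparsity for c in cand}
        programs[g], _ = _greedy_select(scorer, cand, log_odds, base, tol)
    return _network_from_programs(programs), programs


# ---------------------------------------------------------------------------
# Consensus and stability
# ---------------------------------------------------------------------------

def consensus_network(runs: Sequence[RegulatoryNetwork],
                      min_support: int) -> RegulatoryNetwork:
    """Keep edges supported by >= ``min_support`` of the runs.

    Confidence is the support fraction, weight the mean over supporting runs.
    """
    if not runs:
        raise ValueError("need at least one run")
    if min_support > len(runs):
        warnings.warn(f"min_support {min_support} exceeds number of runs "
                      f"{len(runs)}; consensus network is empty")
    support: Dict[Tuple[str, str], List[float]] = {}
    for net in runs:
        for e in net:
            support.setdefault((e.regulator, e.target), []).append(e.weight)
    out = RegulatoryNetwork()
    n = len(runs)
    for (r, t), weights in support.items():
        if len(weights) >= min_support:
            out.add_edge(r, t, weight=float(np.mean(weights)),
                         confidence=len(weights) / n)
    return out


def stability_confidence(expr: ExpressionMatrix, candidates: RegulatorSet,
                         hyper: Optional[Hyperparameters] = None,
                         n_subsets: int = 100, subset_fraction: float = 0.5,
                         seed: int = 0) -> RegulatoryNetwork:
    """Edge confidences from learner runs on random sample subsets."""
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    if not (0.0 < subset_fraction <= 1.0):
        raise ValueError("subset_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(n_subsets):
        k = max(2, int(round(subset_fraction * expr.n_samples)))
        idx = sorted(rng.choice(expr.n_samples, size=min(k, expr.n_samples),
                                replace=False).tolist())
        sub = expr.subset_samples(idx)
        runs.append(run_merlin(sub, candidates, hyper=hyper).network)
    return consensus_network(runs, min_support=1)
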