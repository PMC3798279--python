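"""Edge-, regulator- and module-based network comparison metrics.

Edge metrics (confusion counts, fold enrichment, precision-recall/AUPR) are
computed on the universe of possible edges restricted to the regulator and
target nodes common to both networks, with self-pairs excluded.  Regulator
and module metrics use hypergeometric overlap tests with Benjamini-Hochberg
control across tests.  Diagnostics include the regulator-sharing modularity
of a partition (within minus between, each in [0, 1], so the score lies in
[-1, 1]) and per-module silhouette on correlation distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

from .datatypes import (ExpressionMatrix, ModuleAssignment,
                        RegulatoryNetwork)
from .learner import gene_distance_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeConfusion", "RegulatorModuleMap", "EvaluationReport",
    "edge_confusion", "fold_enrichment", "precision_recall_curve", "aupr",
    "hypergeometric_tail", "bh_fdr", "regulator_target_overlap",
    "regulator_module_map", "regulator_module_fscore",
    "regulatory_modularity", "silhouette_by_module",
    "interaction_enrichment_zscore", "geneset_enrichment", "module_stats",
    "edge_fscore", "evaluate_networks",
]


# ---------------------------------------------------------------------------
# Edge-based metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeConfusion:
    true_positives: int
    inferred_total: int
    true_total: int
    universe_total: int

    def __post_init__(self) -> None:
        if not (self.true_positives <= min(self.inferred_total, self.true_total)
                <= self.universe_total):
            raise ValueError(f"inconsistent confusion counts: {self}")


def edge_confusion(inferred: RegulatoryNetwork,
                   truth: RegulatoryNetwork) -> EdgeConfusion:
    """Confusion counts over the common regulator x target universe."""
    if len(inferred) == 0 or len(truth) == 0:
        raise ValueError("both networks must be non-empty")
    regs = set(inferred.regulators) & set(truth.regulators)
    nodes = set(inferred.nodes) & set(truth.nodes)
    universe = {(r, t) for r in regs for t in nodes if r != t}
    if not universe:
        raise ValueError("empty comparison universe: the networks share no "
                         "regulator/target nodes")
    inf_edges = inferred.edge_keys() & universe
    true_edges = truth.edge_keys() & universe
    return EdgeConfusion(true_positives=len(inf_edges & true_edges),
                         inferred_total=len(inf_edges),
                         true_total=len(true_edges),
                         universe_total=len(universe))


def fold_enrichment(c: EdgeConfusion) -> float:
    """Precision of the inferred edges over the background edge density."""
    if c.inferred_total == 0 or c.true_total == 0 or c.universe_total == 0:
        raise ValueError("fold enrichment undefined for zero denominators")
    return (c.true_positives / c.inferred_total) / (c.true_total
                                                    / c.universe_total)


def edge_fscore(c: EdgeConfusion) -> Tuple[float, float, float]:
    """Precision, recall and F-score of a thresholded network."""
    precision = c.true_positives / c.inferred_total if c.inferred_total else 0.0
    recall = c.true_positives / c.true_total if c.true_total else 0.0
    f = (2 * precision * recall / (precision + recall)
         if precision + recall > 0 else 0.0)
    return precision, recall, f


def precision_recall_curve(ranked_edges: Sequence[Tuple[str, str, float]],
                           truth: RegulatoryNetwork,
                           ) -> List[Tuple[float, float, float]]:
    """PR points (recall, precision, threshold), one per distinct confidence.

    Edges with equal confidence enter the curve together as one block.
    """
    if len(truth) == 0:
        raise ValueError("truth network has no positive edges")
    true_edges = truth.edge_keys()
    ordered = sorted(ranked_edges, key=lambda e: (-e[2], e[0], e[1]))
    n_true = len(true_edges)
    points: List[Tuple[float, float, float]] = []
    tp = 0
    npred = 0
    i = 0
    while i < len(ordered):
        conf = ordered[i][2]
        while i < len(ordered) and ordered[i][2] == conf:
            r, t, _ = ordered[i]
            npred += 1
            if (r, t) in true_edges:
                tp += 1
            i += 1
        points.append((tp / n_true, tp / npred, conf))
    return points


def aupr(curve: Sequence[Tuple[float, float, float]]) -> float:
    """Trapezoidal area under the precision-recall curve over recall."""
    if not curve:
        raise ValueError("empty precision-recall curve")
    area = 0.0
    prev_recall, prev_precision = 0.0, curve[0][1]
    for recall, precision, _ in curve:
        area += (recall - prev_recall) * (precision + prev_precision) / 2.0
        prev_recall, prev_precision = recall, precision
    return area


# ---------------------------------------------------------------------------
# Hypergeometric machinery
# ---------------------------------------------------------------------------

def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for drawing n from N with K successes."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"invalid hypergeometric counts k={k} K={K} "
                         f"n={n} N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# Regulator-based measures
# ---------------------------------------------------------------------------

def regulator_target_overlap(inferred: RegulatoryNetwork,
                             truth: RegulatoryNetwork,
                             fdr_threshold: float = 0.05,
                             ) -> Tuple[float, pd.DataFrame]:
    """Per-regulator hypergeometric overlap of inferred vs true target sets.

    Background is the shared target universe (nodes present in both
    networks).  Returns the fraction of tested regulators whose overlap is
    significant at the BH-adjusted threshold, plus the per-regulator table.
    """
    regs = sorted(set(inferred.regulators) | set(truth.regulators))
    background = set(inferred.nodes) & set(truth.nodes)
    rows = []
    inf_map = inferred.targets_map()
    true_map = truth.targets_map()
    for r in regs:
        bg = background - {r}
        t_inf = set(inf_map.get(r, ())) & bg
        t_true = set(true_map.get(r, ())) & bg
        if not t_inf and not t_true:
            logger.info("regulator %s has no targets in either network; "
                        "excluded from overlap test", r)
            continue
        k = len(t_inf & t_true)
        p = hypergeometric_tail(k, len(t_true), len(t_inf), len(bg))
        rows.append((r, len(t_inf), len(t_true), k, len(bg), p))
    table = pd.DataFrame(rows, columns=["regulator", "n_inferred", "n_true",
                                        "overlap", "background", "p_value"])
    if table.empty:
        return 0.0, table.assign(q_value=[], significant=[])
    table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    table["significant"] = table["q_value"] < fdr_threshold
    fraction = float(table["significant"].mean())
    return fraction, table


# ---------------------------------------------------------------------------
# Module-based measures
# ---------------------------------------------------------------------------

@dataclass
class RegulatorModuleMap:
    """Significant regulator-module associations with their p/q values."""

    associations: Set[Tuple[str, int]]
    table: pd.DataFrame

    def pairs(self) -> Set[Tuple[str, int]]:
        return set(self.associations)


def regulator_module_map(network: RegulatoryNetwork,
                         modules: ModuleAssignment,
                         fdr_threshold: float = 0.05,
                         min_module_size: int = 5) -> RegulatorModuleMap:
    """Hypergeometric enrichment of each regulator's targets in each module.

    Only modules with at least ``min_module_size`` genes are tested;
    BH correction is applied across all regulator x module tests.
    """
    background = set(modules.membership)
    N = len(background)
    big_modules = {m: set(genes) for m, genes in modules.modules().items()
                   if len(genes) >= min_module_size}
    rows = []
    for r in network.regulators:
        targets = set(network.targets_of(r)) & background
        if not targets:
            continue
        for m, genes in sorted(big_modules.items()):
            k = len(targets & genes)
            p = hypergeometric_tail(k, len(genes), len(targets), N)
            rows.append((r, m, len(targets), len(genes), k, p))
    table = pd.DataFrame(rows, columns=["regulator", "module", "n_targets",
                                        "module_size", "overlap", "p_value"])
    if table.empty:
        table["q_value"] = []
        return RegulatorModuleMap(set(), table)
    table["q_value"] = bh_fdr(table["p_value"].to_numpy())
    sig = table[table["q_value"] < fdr_threshold]
    pairs = {(str(row.regulator), int(row.module))
             for row in sig.itertuples(index=False)}
    return RegulatorModuleMap(pairs, table)


def regulator_module_fscore(true_map: RegulatorModuleMap,
                            inferred_map: RegulatorModuleMap,
                            ) -> Tuple[float, float, float, float]:
    """Precision/recall/F of inferred vs true regulator-module pairs, plus
    the hypergeometric overlap p-value over the tested pair universe."""
    true_pairs = true_map.pairs()
    pred_pairs = inferred_map.pairs()
    if not true_pairs:
        raise ValueError("true regulator-module map is empty")
    inter = true_pairs & pred_pairs
    precision = len(inter) / len(pred_pairs) if pred_pairs else 0.0
    recall = len(inter) / len(true_pairs)
    f = (2 * precision * recall / (precision + recall)
         if precision + recall > 0 else 0.0)
    universe = _tested_pairs(true_map) | _tested_pairs(inferred_map)
    universe |= true_pairs | pred_pairs
    N = len(universe)
    p = hypergeometric_tail(len(inter), len(true_pairs & universe),
                            len(pred_pairs & universe), N) if N else 1.0
    return precision, recall, f, p


def _tested_pairs(m: RegulatorModuleMap) -> Set[Tuple[str, int]]:
    if m.table.empty:
        return set()
    return {(str(r.regulator), int(r.module))
            for r in m.table.itertuples(index=False)}


def regulatory_modularity(network: RegulatoryNetwork,
                          modules: ModuleAssignment) -> Dict[int, float]:
    """Within- minus between-module regulator-sharing similarity per module.

    Pairwise similarity is the Dice form 2c/(n_i + n_j) over regulator sets
    (0 when both genes have no regulators); both the within and between
    components are means of similarities in [0, 1], so each module's score
    lies in [-1, 1].  Singleton modules score 0.
    """
    genes = modules.genes
    regsets = {g: frozenset(network.regulators_of(g)) for g in genes}

    def sim(a: str, b: str) -> float:
        ra, rb = regsets[a], regsets[b]
        tot = len(ra) + len(rb)
        if tot == 0:
            return 0.0
        return 2.0 * len(ra & rb) / tot

    scores: Dict[int, float] = {}
    by_module = modules.modules()
    for m, mem in by_module.items():
        if len(mem) < 2:
            logger.info("module %d is a singleton; modularity set to 0", m)
            scores[m] = 0.0
            continue
        within = [sim(a, b) for i, a in enumerate(mem) for b in mem[i + 1:]]
        outside = [g for g in genes if modules.module_of(g) != m]
        if outside:
            between = [sim(a, b) for a in mem for b in outside]
            between_mean = float(np.mean(between))
        else:
            between_mean = 0.0
        scores[m] = float(np.mean(within)) - between_mean
    return scores


def silhouette_by_module(expr: ExpressionMatrix,
                         modules: ModuleAssignment) -> Dict[int, float]:
    """Mean silhouette per module on (1 - Pearson)/2 expression distance."""
    if modules.n_modules < 2:
        raise ValueError("silhouette requires at least two modules")
    genes = expr.gene_ids
    labels = np.array([modules.module_of(g) for g in genes])
    dist = gene_distance_matrix(expr, weights=None)
    # expression-only distance is exactly (1 - rho)/2 with zero diagonal
    scores = silhouette_samples(dist, labels, metric="precomputed")
    out: Dict[int, float] = {}
    for m in sorted(set(labels.tolist())):
        out[int(m)] = float(scores[labels == m].mean())
    return out


# ---------------------------------------------------------------------------
# Enrichment statistics
# ---------------------------------------------------------------------------

def interaction_enrichment_zscore(regulator_set: Sequence[str],
                                  interaction_edges: Iterable[Tuple[str, str]],
                                  candidate_pool: Sequence[str],
                                  n_random: int = 100,
                                  seed: int = 0) -> float:
    """Z-score of observed interactions among a regulator set vs random sets.

    ``n_random`` equal-sized sets are drawn from ``candidate_pool``; the
    z-score is (observed - mean)/sd of their interaction counts.  Returns NaN
    (with a log message) when the background sd is zero.
    """
    reg_set = list(dict.fromkeys(regulator_set))
    pool = list(dict.fromkeys(candidate_pool))
    if not set(reg_set) <= set(pool):
        raise ValueError("regulator set must be drawn from the candidate pool")
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    pairs = {frozenset(e) for e in interaction_edges if e[0] != e[1]}

    def count(members: Sequence[str]) -> int:
        s = set(members)
        return sum(1 for p in pairs if p <= s)

    observed = count(reg_set)
    rng = np.random.default_rng(seed)
    draws = [count(rng.choice(pool, size=len(reg_set), replace=False))
             for _ in range(n_random)]
    mean, sd = float(np.mean(draws)), float(np.std(draws))
    if sd == 0.0:
        logger.warning("degenerate background (sd = 0) in interaction "
                       "enrichment; z-score undefined")
        return math.nan
    return (observed - mean) / sd


def geneset_enrichment(modules: ModuleAssignment,
                       genesets: Mapping[str, Sequence[str]],
                       background: Sequence[str],
                       fdr_threshold: float = 0.05,
                       min_module_size: int = 5) -> pd.DataFrame:
    """Module x gene-set hypergeometric enrichment with BH correction.

    Columns follow the supplementary-table layout: module id, term, p-value,
    FDR, annotation counts, fold enrichment and the contributing genes.
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background gene universe")
    N = len(bg)
    rows = []
    for m, mem in sorted(modules.modules().items()):
        mem_bg = set(mem) & bg
        if len(mem_bg) < min_module_size:
            continue
        for term, members in genesets.items():
            term_bg = set(members) & bg
            if not term_bg:
                continue
            hits = sorted(mem_bg & term_bg)
            p = hypergeometric_tail(len(hits), len(term_bg), len(mem_bg), N)
            fold = ((len(hits) / len(mem_bg)) / (len(term_bg) / N)
                    if hits else 0.0)
            rows.append((m, term, p, N, len(term_bg), len(mem_bg),
                         len(hits), fold, ",".join(hits)))
    table = pd.DataFrame(rows, columns=[
        "module", "term", "p_value", "background_size", "term_size",
        "module_size", "overlap", "fold_enrichment", "genes"])
    if table.empty:
        table["fdr"] = []
        table["significant"] = []
        return table
    table["fdr"] = bh_fdr(table["p_value"].to_numpy())
    table["significant"] = table["fdr"] < fdr_threshold
    return table.sort_values(["p_value", "module", "term"]).reset_index(drop=True)


def module_stats(modules: ModuleAssignment,
                 min_size: int = 5) -> Tuple[int, float]:
    """Count of good-sized modules (>= min_size genes) and the fraction of
    genes they cover."""
    sizes = modules.sizes()
    good = {m for m, s in sizes.items() if s >= min_size}
    covered = sum(sizes[m] for m in good)
    total = sum(sizes.values())
    return len(good), covered / total if total else 0.0


# ---------------------------------------------------------------------------
# Bundled report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Metric bundle comparing an inferred network (and modules) to a truth."""

    aupr: Optional[float]
    fold_enrichment: float
    edge_precision: float
    edge_recall: float
    edge_fscore: float
    per_regulator_overlap: float
    regulator_module_precision: Optional[float] = None
    regulator_module_recall: Optional[float] = None
    regulator_module_fscore: Optional[float] = None
    regulator_module_overlap_p: Optional[float] = None
    modularity_by_module: Dict[int, float] = field(default_factory=dict)
    silhouette_by_module: Dict[int, float] = field(default_factory=dict)
    good_module_count: Optional[int] = None
    gene_coverage: Optional[float] = None

    def to_dict(self) -> Dict[str, object]:
        d = {
            "aupr": self.aupr,
            "fold_enrichment": self.fold_enrichment,
            "edge_precision": self.edge_precision,
            "edge_recall": self.edge_recall,
            "edge_fscore": self.edge_fscore,
            "per_regulator_overlap": self.per_regulator_overlap,
            "regulator_module_precision": self.regulator_module_precision,
            "regulator_module_recall": self.regulator_module_recall,
            "regulator_module_fscore": self.regulator_module_fscore,
            "regulator_module_overlap_p": self.regulator_module_overlap_p,
            "good_module_count": self.good_module_count,
            "gene_coverage": self.gene_coverage,
        }
        if self.modularity_by_module:
            d["mean_regulatory_modularity"] = float(
                np.mean(list(self.modularity_by_module.values())))
        if self.silhouette_by_module:
            d["mean_silhouette"] = float(
                np.mean(list(self.silhouette_by_module.values())))
        return d


def evaluate_networks(inferred: RegulatoryNetwork, truth: RegulatoryNetwork,
                      modules: Optional[ModuleAssignment] = None,
                      true_modules: Optional[ModuleAssignment] = None,
                      expr: Optional[ExpressionMatrix] = None,
                      ranked_edges: Optional[Sequence[Tuple[str, str, float]]]
                      = None,
                      fdr_threshold: float = 0.05) -> EvaluationReport:
    """Compute the full metric suite for one inferred network."""
    confusion = edge_confusion(inferred, truth)
    precision, recall, f = edge_fscore(confusion)
    area = None
    if ranked_edges is not None:
        area = aupr(precision_recall_curve(ranked_edges, truth))
    overlap_fraction, _ = regulator_target_overlap(inferred, truth,
                                                   fdr_threshold)
    report = EvaluationReport(
        aupr=area,
        fold_enrichment=fold_enrichment(confusion),
        edge_precision=precision, edge_recall=recall, edge_fscore=f,
        per_regulator_overlap=overlap_fraction)
    if true_modules is not None:
        tmap = regulator_module_map(truth, true_modules, fdr_threshold)
        imap = regulator_module_map(inferred, true_modules, fdr_threshold)
        if tmap.pairs():
            p, r, fs, pv = regulator_module_fscore(tmap, imap)
            report.regulator_module_precision = p
            report.regulator_module_recall = r
            report.regulator_module_fscore = fs
            report.regulator_module_overlap_p = pv
    if modules is not None:
        report.modularity_by_module = regulatory_modularity(inferred, modules)
        report.good_module_count, report.gene_coverage = module_stats(modules)
        if expr is not None and modules.n_modules >= 2:
            report.silhouette_by_module = silhouette_by_module(expr, modules)
    return report
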