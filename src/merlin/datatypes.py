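"""Data containers shared by all stages of the pipeline.

The central objects are the expression matrix (genes x samples, log scale),
the directed regulatory network (regulator -> target edges with regression
weights and optional confidences), the module assignment (a partition of the
genes), and the per-gene regulatory program (the conditional-Gaussian
parameters of one gene given its selected regulators).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: floor applied to every conditional variance to keep log-densities finite
VARIANCE_FLOOR = 1e-8


class SingularCovarianceError(np.linalg.LinAlgError):
    """Raised when the regulator covariance cannot be inverted (ridge = 0)."""


class ExpressionMatrix:
    """Genes x samples real-valued expression, log scale, NaN = missing."""

    def __init__(self, gene_ids: Sequence[str], sample_ids: Sequence[str],
                 values) -> None:
        self.gene_ids: List[str] = [str(g) for g in gene_ids]
        self.sample_ids: List[str] = [str(s) for s in sample_ids]
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise ValueError(f"duplicate gene id: {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValueError(f"duplicate sample id: {dup!r}")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    # -- construction ----------------------------------------------------
    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=list(self.gene_ids),
                            columns=list(self.sample_ids))

    # -- access ----------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def index_of(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} not in expression matrix") from None

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.index_of(gene)]

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def subset_samples(self, idx: Sequence[int]) -> "ExpressionMatrix":
        idx = list(idx)
        return ExpressionMatrix(self.gene_ids,
                                [self.sample_ids[i] for i in idx],
                                self.values[:, idx])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        rows = [self.index_of(g) for g in genes]
        return ExpressionMatrix(list(genes), self.sample_ids, self.values[rows])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"


def _first_duplicate(items: Sequence[str]) -> str:
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return ""


class RegulatorSet:
    """Ordered, duplicate-free set of candidate regulator ids."""

    def __init__(self, regulator_ids: Iterable[str]) -> None:
        ids = [str(r) for r in regulator_ids]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate regulator id: {_first_duplicate(ids)!r}")
        self.regulator_ids: List[str] = ids

    def validate_against(self, expr: ExpressionMatrix) -> None:
        missing = [r for r in self.regulator_ids if r not in expr._index]
        if missing:
            raise KeyError(f"regulators absent from expression matrix: {missing}")

    def __iter__(self) -> Iterator[str]:
        return iter(self.regulator_ids)

    def __len__(self) -> int:
        return len(self.regulator_ids)

    def __contains__(self, item: str) -> bool:
        return item in set(self.regulator_ids)

    def __repr__(self) -> str:  # pragma: no cover
        return f"RegulatorSet({len(self)} regulators)"


@dataclass(frozen=True)
class Edge:
    regulator: str
    target: str
    weight: float = 0.0
    confidence: Optional[float] = None


class RegulatoryNetwork:
    """Directed regulator -> target graph; cycles allowed, self-edges not."""

    def __init__(self, edges: Iterable[Edge] = ()) -> None:
        self._edges: Dict[Tuple[str, str], Edge] = {}
        for e in edges:
            self.add_edge(e.regulator, e.target, e.weight, e.confidence)

    def add_edge(self, regulator: str, target: str, weight: float = 0.0,
                 confidence: Optional[float] = None) -> None:
        if regulator == target:
            raise ValueError(f"self-edge not allowed: {regulator!r}")
        if confidence is not None and not (0.0 <= confidence <= 1.0):
            raise ValueError(f"confidence {confidence} outside [0, 1]")
        self._edges[(regulator, target)] = Edge(regulator, target,
                                                float(weight), confidence)

    # -- queries ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self._edges)

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        return pair in self._edges

    def __iter__(self) -> Iterator[Edge]:
        return iter(self._edges.values())

    def edge(self, regulator: str, target: str) -> Edge:
        return self._edges[(regulator, target)]

    def edge_keys(self) -> set:
        return set(self._edges)

    def targets_of(self, regulator: str) -> List[str]:
        return [t for (r, t) in self._edges if r == regulator]

    def regulators_of(self, target: str) -> List[str]:
        return [r for (r, t) in self._edges if t == target]

    def targets_map(self) -> Dict[str, List[str]]:
        out: Dict[str, List[str]] = {}
        for (r, t) in self._edges:
            out.setdefault(r, []).append(t)
        return out

    @property
    def regulators(self) -> List[str]:
        return sorted({r for (r, _) in self._edges})

    @property
    def nodes(self) -> List[str]:
        return sorted({g for pair in self._edges for g in pair})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return self._edges == other._edges

    def same_structure(self, other: "RegulatoryNetwork") -> bool:
        return self.edge_keys() == other.edge_keys()

    # -- conversion ------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        rows = [(e.regulator, e.target, e.weight, e.confidence)
                for e in sorted(self, key=lambda e: (e.regulator, e.target))]
        return pd.DataFrame(rows, columns=["regulator", "target",
                                           "weight", "confidence"])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RegulatoryNetwork":
        net = cls()
        for row in df.itertuples(index=False):
            conf = getattr(row, "confidence", None)
            if conf is not None and (isinstance(conf, float) and np.isnan(conf)):
                conf = None
            net.add_edge(str(row.regulator), str(row.target),
                         float(getattr(row, "weight", 0.0)), conf)
        return net

    def __repr__(self) -> str:  # pragma: no cover
        return f"RegulatoryNetwork({len(self)} edges)"


class ModuleAssignment:
    """Partition of genes into modules; labels are dense integers from 1.

    Labels are canonicalised so that modules are numbered in lexicographic
    order of their smallest member gene; equal partitions therefore compare
    equal regardless of how the raw labels were produced.
    """

    def __init__(self, membership: Mapping[str, int]) -> None:
        if not membership:
            raise ValueError("module assignment must cover at least one gene")
        groups: Dict[int, List[str]] = {}
        for gene, mod in membership.items():
            groups.setdefault(int(mod), []).append(str(gene))
        ordered = sorted(groups.values(), key=lambda genes: min(genes))
        self.membership: Dict[str, int] = {}
        for new_id, genes in enumerate(ordered, start=1):
            for g in genes:
                self.membership[g] = new_id
        self._modules: Dict[int, List[str]] = {
            i + 1: sorted(genes) for i, genes in enumerate(ordered)}

    @classmethod
    def from_labels(cls, genes: Sequence[str],
                    labels: Sequence[int]) -> "ModuleAssignment":
        if len(genes) != len(labels):
            raise ValueError("genes and labels differ in length")
        return cls(dict(zip(genes, labels)))

    def module_of(self, gene: str) -> int:
        try:
            return self.membership[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} has no module assignment") from None

    def modules(self) -> Dict[int, List[str]]:
        return {m: list(genes) for m, genes in self._modules.items()}

    @property
    def genes(self) -> List[str]:
        return sorted(self.membership)

    @property
    def n_modules(self) -> int:
        return len(self._modules)

    def sizes(self) -> Dict[int, int]:
        return {m: len(genes) for m, genes in self._modules.items()}

    def covers(self, genes: Iterable[str]) -> bool:
        return set(genes) <= set(self.membership)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModuleAssignment):
            return NotImplemented
        return self.membership == other.membership

    def __repr__(self) -> str:  # pragma: no cover
        return (f"ModuleAssignment({len(self.membership)} genes, "
                f"{self.n_modules} modules)")


@dataclass
class GeneRegulatoryProgram:
    """Conditional Gaussian of one target gene given its regulators."""

    target_id: str
    regulator_ids: Tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    conditional_variance: float

    def __post_init__(self) -> None:
        self.regulator_ids = tuple(self.regulator_ids)
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        if len(self.coefficients) != len(self.regulator_ids):
            raise ValueError("coefficients length != number of regulators")
        if self.conditional_variance < VARIANCE_FLOOR:
            raise ValueError(
                f"conditional variance {self.conditional_variance} below floor "
                f"{VARIANCE_FLOOR}; the floor must be applied at fit time")

    @property
    def weights(self) -> Dict[str, float]:
        return dict(zip(self.regulator_ids, self.coefficients.tolist()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneRegulatoryProgram):
            return NotImplemented
        return (self.target_id == other.target_id
                and self.regulator_ids == other.regulator_ids
                and np.array_equal(self.coefficients, other.coefficients)
                and self.intercept == other.intercept
                and self.conditional_variance == other.conditional_variance)


@dataclass
class Hyperparameters:
    """User-facing knobs of the learner.

    sparsity
        Log-odds offset of the edge prior; more negative means sparser
        networks.
    module_weight
        Coefficient on the module feature f (fraction of a regulator's
        current targets inside the candidate gene's module); 0 switches the
        module prior off and reduces the method to per-gene regression.
    cluster_threshold
        Stop height of the agglomerative module clustering, in (0, 1).
    score_tolerance
        Minimum score improvement counted as progress; ``None`` resolves to
        ``1e-4 * n_genes`` at fit time.
    """

    sparsity: float = -5.0
    module_weight: float = 4.0
    cluster_threshold: float = 0.6
    max_iterations: int = 30
    score_tolerance: Optional[float] = None
    max_regulators_per_gene: Optional[int] = 10
    ridge: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_weight < 0:
            raise ValueError("module_weight must be >= 0")
        if not (0.0 < self.cluster_threshold < 1.0):
            raise ValueError("cluster_threshold must be in (0, 1)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.score_tolerance is not None and self.score_tolerance <= 0:
            raise ValueError("score_tolerance must be > 0")
        if (self.max_regulators_per_gene is not None
                and self.max_regulators_per_gene < 0):
            raise ValueError("max_regulators_per_gene must be >= 0 or None")
        if self.ridge < 0:
            raise ValueError("ridge must be >= 0")

    def resolved_tolerance(self, n_genes: int) -> float:
        if self.score_tolerance is not None:
            return self.score_tolerance
        return 1e-4 * max(n_genes, 1)


@dataclass(frozen=True)
class EdgeFeature:
    """Fraction of a regulator's previous-iteration targets inside a module."""

    value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(f"edge feature {self.value} outside [0, 1]")
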