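"""Expression preprocessing: imputation, log transform, per-group centering
and low-change filtering."""

from __future__ import annotations

from typing import Dict, Mapping

import numpy as np

from .datatypes import ExpressionMatrix

__all__ = ["impute_missing_with_gene_mean", "log_transform_counts",
           "center_per_group", "filter_low_change"]


def impute_missing_with_gene_mean(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Replace each missing value with the gene's mean over observed samples."""
    values = expr.values.copy()
    for i, gene in enumerate(expr.gene_ids):
        row = values[i]
        missing = np.isnan(row)
        if not missing.any():
            continue
        if missing.all():
            raise ValueError(f"gene {gene!r} has no observed values; "
                             "cannot impute")
        row[missing] = row[~missing].mean()
    return ExpressionMatrix(expr.gene_ids, expr.sample_ids, values)


def log_transform_counts(expr: ExpressionMatrix,
                         pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(count + pseudocount); counts must be non-negative."""
    values = expr.values
    if np.nanmin(values) < 0:
        raise ValueError("counts must be non-negative for the log transform")
    return ExpressionMatrix(expr.gene_ids, expr.sample_ids,
                            np.log2(values + pseudocount))


def center_per_group(expr: ExpressionMatrix,
                     grouping: Mapping[str, str]) -> ExpressionMatrix:
    """Subtract, per gene, the mean within each sample group (e.g. each time
    course), leaving every gene zero-mean inside every group."""
    unassigned = [s for s in expr.sample_ids if s not in grouping]
    if unassigned:
        raise ValueError(f"samples without group assignment: {unassigned}")
    values = expr.values.copy()
    groups: Dict[str, list] = {}
    for j, s in enumerate(expr.sample_ids):
        groups.setdefault(str(grouping[s]), []).append(j)
    for cols in groups.values():
        block = values[:, cols]
        values[:, cols] = block - block.mean(axis=1, keepdims=True)
    return ExpressionMatrix(expr.gene_ids, expr.sample_ids, values)


def filter_low_change(expr: ExpressionMatrix,
                      threshold: float = 1.0) -> ExpressionMatrix:
    """Keep genes whose absolute (centered) value reaches the threshold in at
    least one sample; the boundary is inclusive."""
    keep = [g for i, g in enumerate(expr.gene_ids)
            if np.max(np.abs(expr.values[i])) >= threshold]
    if not keep:
        raise ValueError("no genes pass the change filter")
    return expr.subset_genes(keep)
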