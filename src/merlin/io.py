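"""Readers and writers for the plain-text dialects used by the tool.

Expression: TSV with a header row of sample ids and the gene id in the first
column; empty cells are missing values.  Networks: TSV with columns
(regulator, target, weight, confidence).  Modules: TSV (gene, module).
Regulator lists: one id per line with '#' comments.  Gene sets: standard GMT
(name, description, tab-separated members).  Run configurations: YAML.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .datatypes import (ExpressionMatrix, Hyperparameters, ModuleAssignment,
                        RegulatoryNetwork)

__all__ = [
    "read_expression", "write_expression", "read_regulators",
    "write_regulators", "read_network", "write_network", "read_modules",
    "write_modules", "read_gmt", "read_interactions", "write_report",
    "RunConfig", "ParseError",
]


class ParseError(ValueError):
    """Malformed input file; the message carries the file and line."""


def read_expression(path: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    genes = [str(g) for g in df.index]
    seen: Dict[str, int] = {}
    for lineno, g in enumerate(genes, start=2):  # header is line 1
        if g in seen:
            raise ParseError(f"{path}:{lineno}: duplicate gene id {g!r} "
                             f"(first seen at line {seen[g]})")
        seen[g] = lineno
    return ExpressionMatrix(genes, [str(s) for s in df.columns],
                            df.to_numpy(dtype=float))


def write_expression(expr: ExpressionMatrix, path: str) -> None:
    expr.to_dataframe().to_csv(path, sep="\t", index_label="gene")


def read_regulators(path: str) -> List[str]:
    regs: List[str] = []
    seen: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            entry = line.split("#", 1)[0].strip()
            if not entry:
                continue
            if entry in seen:
                raise ParseError(f"{path}:{lineno}: duplicate regulator "
                                 f"{entry!r} (first seen at line {seen[entry]})")
            seen[entry] = lineno
            regs.append(entry)
    return regs


def write_regulators(regulators: Sequence[str], path: str) -> None:
    with open(path, "w") as fh:
        for r in regulators:
            fh.write(f"{r}\n")


def read_network(path: str) -> RegulatoryNetwork:
    df = pd.read_csv(path, sep="\t")
    required = {"regulator", "target"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}:1: network header must contain "
                         f"{sorted(required)}; got {list(df.columns)}")
    net = RegulatoryNetwork()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        weight = float(getattr(row, "weight", 0.0) or 0.0)
        conf = getattr(row, "confidence", None)
        if conf is not None and (pd.isna(conf)):
            conf = None
        try:
            net.add_edge(str(row.regulator), str(row.target), weight,
                         None if conf is None else float(conf))
        except ValueError as exc:
            raise ParseError(f"{path}:{i}: {exc}") from exc
    return net


def write_network(net: RegulatoryNetwork, path: str) -> None:
    net.to_dataframe().to_csv(path, sep="\t", index=False)


def read_modules(path: str) -> ModuleAssignment:
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "module"} <= set(df.columns):
        raise ParseError(f"{path}:1: module header must contain "
                         f"['gene', 'module']; got {list(df.columns)}")
    membership: Dict[str, int] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        gene = str(row.gene)
        if gene in membership:
            raise ParseError(f"{path}:{i}: gene {gene!r} assigned twice")
        try:
            membership[gene] = int(row.module)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}:{i}: module id {row.module!r} "
                             "is not an integer") from exc
    return ModuleAssignment(membership)


def write_modules(modules: ModuleAssignment, path: str) -> None:
    rows = sorted(modules.membership.items())
    pd.DataFrame(rows, columns=["gene", "module"]).to_csv(path, sep="\t",
                                                          index=False)


def read_gmt(path: str) -> Dict[str, List[str]]:
    sets: Dict[str, List[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs name, "
                                 "description and at least one member")
            name = parts[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set {name!r}")
            sets[name] = [p for p in parts[2:] if p]
    return sets


def read_interactions(path: str) -> List[Tuple[str, str]]:
    pairs: List[Tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ParseError(f"{path}:{lineno}: interaction line needs "
                                 "two tab-separated ids")
            pairs.append((parts[0], parts[1]))
    return pairs


def write_report(report: Mapping[str, object], path: str) -> None:
    """Write a metric bundle as JSON (.json) or two-column TSV (otherwise)."""
    clean = {k: _jsonable(v) for k, v in report.items()}
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(clean, fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        with open(path, "w") as fh:
            fh.write("metric\tvalue\n")
            for k in sorted(clean):
                fh.write(f"{k}\t{clean[k]}\n")


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, dict):
        return {str(k): _jsonable(x) for k, x in v.items()}
    return v


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; echoed next to every output."""

    command: str
    hyper: Hyperparameters = field(default_factory=Hyperparameters)
    seed: int = 0
    inputs: Dict[str, str] = field(default_factory=dict)
    options: Dict[str, object] = field(default_factory=dict)

    def save(self, path: str) -> None:
        payload = {
            "command": self.command,
            "seed": self.seed,
            "hyperparameters": asdict(self.hyper),
            "inputs": dict(self.inputs),
            "options": {k: _jsonable(v) for k, v in self.options.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        hyper = Hyperparameters(**payload.get("hyperparameters", {}))
        return cls(command=payload.get("command", ""),
                   hyper=hyper, seed=int(payload.get("seed", 0)),
                   inputs=payload.get("inputs", {}) or {},
                   options=payload.get("options", {}) or {})
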