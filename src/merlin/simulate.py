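"""Modular ground-truth networks and steady-state knockout expression.

The generator partitions genes into modules, designates a fraction of them
as regulators, and wires each target to regulators drawn preferentially from
its own module (probability ``q``), so that ``q`` dials the regulatory
modularity of the truth.  Expression is the steady state of a linear-Gaussian
system ``x = b + Wx + noise``: one sample per gene, with that gene clamped to
a strong-depletion value and dropped from its own update, mimicking a
genome-wide single-knockout design.  The interaction matrix is rescaled to
spectral radius 0.8 so the steady state exists and is unique.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np

from .datatypes import (ExpressionMatrix, ModuleAssignment,
                        RegulatoryNetwork, RegulatorSet)

__all__ = ["GroundTruth", "generate_modular_network",
           "simulate_knockout_expression", "simulate_dataset",
           "NetworkGenerationError"]

SPECTRAL_RADIUS = 0.8


class NetworkGenerationError(RuntimeError):
    """Raised when the requested modular wiring cannot be realised."""


@dataclass
class GroundTruth:
    """A simulated truth: network, modules, regulators and system parameters."""

    network: RegulatoryNetwork
    modules: ModuleAssignment
    regulators: RegulatorSet
    basal: Dict[str, float]
    within_module_probability: float
    gene_ids: List[str]

    def weight_matrix(self) -> np.ndarray:
        """Dense W with W[target, regulator] = interaction strength."""
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        W = np.zeros((len(self.gene_ids), len(self.gene_ids)))
        for e in self.network:
            W[idx[e.target], idx[e.regulator]] = e.weight
        return W


def _gene_names(n: int) -> List[str]:
    width = max(3, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_modular_network(n_genes: int = 100,
                             regulator_fraction: float = 0.11,
                             n_modules: Optional[int] = None,
                             mean_indegree: float = 1.75,
                             q: float = 0.8,
                             seed: int = 0) -> GroundTruth:
    """Draw a modular truth network.

    Genes are split uniformly at random into ``n_modules`` modules;
    regulators are allocated to modules proportionally to module size.  Each
    target draws indegree ``1 + Poisson(mean_indegree - 1)``; each edge's
    source comes from the target's own module's regulators with probability
    ``q`` and from another module's regulators otherwise.  Signed strengths
    are uniform on +-[0.5, 1.5]; the full weight matrix is rescaled to
    spectral radius 0.8.
    """
    if not (0.0 < regulator_fraction < 1.0):
        raise ValueError("regulator_fraction must be in (0, 1)")
    if not (0.0 <= q <= 1.0):
        raise ValueError("q must be in [0, 1]")
    if n_modules is None:
        n_modules = max(2, n_genes // 10)
    if n_modules > n_genes:
        raise ValueError("n_modules cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    perm = rng.permutation(n_genes)
    membership: Dict[str, int] = {}
    module_members: Dict[int, List[str]] = {m: [] for m in range(1, n_modules + 1)}
    for pos, gi in enumerate(perm):
        m = pos % n_modules + 1
        membership[genes[gi]] = m
        module_members[m].append(genes[gi])
    n_regs = max(1, int(round(regulator_fraction * n_genes)))
    reg_alloc = _proportional_allocation(
        [len(module_members[m]) for m in range(1, n_modules + 1)], n_regs)
    regulators: List[str] = []
    module_regs: Dict[int, List[str]] = {}
    for m in range(1, n_modules + 1):
        k = reg_alloc[m - 1]
        chosen = list(rng.choice(module_members[m], size=k, replace=False))
        module_regs[m] = [str(c) for c in chosen]
        regulators.extend(module_regs[m])
    all_regs = sorted(regulators)
    net = RegulatoryNetwork()
    for g in genes:
        mod = membership[g]
        indeg = 1 + rng.poisson(max(mean_indegree - 1.0, 0.0))
        within_pool = [r for r in module_regs[mod] if r != g]
        out_pool = [r for r in all_regs
                    if membership[r] != mod and r != g]
        if not within_pool and q == 1.0:
            raise NetworkGenerationError(
                f"module {mod} has no regulator other than {g!r} but q = 1 "
                "forces within-module edges")
        # one Bernoulli(q) per edge decides within/between, then sources are
        # sampled without replacement so the realised within fraction is an
        # unbiased estimate of q whenever the pools are large enough
        n_within_wanted = int(rng.binomial(indeg, q))
        n_out_wanted = indeg - n_within_wanted
        n_within = min(n_within_wanted, len(within_pool))
        n_out = min(n_out_wanted, len(out_pool))
        if n_out < n_out_wanted:  # out pool short; fall back within
            n_within = min(n_within + (n_out_wanted - n_out),
                           len(within_pool))
        if n_within < n_within_wanted and q < 1.0:
            # within pool short; redirect the shortfall across modules
            n_out = min(n_out + (n_within_wanted - n_within), len(out_pool))
        chosen: List[str] = []
        if n_within:
            chosen.extend(str(r) for r in
                          rng.choice(within_pool, size=n_within, replace=False))
        if n_out:
            chosen.extend(str(r) for r in
                          rng.choice(out_pool, size=n_out, replace=False))
        if not chosen:
            raise NetworkGenerationError(
                f"could not wire any regulator to target {g!r}")
        for r in chosen:
            strength = rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
            net.add_edge(r, g, weight=float(strength))
    net = _rescale_spectral_radius(net, genes)
    basal = {g: float(rng.normal(0.0, 1.0)) for g in genes}
    return GroundTruth(network=net, modules=ModuleAssignment(membership),
                       regulators=RegulatorSet(all_regs), basal=basal,
                       within_module_probability=q, gene_ids=genes)


def _proportional_allocation(sizes: Sequence[int], total: int) -> List[int]:
    """Largest-remainder allocation of ``total`` regulators over modules;
    every module gets at least one when total >= number of modules."""
    sizes = list(sizes)
    n = sum(sizes)
    raw = [total * s / n for s in sizes]
    alloc = [int(x) for x in raw]
    if total >= len(sizes):
        alloc = [max(1, a) for a in alloc]
    remainders = sorted(range(len(sizes)), key=lambda i: (raw[i] - int(raw[i]),),
                        reverse=True)
    i = 0
    while sum(alloc) < total:
        alloc[remainders[i % len(sizes)]] += 1
        i += 1
    while sum(alloc) > total:
        j = max(range(len(sizes)), key=lambda i: alloc[i])
        if alloc[j] <= 1:
            break
        alloc[j] -= 1
    return [min(a, s) for a, s in zip(alloc, sizes)]


def _rescale_spectral_radius(net: RegulatoryNetwork,
                             genes: Sequence[str],
                             target_radius: float = SPECTRAL_RADIUS,
                             ) -> RegulatoryNetwork:
    idx = {g: i for i, g in enumerate(genes)}
    W = np.zeros((len(genes), len(genes)))
    for e in net:
        W[idx[e.target], idx[e.regulator]] = e.weight
    radius = float(np.max(np.abs(np.linalg.eigvals(W))))
    if radius <= target_radius or radius == 0.0:
        return net
    scale = target_radius / radius
    out = RegulatoryNetwork()
    for e in net:
        out.add_edge(e.regulator, e.target, weight=e.weight * scale)
    return out


def simulate_knockout_expression(truth: GroundTruth,
                                 noise_sd: float = 0.1,
                                 knockout_value: float = -3.0,
                                 seed: int = 0) -> ExpressionMatrix:
    """Steady-state expression for one knockout per gene.

    In the sample for gene g, the gene is clamped to ``knockout_value`` and
    removed from its own update; the remaining genes solve
    ``x = b + noise + Wx`` exactly.  Output has exactly ``n_genes`` samples,
    named ``KO_<gene>``.
    """
    genes = truth.gene_ids
    n = len(genes)
    W = truth.weight_matrix()
    radius = float(np.max(np.abs(np.linalg.eigvals(W)))) if n else 0.0
    if radius >= 1.0:
        raise ValueError(
            f"weight matrix spectral radius {radius:.3f} >= 1; "
            "the linear system has no stable steady state")
    b = np.array([truth.basal[g] for g in genes])
    rng = np.random.default_rng(seed)
    values = np.zeros((n, n))
    eye = np.eye(n - 1) if n > 1 else np.eye(0)
    for s in range(n):
        eps = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
        others = [i for i in range(n) if i != s]
        W_oo = W[np.ix_(others, others)]
        rhs = (b[others] + eps[others]
               + W[others, s] * knockout_value)
        x_o = np.linalg.solve(eye - W_oo, rhs)
        values[others, s] = x_o
        values[s, s] = knockout_value
    sample_ids = [f"KO_{g}" for g in genes]
    return ExpressionMatrix(genes, sample_ids, values)


def simulate_dataset(n_genes: int = 100, regulator_fraction: float = 0.11,
                     n_modules: Optional[int] = None,
                     mean_indegree: float = 1.75, q: float = 0.8,
                     noise_sd: float = 0.1, knockout_value: float = -3.0,
                     seed: int = 0):
    """Convenience wrapper: truth plus its knockout expression matrix."""
    truth = generate_modular_network(n_genes, regulator_fraction, n_modules,
                                     mean_indegree, q, seed=seed)
    expr = simulate_knockout_expression(truth, noise_sd=noise_sd,
                                        knockout_value=knockout_value,
                                        seed=seed + 1)
    return truth, expr
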