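"""Edge-, regulator- and module-based metrics against independent oracles."""

import itertools
import math

import numpy as np
import pytest

from merlin import (ExpressionMatrix, ModuleAssignment, RegulatoryNetwork)
from merlin.evaluation import (EdgeConfusion, aupr, bh_fdr, edge_confusion,
                               fold_enrichment, geneset_enrichment,
                               hypergeometric_tail,
                               interaction_enrichment_zscore, module_stats,
                               precision_recall_curve, regulator_module_map,
                               regulator_module_fscore,
                               regulator_target_overlap,
                               regulatory_modularity, silhouette_by_module)


def _net(*edges):
    net = RegulatoryNetwork()
    for r, t in edges:
        net.add_edge(r, t, 1.0)
    return net


class TestEdgeConfusion:
    def test_perfect_network(self):
        truth = _net(("A", "B"), ("A", "C"), ("D", "B"))
        c = edge_confusion(truth, truth)
        assert c.true_positives == c.inferred_total == c.true_total == 3

    def test_disjoint_edges_give_zero_tp(self):
        inferred = _net(("A", "B"), ("D", "C"))
        truth = _net(("A", "C"), ("D", "B"))
        assert edge_confusion(inferred, truth).true_positives == 0

    def test_matches_exhaustive_enumeration(self):
        inferred = _net(("A", "B"), ("A", "C"), ("D", "E"))
        truth = _net(("A", "B"), ("D", "B"), ("D", "C"), ("A", "E"))
        c = edge_confusion(inferred, truth)
        regs = {"A", "D"}
        nodes = ({"A", "B", "C", "D", "E"})  # common to both networks
        universe = {(r, t) for r in regs for t in nodes if r != t}
        inf = inferred.edge_keys() & universe
        tru = truth.edge_keys() & universe
        assert c.true_positives == len(inf & tru)
        assert c.inferred_total == len(inf)
        assert c.true_total == len(tru)
        assert c.universe_total == len(universe)

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError, match="universe"):
            edge_confusion(_net(("A", "B")), _net(("C", "D")))


class TestFoldEnrichment:
    def test_direct_ratio(self):
        c = EdgeConfusion(30, 100, 60, 600)
        assert fold_enrichment(c) == pytest.approx(3.0)

    def test_perfect_network_attains_maximum(self):
        truth = _net(("A", "B"), ("A", "C"))
        c = edge_confusion(truth, truth)
        assert fold_enrichment(c) == pytest.approx(
            c.universe_total / c.true_total)

    def test_background_density_gives_one(self):
        c = EdgeConfusion(10, 100, 60, 600)  # precision 0.1 = density 0.1
        assert fold_enrichment(c) == pytest.approx(1.0)

    def test_zero_denominator_errors(self):
        with pytest.raises(ValueError):
            fold_enrichment(EdgeConfusion(0, 0, 5, 10))


def _aupr_oracle(ranked, truth):
    """Brute-force AUPR: PR point at every distinct threshold, trapezoid."""
    true_edges = truth.edge_keys()
    thresholds = sorted({c for _, _, c in ranked}, reverse=True)
    pts = []
    for th in thresholds:
        called = [(r, t) for r, t, c in ranked if c >= th]
        tp = sum(1 for e in called if e in true_edges)
        pts.append((tp / len(true_edges), tp / len(called)))
    area, prev_r, prev_p = 0.0, 0.0, pts[0][1]
    for r, p in pts:
        area += (r - prev_r) * (p + prev_p) / 2
        prev_r, prev_p = r, p
    return area


class TestPrecisionRecall:
    def test_perfect_ranking_has_unit_aupr(self):
        truth = _net(("A", "B"), ("A", "C"))
        ranked = [("A", "B", 0.9), ("A", "C", 0.8), ("D", "B", 0.2),
                  ("D", "C", 0.1)]
        assert aupr(precision_recall_curve(ranked, truth)) == pytest.approx(1.0)

    def test_single_threshold_gives_prevalence(self):
        truth = _net(("A", "B"), ("A", "C"))
        ranked = [(r, t, 0.5) for r in "AD" for t in "BC"]
        area = aupr(precision_recall_curve(ranked, truth))
        assert area == pytest.approx(2 / 4)

    def test_matches_brute_force_oracle(self, rng):
        truth = _net(("A", "B"), ("A", "C"), ("D", "B"))
        pairs = [(r, t) for r in "AD" for t in "BCE"]
        for _ in range(10):
            ranked = [(r, t, float(rng.choice([0.1, 0.5, 0.9])))
                      for r, t in pairs]
            got = aupr(precision_recall_curve(ranked, truth))
            assert got == pytest.approx(_aupr_oracle(ranked, truth),
                                        abs=1e-12)

    def test_no_positives_errors(self):
        with pytest.raises(ValueError):
            precision_recall_curve([("A", "B", 1.0)], RegulatoryNetwork())


class TestHypergeometricTail:
    def test_zero_successes_gives_one(self):
        assert hypergeometric_tail(0, 5, 3, 20) == pytest.approx(1.0)

    def test_combinatorial_enumeration(self):
        # draw 2 from 4 with 2 successes: P(X >= 2) = C(2,2)/C(4,2) = 1/6
        assert hypergeometric_tail(2, 2, 2, 4) == pytest.approx(1 / 6)

    def test_total_probability(self):
        from scipy.stats import hypergeom
        p_ge = hypergeometric_tail(3, 6, 5, 15)
        p_le = hypergeom.cdf(2, 15, 6, 5)
        assert p_ge + p_le == pytest.approx(1.0)

    def test_invalid_counts_error(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(5, 2, 3, 10)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_identical_ps_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_textbook_step_up(self):
        p = [0.01, 0.02, 0.03, 0.5]
        # oracle: q_i = min over j >= i of p_(j) * m / j
        m = len(p)
        ranked = [pv * m / (i + 1) for i, pv in enumerate(sorted(p))]
        oracle = [min(ranked[i:]) for i in range(m)]
        np.testing.assert_allclose(bh_fdr(p), oracle)

    def test_order_invariance(self, rng):
        p = rng.uniform(size=12)
        perm = rng.permutation(12)
        q1 = bh_fdr(p)[perm]
        q2 = bh_fdr(p[perm])
        np.testing.assert_allclose(q1, q2)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


class TestRegulatorTargetOverlap:
    def test_identical_networks_fully_significant(self):
        net = _net(*[("A", f"T{i}") for i in range(10)],
                   *[("B", f"T{i}") for i in range(10, 20)])
        frac, table = regulator_target_overlap(net, net)
        assert frac == pytest.approx(1.0)
        assert table["significant"].all()

    def test_hand_computed_two_regulator_case(self):
        truth = _net(("A", "T1"), ("A", "T2"), ("B", "T3"),
                     ("A", "T4"), ("B", "T4"))
        inferred = _net(("A", "T1"), ("A", "T3"), ("B", "T3"), ("B", "T2"),
                        ("A", "T4"), ("B", "T4"))
        frac, table = regulator_target_overlap(inferred, truth)
        bg = {"A", "B", "T1", "T2", "T3", "T4"}
        for row in table.itertuples(index=False):
            bgr = bg - {row.regulator}
            t_true = {t for r, t in truth.edge_keys() if r == row.regulator}
            t_inf = {t for r, t in inferred.edge_keys() if r == row.regulator}
            k = len(t_true & t_inf & bgr)
            p = hypergeometric_tail(k, len(t_true & bgr), len(t_inf & bgr),
                                    len(bgr))
            assert row.p_value == pytest.approx(p)
        qs = bh_fdr(table["p_value"].to_numpy())
        np.testing.assert_allclose(table["q_value"].to_numpy(), qs)

    def test_random_targets_stay_near_null_level(self, rng):
        # uniformly random inferred targets should rarely reach FDR < 0.05
        genes = [f"T{i}" for i in range(40)]
        truth = _net(*[("R", g) for g in genes[:8]])
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            targets = rng.choice(genes, size=8, replace=False)
            inferred = _net(*[("R", t) for t in targets])
            frac, _ = regulator_target_overlap(inferred, truth)
            hits += frac > 0
        assert hits / n_rep <= 0.15


class TestRegulatorModuleMap:
    def test_concentrated_targets_are_detected(self):
        genes = [f"G{i}" for i in range(100)]
        modules = ModuleAssignment(
            {g: i // 10 + 1 for i, g in enumerate(genes)})
        net = _net(*[("G99", g) for g in genes[:10]])
        m = regulator_module_map(net, modules)
        assert ("G99", 1) in m.pairs()
        q = m.table.loc[(m.table.regulator == "G99")
                        & (m.table.module == 1), "q_value"].iloc[0]
        assert q < 1e-6

    def test_regulator_without_targets_has_no_associations(self):
        genes = [f"G{i}" for i in range(20)]
        modules = ModuleAssignment({g: i // 10 + 1
                                    for i, g in enumerate(genes)})
        m = regulator_module_map(RegulatoryNetwork(), modules)
        assert m.pairs() == set()

    def test_uniform_random_targets_controlled_at_fdr(self, rng):
        genes = [f"G{i}" for i in range(100)]
        modules = ModuleAssignment(
            {g: i // 10 + 1 for i, g in enumerate(genes)})
        false_discovery_runs = 0
        n_rep = 60
        for _ in range(n_rep):
            net = RegulatoryNetwork()
            for r in ("RA", "RB"):
                for t in rng.choice(genes, size=10, replace=False):
                    net.add_edge(r, str(t), 1.0)
            modules_all = ModuleAssignment(
                {**modules.membership, "RA": 11, "RB": 11})
            m = regulator_module_map(net, modules_all)
            false_discovery_runs += bool(m.pairs())
        assert false_discovery_runs / n_rep <= 0.15


class TestRegulatorModuleFscore:
    def _map(self, pairs):
        from merlin.evaluation import RegulatorModuleMap
        import pandas as pd
        table = pd.DataFrame([(r, m, 0, 0, 0, 0.0, 0.0) for r, m in pairs],
                             columns=["regulator", "module", "n_targets",
                                      "module_size", "overlap", "p_value",
                                      "q_value"])
        return RegulatorModuleMap(set(pairs), table)

    def test_identical_maps_are_perfect(self):
        m = self._map({("A", 1), ("B", 2)})
        p, r, f, _ = regulator_module_fscore(m, m)
        assert (p, r, f) == (1.0, 1.0, 1.0)

    def test_disjoint_maps_score_zero(self):
        p, r, f, _ = regulator_module_fscore(self._map({("A", 1)}),
                                             self._map({("B", 2)}))
        assert f == 0.0

    def test_harmonic_mean(self):
        true = self._map({("A", 1), ("B", 1), ("C", 1), ("D", 1)})
        pred = self._map({("A", 1), ("X", 1)})
        p, r, f, _ = regulator_module_fscore(true, pred)
        assert p == pytest.approx(0.5)
        assert r == pytest.approx(0.25)
        assert f == pytest.approx(1 / 3)

    def test_empty_true_map_errors(self):
        with pytest.raises(ValueError):
            regulator_module_fscore(self._map(set()), self._map({("A", 1)}))


class TestRegulatoryModularity:
    def test_within_only_sharing_is_positive(self):
        modules = ModuleAssignment({"A": 1, "B": 1, "C": 2, "D": 2})
        net = _net(("R1", "A"), ("R1", "B"), ("R2", "C"), ("R2", "D"))
        scores = regulatory_modularity(net, modules)
        assert all(v > 0 for m, v in scores.items()
                   if m in {modules.module_of("A"), modules.module_of("C")})

    def test_uniform_sharing_scores_zero(self):
        modules = ModuleAssignment({"A": 1, "B": 1, "C": 2, "D": 2})
        net = _net(*[("R", g) for g in "ABCD"])
        scores = regulatory_modularity(net, modules)
        assert all(v == pytest.approx(0.0) for v in scores.values())

    def test_hand_computation_on_four_genes(self):
        modules = ModuleAssignment({"A": 1, "B": 1, "C": 2, "D": 2})
        net = _net(("R1", "A"), ("R1", "B"), ("R2", "B"), ("R1", "C"),
                   ("R3", "D"))
        scores = regulatory_modularity(net, modules)
        s = {}
        regs = {g: {r for r, t in net.edge_keys() if t == g} for g in "ABCD"}

        def sim(a, b):
            tot = len(regs[a]) + len(regs[b])
            return 2 * len(regs[a] & regs[b]) / tot if tot else 0.0

        m1 = sim("A", "B") - np.mean([sim(a, b) for a in "AB" for b in "CD"])
        m2 = sim("C", "D") - np.mean([sim(a, b) for a in "CD" for b in "AB"])
        assert scores[modules.module_of("A")] == pytest.approx(m1)
        assert scores[modules.module_of("C")] == pytest.approx(m2)

    def test_bounded_on_random_networks(self, rng):
        genes = [f"G{i}" for i in range(12)]
        for _ in range(100):
            labels = rng.integers(1, 4, size=12)
            modules = ModuleAssignment(dict(zip(genes, labels.tolist())))
            net = RegulatoryNetwork()
            for g in genes:
                for r in rng.choice(genes, size=2, replace=False):
                    if str(r) != g:
                        net.add_edge(str(r), g, 1.0)
            scores = regulatory_modularity(net, modules)
            assert all(-1.0 <= v <= 1.0 for v in scores.values())


class TestSilhouette:
    def test_separated_blocks_score_high(self, rng):
        base1 = rng.normal(size=10)
        base2 = rng.normal(size=10)
        rows = [base1 + 0.05 * rng.normal(size=10) for _ in range(5)]
        rows += [base2 + 0.05 * rng.normal(size=10) for _ in range(5)]
        genes = [f"G{i}" for i in range(10)]
        expr = ExpressionMatrix(genes, [f"s{i}" for i in range(10)],
                                np.stack(rows))
        modules = ModuleAssignment({g: 1 if i < 5 else 2
                                    for i, g in enumerate(genes)})
        scores = silhouette_by_module(expr, modules)
        assert all(v > 0.5 for v in scores.values())

    def test_random_assignment_near_zero(self, rng):
        genes = [f"G{i}" for i in range(20)]
        expr = ExpressionMatrix(genes, [f"s{i}" for i in range(15)],
                                rng.normal(size=(20, 15)))
        means = []
        for _ in range(20):
            labels = rng.integers(1, 3, size=20)
            if len(set(labels.tolist())) < 2:
                continue
            modules = ModuleAssignment(dict(zip(genes, labels.tolist())))
            scores = silhouette_by_module(expr, modules)
            means.append(np.mean(list(scores.values())))
        assert abs(np.mean(means)) < 0.1

    def test_single_module_errors(self, rng):
        genes = ["A", "B"]
        expr = ExpressionMatrix(genes, ["s0", "s1", "s2"],
                                rng.normal(size=(2, 3)))
        with pytest.raises(ValueError):
            silhouette_by_module(expr, ModuleAssignment({"A": 1, "B": 1}))


class TestInteractionEnrichment:
    def test_null_set_scores_near_zero(self, rng):
        # a set drawn like the background draws matches the background mean
        # in expectation, so |z| stays small
        pool = [f"P{i}" for i in range(30)]
        edges = [tuple(rng.choice(pool, size=2, replace=False))
                 for _ in range(60)]
        null_set = [str(x) for x in rng.choice(pool, size=6, replace=False)]
        z = interaction_enrichment_zscore(null_set, edges, pool,
                                          n_random=200, seed=0)
        assert abs(z) < 2.0

    def test_clique_scores_above_one(self):
        pool = [f"P{i}" for i in range(20)]
        clique = pool[:5]
        edges = list(itertools.combinations(clique, 2))
        z = interaction_enrichment_zscore(clique, edges, pool,
                                          n_random=100, seed=1)
        assert z > 1.0

    def test_degenerate_draw_returns_sentinel(self):
        pool = ["A", "B", "C"]
        z = interaction_enrichment_zscore(pool, [("A", "B")], pool,
                                          n_random=10, seed=0)
        assert math.isnan(z)


class TestGenesetEnrichment:
    def test_exact_module_match_is_top_hit(self):
        genes = [f"G{i}" for i in range(20)]
        modules = ModuleAssignment({g: 1 if i < 6 else 2
                                    for i, g in enumerate(genes)})
        sets = {"exact": genes[:6], "other": genes[10:14]}
        table = geneset_enrichment(modules, sets, genes)
        top = table.iloc[0]
        assert top["term"] == "exact"
        assert top["module"] == 1
        assert top["p_value"] == pytest.approx(
            hypergeometric_tail(6, 6, 6, 20))

    def test_disjoint_module_not_significant(self):
        genes = [f"G{i}" for i in range(20)]
        modules = ModuleAssignment({g: 1 if i < 6 else 2
                                    for i, g in enumerate(genes)})
        sets = {"away": genes[14:20]}
        table = geneset_enrichment(modules, sets, genes)
        sub = table[table.module == 1]
        assert not sub["significant"].any()

    def test_hand_hypergeometric_on_toy_background(self):
        genes = [f"G{i}" for i in range(20)]
        modules = ModuleAssignment({g: 1 if i < 8 else 2
                                    for i, g in enumerate(genes)})
        sets = {"term": genes[4:10]}
        table = geneset_enrichment(modules, sets, genes)
        row = table[(table.module == 1) & (table.term == "term")].iloc[0]
        assert row["p_value"] == pytest.approx(
            hypergeometric_tail(4, 6, 8, 20))
        assert row["fold_enrichment"] == pytest.approx((4 / 8) / (6 / 20))

    def test_empty_background_errors(self):
        modules = ModuleAssignment({f"G{i}": 1 for i in range(6)})
        with pytest.raises(ValueError):
            geneset_enrichment(modules, {"s": ["G1"]}, [])


class TestModuleStats:
    def test_all_singletons(self):
        modules = ModuleAssignment({f"G{i}": i for i in range(6)})
        assert module_stats(modules) == (0, 0.0)

    def test_one_big_module(self):
        modules = ModuleAssignment({f"G{i}": 1 for i in range(8)})
        count, coverage = module_stats(modules)
        assert (count, coverage) == (1, 1.0)

    def test_mixed_sizes(self):
        membership = {}
        for i, size in enumerate((6, 5, 4, 3)):
            for j in range(size):
                membership[f"M{i}_{j}"] = i + 1
        count, coverage = module_stats(ModuleAssignment(membership))
        assert count == 2
        assert coverage == pytest.approx(11 / 18)
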