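from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ppintegrate.analyze import (
    coexpression_cutoff,
    compare_external_dataset,
    detect_central_proteins,
    hub_report,
    map_modules_to_complexes,
    overlay_coexpression,
    pairwise_coexpression,
)
from ppintegrate.datasets_io import ExpressionMatrix, InteractionDataset, ModuleSet


def expr_from(rows: dict) -> ExpressionMatrix:
    return ExpressionMatrix(values=pd.DataFrame.from_dict(rows, orient="index",
                                                          dtype=float))


class TestCentralProteins:
    def star(self, weight=1.0):
        g = nx.Graph()
        for leaf in ["l1", "l2", "l3", "l4", "l5"]:
            g.add_edge("center", leaf, weight=weight)
        return g

    def test_star_center_is_hub(self):
        g = self.star()
        # degrees: center 5, leaves 1 -> mean 10/6, threshold 10/3
        assert detect_central_proteins(g.nodes, g) == {"center"}

    def test_clique_has_no_hub(self):
        g = nx.complete_graph(["a", "b", "c", "d"])
        nx.set_edge_attributes(g, 1.0, "weight")
        assert detect_central_proteins(g.nodes, g) == set()

    def test_path_has_no_hub(self):
        g = nx.path_graph(["a", "b", "c"])
        nx.set_edge_attributes(g, 1.0, "weight")
        # degrees (1,2,1), mean 4/3, threshold 8/3 > 2
        assert detect_central_proteins(g.nodes, g) == set()

    def test_scale_invariance(self):
        hubs1 = detect_central_proteins(self.star(1.0).nodes, self.star(1.0))
        hubs2 = detect_central_proteins(self.star(7.3).nodes, self.star(7.3))
        assert hubs1 == hubs2

    def test_degree_counts_only_within_module(self):
        g = self.star()
        g.add_edge("l1", "outside", weight=1.0)
        members = ["center", "l1", "l2", "l3", "l4", "l5"]
        assert detect_central_proteins(members, g) == {"center"}

    def test_empty_module_errors(self):
        with pytest.raises(ValueError):
            detect_central_proteins([], nx.Graph())

    def test_hub_report_matches_rule(self):
        g = self.star()
        modules = ModuleSet("m", [("M1", frozenset(g.nodes))])
        (rep,) = hub_report(modules, g)
        assert rep.hubs == {"center"}
        assert rep.threshold == pytest.approx(10 / 3)
        assert rep.degrees["center"] == 5


class TestPairwiseCoexpression:
    def test_self_correlation_is_one(self):
        e = expr_from({"g": [1, 2, 3, 4]})
        assert pairwise_coexpression(e, [("g", "g")]) == {("g", "g"): 1.0}

    def test_anticorrelated(self):
        e = expr_from({"x": [1, 2, 3, 4], "y": [-1, -2, -3, -4]})
        assert pairwise_coexpression(e, [("x", "y")])[("x", "y")] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        e = expr_from({"x": [1, 2, 3, 4], "y": [1, 2, 3, 5]})
        expected = 6.5 / math.sqrt(5.0 * 8.75)  # textbook formula by hand
        assert pairwise_coexpression(e, [("x", "y")])[("x", "y")] == pytest.approx(
            expected, abs=1e-12
        )

    def test_missing_gene_absent_not_zero(self):
        e = expr_from({"x": [1, 2, 3]})
        assert pairwise_coexpression(e, [("x", "nope")]) == {}

    def test_zero_variance_absent_with_warning(self, caplog):
        e = expr_from({"x": [1, 2, 3], "flat": [5, 5, 5]})
        with caplog.at_level("WARNING"):
            out = pairwise_coexpression(e, [("x", "flat")])
        assert out == {}
        assert any("zero-variance" in r.message for r in caplog.records)

    def test_too_few_conditions_errors(self):
        e = expr_from({"x": [1, 2], "y": [3, 4]})
        with pytest.raises(ValueError, match=">=3"):
            pairwise_coexpression(e, [("x", "y")])


class TestCoexpressionCutoff:
    def test_all_equal(self):
        assert coexpression_cutoff([0.5] * 8, 0.7) == 0.5

    def test_enumerable_ten_values(self):
        values = [i / 10 for i in range(10)]  # 0.0 .. 0.9
        assert coexpression_cutoff(values, 0.7) == pytest.approx(0.3)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            coexpression_cutoff([], 0.7)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5])
    def test_fraction_bounds(self, bad):
        with pytest.raises(ValueError):
            coexpression_cutoff([0.5], bad)

    @pytest.mark.parametrize("seed", range(5))
    def test_postcondition_by_direct_counting(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(-1, 1, size=int(rng.integers(5, 200))).tolist()
        frac = float(rng.uniform(0.2, 0.9))
        c = coexpression_cutoff(values, frac)
        need = math.ceil(frac * len(values) - 1e-9)
        assert sum(1 for v in values if v >= c) >= need
        # c is the largest such value: any strictly larger input fails the count
        above = sorted(v for v in values if v > c)
        if above:
            assert sum(1 for v in values if v >= above[0]) < need


class TestOverlayCoexpression:
    def test_perfectly_correlated_pair(self):
        e = expr_from({"a": [1, 2, 3, 4], "b": [2, 4, 6, 8]})
        modules = ModuleSet("m", [("M1", frozenset({"a", "b"}))])
        rows = overlay_coexpression(modules, e, cutoff=0.5)
        assert rows == [("M1", "a", "b", pytest.approx(1.0))]

    def test_uncorrelated_noise_near_one_cutoff(self):
        rng = np.random.default_rng(0)
        e = expr_from({f"g{i}": rng.normal(size=30).tolist() for i in range(6)})
        modules = ModuleSet("m", [("M1", frozenset(e.genes))])
        assert overlay_coexpression(modules, e, cutoff=0.95) == []

    def test_nonfinite_cutoff_errors(self):
        e = expr_from({"a": [1, 2, 3]})
        with pytest.raises(ValueError):
            overlay_coexpression(ModuleSet("m", [("M1", frozenset({"a"}))]), e,
                                 cutoff=float("inf"))

    def test_benchmark_complex_linked_fraction(self, small_benchmark):
        datasets, expr, _, truth = small_benchmark
        pairs = sorted(truth.true_pairs)
        corr = pairwise_coexpression(expr, pairs)
        cutoff = coexpression_cutoff(list(corr.values()), 0.7)
        rows = overlay_coexpression(truth.complexes, expr, cutoff)
        # by construction of the cutoff, >= 70% of co-complex pairs exceed it
        # (strictly-above vs >= differs only at ties, absent in continuous data)
        assert len(rows) >= 0.7 * len(corr) - len(truth.complexes.modules)


class TestMapModulesToComplexes:
    def test_exact_match(self):
        modules = ModuleSet("m", [("M1", frozenset({"a", "b", "c"}))])
        complexes = ModuleSet("c", [("C1", frozenset({"a", "b", "c"}))])
        (row,) = map_modules_to_complexes(modules, complexes)
        assert (row.best_module, row.coverage, row.split) == ("M1", 1.0, 1)

    def test_even_split_tie_breaks_to_smaller_label(self):
        modules = ModuleSet("m", [("M1", frozenset({"a", "b"})), ("M2", frozenset({"c", "d"}))])
        complexes = ModuleSet("c", [("C1", frozenset({"a", "b", "c", "d"}))])
        (row,) = map_modules_to_complexes(modules, complexes)
        assert (row.best_module, row.coverage, row.split) == ("M1", 0.5, 2)

    def test_unmapped_complex(self):
        modules = ModuleSet("m", [("M1", frozenset({"a"}))])
        complexes = ModuleSet("c", [("C1", frozenset({"z"}))])
        (row,) = map_modules_to_complexes(modules, complexes)
        assert (row.best_module, row.coverage, row.split) == (None, 0.0, 0)


def _ds(name, pairs, **kw):
    return InteractionDataset.from_pairs(name, pairs, **kw)


class TestCompareExternalDataset:
    def test_external_subset_of_used(self):
        used = [_ds("u", [("a", "b"), ("c", "d")])]
        external = _ds("ext", [("a", "b")])
        modules = ModuleSet("m", [("M1", frozenset({"a", "b"}))])
        rep = compare_external_dataset(external, used, modules)
        assert rep.fraction_in_datasets == 1.0

    def test_disjoint_everything(self):
        used = [_ds("u", [("a", "b")])]
        external = _ds("ext", [("a", "c")])  # both endpoints must be annotated
        modules = ModuleSet("m", [("M1", frozenset({"a", "b", "c"}))])
        # a-c not in datasets; both in M1 though -> use a module-less variant
        modules2 = ModuleSet("m", [("M1", frozenset({"a"})), ("M2", frozenset({"c"}))])
        rep = compare_external_dataset(external, used, modules2)
        assert rep.n_annotated == 1
        assert rep.fraction_in_datasets == 0.0
        assert rep.fraction_in_datasets_or_comodular == 0.0
        assert rep.fraction_in_datasets_or_comodular_or_hub == 0.0

    def test_constructed_cumulative_fractions(self):
        # 10 external pairs, all annotated: 3 in used datasets, 2 more
        # co-modular, 1 more touching a hub, 4 with nothing
        used = [_ds("u", [("a1", "b1"), ("a2", "b2"), ("a3", "b3"),
                          ("z1", "z2"), ("z3", "z4"), ("z5", "z6"),
                          ("h1", "z7"), ("q1", "q2"), ("q3", "q4"),
                          ("q5", "q6"), ("q7", "q8")])]
        modules = ModuleSet("m", [
            ("M1", frozenset({"z1", "z3"})),
            ("M2", frozenset({"z5", "h1"})),
        ])
        hubs = {"h1"}
        external = _ds("ext", [
            ("a1", "b1"), ("a2", "b2"), ("a3", "b3"),  # in datasets
            ("z1", "z3"),                              # co-modular (M1)
            ("h1", "z5"),                              # co-modular (M2)
            ("h1", "q1"),                              # hub-touching only
            ("q1", "q3"), ("q3", "q5"), ("q5", "q7"), ("q2", "q4"),  # nothing
        ])
        rep = compare_external_dataset(external, used, modules, hubs)
        assert rep.n_annotated == 10
        assert rep.fraction_in_datasets == pytest.approx(0.3)
        assert rep.fraction_in_datasets_or_comodular == pytest.approx(0.5)
        assert rep.fraction_in_datasets_or_comodular_or_hub == pytest.approx(0.6)

    def test_cumulative_monotonicity(self):
        rng = np.random.default_rng(1)
        proteins = [f"p{i}" for i in range(20)]
        def rand_pairs(k):
            out = set()
            while len(out) < k:
                a, b = rng.choice(proteins, size=2, replace=False)
                out.add((min(a, b), max(a, b)))
            return sorted(out)
        used = [_ds("u", rand_pairs(15))]
        external = _ds("e", rand_pairs(12))
        modules = ModuleSet("m", [("M1", frozenset(proteins[:8])),
                                  ("M2", frozenset(proteins[8:16]))])
        rep = compare_external_dataset(external, used, modules, {proteins[0]})
        assert (rep.n_in_datasets <= rep.n_in_datasets_or_comodular
                <= rep.n_in_datasets_or_comodular_or_hub <= rep.n_annotated)

    def test_mean_coexpression_reported(self):
        e = expr_from({"a": [1, 2, 3, 4], "b": [2, 4, 6, 8]})
        used = [_ds("u", [("a", "b")])]
        external = _ds("ext", [("a", "b")])
        modules = ModuleSet("m", [("M1", frozenset({"a", "b"}))])
        rep = compare_external_dataset(external, used, modules, expr=e)
        assert rep.mean_coexpression == pytest.approx(1.0)
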