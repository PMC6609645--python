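"""Shadow-probe selection, discretization, reducts, rules and voting."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metmap import ruleclass as rc
from metmap.errors import MetmapError


def toy_table():
    """Hand-worked 6-object decision table (2 attributes, 2 classes).

    Objects/levels:
      o1 A=high B=low  -> T2D
      o2 A=high B=low  -> T2D
      o3 A=high B=high -> T2D
      o4 A=low  B=low  -> nonDM
      o5 A=low  B=high -> nonDM
      o6 A=high B=high -> nonDM   (conflicts with o3)

    The unique minimal reduct is {A, B} (A alone cannot discern o1/o6,
    B alone cannot discern o1/o4).  Hand counts over the attribute set {A}
    (used directly as a rule template, not a reduct):
      (A=high -> T2D):  matches o1,o2,o3,o6 (4), support 3, accuracy 3/4,
                        coverage 3/3.
      (A=low -> nonDM): matches o4,o5 (2), support 2, accuracy 1,
                        coverage 2/3.
      (A=high -> nonDM): support 1, accuracy 1/4, coverage 1/3.
    """
    values = pd.DataFrame({
        "A": ["high", "high", "high", "low", "low", "high"],
        "B": ["low", "low", "high", "low", "high", "high"],
    }, index=[f"o{i}" for i in range(1, 7)])
    decision = pd.Series(["T2D", "T2D", "T2D", "nonDM", "nonDM", "nonDM"],
                         index=values.index)
    return rc.DecisionTable(values=values, decision=decision,
                            cut_points={"A": (0.5,), "B": (0.5,)})


class TestSelectAllRelevant:
    def test_label_copy_confirmed(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 20 + [1] * 20)
        X = pd.DataFrame(rng.standard_normal((40, 5)),
                         columns=[f"f{i}" for i in range(5)])
        X["label_copy"] = y.astype(float)
        res = rc.select_all_relevant(X, y, max_iter=15, n_estimators=100, seed=0)
        assert "label_copy" in res.confirmed

    def test_planted_features_found_noise_bounded(self):
        tps, fps = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = np.array([0] * 30 + [1] * 13)
            X = rng.standard_normal((43, 100))
            X[30:, :5] += 1.5
            X = pd.DataFrame(X, columns=[f"f{i}" for i in range(100)])
            res = rc.select_all_relevant(X, y, max_iter=50, n_estimators=200,
                                         seed=seed)
            tp = sum(1 for f in res.confirmed if int(f[1:]) < 5)
            tps.append(tp)
            fps.append(len(res.confirmed) - tp)
        assert np.mean(tps) >= 4
        assert np.mean(fps) <= 5

    def test_all_noise_confirms_almost_nothing(self):
        rng = np.random.default_rng(1)
        y = np.array([0] * 20 + [1] * 20)
        X = pd.DataFrame(rng.standard_normal((40, 50)))
        X.columns = [f"f{i}" for i in range(50)]
        res = rc.select_all_relevant(X, y, max_iter=25, n_estimators=100, seed=1)
        assert len(res.confirmed) <= 3

    def test_guard_rails(self):
        X = pd.DataFrame({"a": [1.0] * 12})
        with pytest.raises(MetmapError):
            rc.select_all_relevant(X, [0, 1] * 6)


class TestDiscretize:
    def test_equal_frequency_hand_example(self):
        X = pd.DataFrame({"v": np.arange(1.0, 10.0)})
        table = rc.discretize(X, ["c"] * 9, n_bins=3)
        assert list(table.values["v"]) == ["low"] * 3 + ["average"] * 3 + \
            ["high"] * 3
        c1, c2 = table.cut_points["v"]
        assert 3 <= c1 < 4 and 6 <= c2 < 7

    def test_test_time_application_beyond_range(self):
        train = pd.DataFrame({"v": np.arange(1.0, 10.0)})
        table = rc.discretize(train, ["c"] * 9, n_bins=3)
        test = pd.DataFrame({"v": [100.0, -50.0]})
        applied = rc.discretize(test, ["c", "c"], cut_points=table.cut_points)
        assert list(applied.values["v"]) == ["high", "low"]

    def test_single_bin_uninformative(self):
        X = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        table = rc.discretize(X, list("abc"), n_bins=1)
        assert set(table.values["v"]) == {"average"}

    def test_few_distinct_values_fall_back(self):
        X = pd.DataFrame({"v": [1.0, 1.0, 1.0, 2.0, 2.0, 2.0]})
        with pytest.warns(UserWarning, match="falling back"):
            table = rc.discretize(X, ["c"] * 6, n_bins=3)
        assert set(table.values["v"]) == {"low", "high"}


class TestComputeReducts:
    def test_single_separating_attribute(self):
        values = pd.DataFrame({"A": ["low", "high"] * 3,
                               "B": ["low", "low", "high", "high", "low", "high"]})
        dec = pd.Series(["x", "y"] * 3)
        table = rc.DecisionTable(values, dec, {})
        assert rc.compute_reducts(table) == [("A",)]

    def test_xor_needs_both_attributes(self):
        values = pd.DataFrame({"A": ["low", "low", "high", "high"],
                               "B": ["low", "high", "low", "high"]})
        dec = pd.Series(["x", "y", "y", "x"])
        table = rc.DecisionTable(values, dec, {})
        assert rc.compute_reducts(table) == [("A", "B")]
        assert rc.compute_reducts(table, strategy="exhaustive") == [("A", "B")]

    def test_exhaustive_enumeration_contains_greedy(self):
        """Every greedy reduct is irreducible, hence one of the minimal
        discerning subsets found by exhaustive enumeration; when the minimal
        reduct is unique the two strategies agree exactly."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            values = pd.DataFrame(
                rng.choice(["low", "average", "high"], size=(8, 5)),
                columns=list("ABCDE"))
            dec = pd.Series(rng.choice(["x", "y"], size=8))
            table = rc.DecisionTable(values, dec, {})
            greedy = rc.compute_reducts(table)[0]
            all_minimal = rc.compute_reducts(table, strategy="exhaustive")
            assert frozenset(greedy) in {frozenset(r) for r in all_minimal}
            if len(all_minimal) == 1:
                assert set(greedy) == set(all_minimal[0])

    def test_greedy_reduct_irreducible(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            values = pd.DataFrame(
                rng.choice(["low", "average", "high"], size=(10, 6)),
                columns=list("ABCDEF"))
            dec = pd.Series(rng.choice(["x", "y"], size=10))
            table = rc.DecisionTable(values, dec, {})
            reduct = rc.compute_reducts(table)[0]
            pairs = rc._discernibility_pairs(table)
            cols = {c: i for i, c in enumerate(table.attributes)}
            full = frozenset(cols[a] for a in reduct)
            if pairs:
                assert rc._covers(full, pairs)
                for a in reduct:
                    assert not rc._covers(full - {cols[a]}, pairs) or \
                        len(full) == 1


class TestInduceRules:
    def test_hand_counts_on_toy_table(self):
        table = toy_table()
        rules = rc.induce_rules(table, [("A",)])
        by_key = {(tuple(sorted(r.antecedent)), r.decision_class): r
                  for r in rules}
        high_t2d = by_key[((("A", "high"),), "T2D")]
        assert (high_t2d.support, high_t2d.accuracy, high_t2d.coverage) == \
            (3, 0.75, 1.0)
        low_non = by_key[((("A", "low"),), "nonDM")]
        assert (low_non.support, low_non.accuracy) == (2, 1.0)
        assert low_non.coverage == pytest.approx(2 / 3)
        high_non = by_key[((("A", "high"),), "nonDM")]
        assert (high_non.support, high_non.accuracy) == (1, 0.25)

    def test_duplicated_object_increments_support(self):
        table = toy_table()
        dup_values = pd.concat([table.values, table.values.iloc[[0]]])
        dup_values.index = list(table.values.index) + ["o1b"]
        dup_dec = pd.concat([table.decision,
                             pd.Series(["T2D"], index=["o1b"])])
        dup = rc.DecisionTable(dup_values, dup_dec, table.cut_points)
        rules = rc.induce_rules(dup, [("A", "B")])
        r = next(r for r in rules
                 if r.antecedent == frozenset({("A", "high"), ("B", "low")})
                 and r.decision_class == "T2D")
        assert r.support == 3 and r.accuracy == 1.0

    def test_statistics_reproducible_by_recounting(self):
        table = toy_table()
        rules = rc.induce_rules(table, rc.compute_reducts(table))
        rows = table.values.to_dict("records")
        dec = list(table.decision)
        sizes = table.decision.value_counts().to_dict()
        for r in rules:
            match = [i for i, row in enumerate(rows)
                     if all(row[a] == lv for a, lv in r.antecedent)]
            support = sum(1 for i in match if dec[i] == r.decision_class)
            assert r.support == support
            assert r.accuracy == pytest.approx(support / len(match))
            assert r.coverage == pytest.approx(support / sizes[r.decision_class])


class TestClassify:
    def test_support_weighted_tally(self):
        rules = [
            rc.Rule(frozenset({("A", "high")}), "T2D", 3, 1.0, 1.0),
            rc.Rule(frozenset({("B", "low")}), "T2D", 2, 1.0, 1.0),
            rc.Rule(frozenset({("C", "low")}), "nonDM", 4, 1.0, 1.0),
        ]
        res = rc.classify(rules, {"A": "high", "B": "low", "C": "low"})
        assert res.predicted == "T2D"
        assert res.votes == {"T2D": 5.0, "nonDM": 4.0}

    def test_no_rule_falls_back_to_majority(self):
        rules = [rc.Rule(frozenset({("A", "high")}), "T2D", 1, 1.0, 1.0)]
        res = rc.classify(rules, {"A": "low"}, default_class="nonDM")
        assert res.predicted == "nonDM" and res.flag == "no_rule"

    def test_tie_breaks_lexicographically(self):
        rules = [
            rc.Rule(frozenset({("A", "high")}), "T2D", 2, 1.0, 1.0),
            rc.Rule(frozenset({("A", "high")}), "nonDM", 2, 1.0, 1.0),
        ]
        res = rc.classify(rules, {"A": "high"})
        # "T2D" < "nonDM" in lexicographic (codepoint) order
        assert res.predicted == "T2D" and res.flag == "tie"


class TestCrossvalidate:
    def test_separable_data_perfect(self):
        y = ["a"] * 10 + ["b"] * 10
        X = pd.DataFrame({"f": [0.0] * 10 + [10.0] * 10})
        res = rc.crossvalidate(X, y, k=5, seed=0, n_bins=2)
        assert res["accuracy"] == 1.0

    def test_small_class_shrinks_k(self):
        y = ["a"] * 12 + ["b"] * 4
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"f": rng.standard_normal(16),
                          "g": rng.standard_normal(16)})
        with pytest.warns(UserWarning, match="reduced"):
            res = rc.crossvalidate(X, y, k=10, seed=0)
        assert res["k"] == 4

    def test_permuted_labels_near_majority_rate(self):
        rng = np.random.default_rng(2)
        accs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            y = np.array(["n"] * 30 + ["t"] * 13)
            X = r.standard_normal((43, 20))
            X[30:, :5] += 2.0
            X = pd.DataFrame(X, columns=[f"f{i}" for i in range(20)])
            yp = rng.permutation(y)
            accs.append(rc.crossvalidate(X, yp, k=10, seed=seed)["accuracy"])
        assert abs(np.mean(accs) - 30 / 43) < 0.1


class TestRuleNetwork:
    def test_triangle_from_single_rule(self):
        rules = [rc.Rule(frozenset({("A", "high"), ("B", "low"), ("C", "low")}),
                         "T2D", 5, 1.0, 1.0)]
        nets = rc.build_rule_network(rules)
        g = nets["T2D"]
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3
        assert all(d["weight"] == 5 for _, _, d in g.edges(data=True))

    def test_shared_pair_weights_add(self):
        pair = {("A", "high"), ("B", "low")}
        rules = [rc.Rule(frozenset(pair), "T2D", 2, 1.0, 1.0),
                 rc.Rule(frozenset(pair | {("C", "low")}), "T2D", 3, 1.0, 1.0)]
        g = rc.build_rule_network(rules)["T2D"]
        assert g.edges["A=high", "B=low"]["weight"] == 5

    def test_min_support_can_empty_network(self):
        rules = [rc.Rule(frozenset({("A", "high"), ("B", "low")}),
                         "T2D", 2, 1.0, 1.0)]
        nets = rc.build_rule_network(rules, min_support=10)
        assert nets == {}
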