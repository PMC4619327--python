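"""Subtree activity, initiating-cell inference, HH scores, dose model."""

import itertools

import numpy as np
import pytest

from wntlineage.lineage_model import CellRecord, LineageTree, parse_name
from wntlineage.reporter_activity import (
    GeneHHScore,
    activity_sister_asymmetry,
    activity_table,
    ancestor_dose_model,
    compare_regulation_classes,
    gene_hh_score,
    hh_fraction,
    infer_initiating_cells,
    subtree_activity,
)
from wntlineage.synthetic_data import SynthParams, make_tree, simulate_reporter


class TestSubtreeActivity:
    def test_leaf_is_own_blot(self, tiny_tree):
        assert subtree_activity(tiny_tree, "ABaa") == 7.0 - 3.0  # blot 4.0

    def test_small_subtree_mean(self, tiny_tree):
        # ABap(8) + ABapa(2) + ABapp(6) -> mean 16/3
        assert subtree_activity(tiny_tree, "ABap") == pytest.approx(16 / 3)

    def test_matches_brute_force_enumeration(self):
        skel = make_tree(200, seed=8, embryo_id="e")
        tree, _ = simulate_reporter(skel, SynthParams(stage=200), seed=9)
        tab = activity_table(tree).set_index("cell")
        rng = np.random.default_rng(0)
        cells = rng.choice(sorted(str(c) for c in tree.cells), 25, replace=False)
        for c in cells:
            brute = np.mean([tree[n].blot for n in tree.subtree(c)])
            assert subtree_activity(tree, c) == pytest.approx(brute)
            assert tab.loc[c, "activity"] == pytest.approx(brute)

    def test_recursive_identity(self, tiny_tree):
        # activity(c)*size(c) = blot(c) + sum_d activity(d)*size(d)
        tab = activity_table(tiny_tree).set_index("cell")
        for cell in tiny_tree.cells:
            ds = tiny_tree.daughters(cell)
            lhs = tab.loc[str(cell), "activity"] * tab.loc[str(cell), "n_cells"]
            rhs = tiny_tree[cell].blot + sum(
                tab.loc[str(d), "activity"] * tab.loc[str(d), "n_cells"] for d in ds
            )
            assert lhs == pytest.approx(rhs)


class TestActivityAsymmetry:
    def test_symmetric_subtrees_zero(self):
        t = LineageTree(
            [CellRecord("ABa", blot=1.0, end_time=1.0),
             CellRecord("ABaa", blot=5.0), CellRecord("ABap", blot=5.0)]
        )
        assert activity_sister_asymmetry(t, t.divisions()[0]) == 0.0

    def test_posterior_expression_positive(self, tiny_tree):
        div = [d for d in tiny_tree.divisions() if str(d.parent) == "ABa"][0]
        # posterior subtree mean 16/3 vs anterior 4
        assert activity_sister_asymmetry(tiny_tree, div) == pytest.approx(16 / 3 - 4)

    def test_asymmetry_larger_after_sys1_high_parent(self):
        # POPTOP-like activation requires two consecutive High divisions, so
        # activity asymmetry concentrates in divisions of High parents
        params = SynthParams(mode="stable-lagged", sigma=10.0,
                             lr_dv_fraction=0.0, activation_depth=2)
        skel = make_tree(350, seed=31, embryo_id="e")
        tree, truth = simulate_reporter(skel, params, seed=32, reporter="POPTOP")
        high = truth.set_index("cell")["high"]
        by_parent = {True: [], False: []}
        for div in tree.divisions():
            a = activity_sister_asymmetry(tree, div)
            h = high.get(str(div.parent))
            if a is not None and h in ("H", "L"):
                by_parent[h == "H"].append(a)
        assert np.mean(by_parent[True]) > np.mean(by_parent[False]) + 5.0


def _expression_tree() -> LineageTree:
    """ABpl's 'pp' grandchild subtree expresses; everything else dark."""
    recs = []
    names_on = {"ABplpp", "ABplppa", "ABplppp"}
    cells = ["ABpl", "ABpla", "ABplp", "ABplaa", "ABplap", "ABplpa", "ABplpp",
             "ABplppa", "ABplppp", "ABplpaa", "ABplpap"]
    birth = {"ABpl": 0.0, "ABpla": 20.0, "ABplp": 20.0}
    for c in cells:
        b = birth.get(c, 40.0 if len(c) == 6 else 60.0)
        recs.append(
            CellRecord(c, birth_time=b, end_time=b + 20.0,
                       blot=100.0 if c in names_on else 0.0)
        )
    return LineageTree(recs, embryo_id="expr", reporter="POPTOP")


class TestInitiatingCells:
    def test_zero_lag_returns_clade_root(self):
        t = _expression_tree()
        assert [str(c) for c in infer_initiating_cells(t, 50.0, lag_minutes=0.0)] \
            == ["ABplpp"]

    def test_lag_walks_to_parent(self):
        t = _expression_tree()
        # ABplpp born at 40; lag 30 -> ancestor alive at t=10 is ABpl...
        # lag 15 -> alive at 25 is ABplp (its parent)
        assert [str(c) for c in infer_initiating_cells(t, 50.0, lag_minutes=15.0)] \
            == ["ABplp"]
        assert [str(c) for c in infer_initiating_cells(t, 50.0, lag_minutes=30.0)] \
            == ["ABpl"]

    def test_threshold_excluding_all_gives_empty(self):
        t = _expression_tree()
        assert infer_initiating_cells(t, 1e6) == []

    def test_idempotent_on_inferred_clade(self):
        t = _expression_tree()
        (root,) = infer_initiating_cells(t, 50.0, lag_minutes=0.0)
        sub = LineageTree(
            [t[c] for c in t.subtree(root)], embryo_id="sub"
        )
        assert infer_initiating_cells(sub, 50.0, lag_minutes=0.0) == [root]

    def test_recovers_planted_initiators(self):
        # expression level 5x noise SD: planted initiating cells recovered
        params = SynthParams(mode="stable-lagged", sigma=40.0, expr_level=200.0,
                             lr_dv_fraction=0.0)
        hits = total = 0
        for i in range(5):
            skel = make_tree(350, seed=50 + i, embryo_id=f"e{i}")
            tree, truth = simulate_reporter(skel, params, seed=60 + i,
                                            reporter="POPTOP")
            true_init = set(truth.loc[truth.initiating, "cell"])
            inferred = {str(c) for c in
                        infer_initiating_cells(tree, 100.0, lag_minutes=30.0)}
            hits += len(true_init & inferred)
            total += len(true_init)
        assert total > 30
        assert hits / total >= 0.9


class TestHHFraction:
    labels = {"ABplpp": "HH", "ABprpp": "HH", "ABplap": "LH", "Epp": "HH",
              "ABarpp": "HH", "Cpp": "LH"}

    def test_all_hh(self):
        res = hh_fraction(["ABplpp", "ABprpp"], self.labels)
        assert res.fraction == 1.0

    def test_counting_matches_brute_force(self):
        cells = list(self.labels) + ["MSap"]  # MSap unlabeled
        res = hh_fraction(cells, self.labels)
        brute = sum(v == "HH" for v in self.labels.values()) / len(self.labels)
        assert res.fraction == pytest.approx(brute)
        assert res.n_excluded == 1

    def test_order_invariant_and_bounded(self):
        cells = list(self.labels)
        f1 = hh_fraction(cells, self.labels).fraction
        f2 = hh_fraction(list(reversed(cells)), self.labels).fraction
        assert f1 == f2 and 0.0 <= f1 <= 1.0


class TestAncestorDoseModel:
    def test_constant_activity_zero_coefficient(self):
        res = ancestor_dose_model([5.0] * 30, list(range(30)),
                                  [i % 7 for i in range(30)])
        assert res["hh_coef"] == pytest.approx(0.0, abs=1e-10)

    def test_recovers_planted_hh_effect(self):
        rng = np.random.default_rng(4)
        n_hh = rng.integers(0, 4, 500)
        n_high = n_hh + rng.integers(0, 4, 500)
        act = 2.0 + 3.5 * n_hh + 0.5 * n_high + rng.normal(0, 1, 500)
        res = ancestor_dose_model(act, n_hh, n_high)
        assert res["hh_coef"] == pytest.approx(3.5, abs=0.3)
        assert res["hh_p"] < 1e-15

    def test_permuted_covariate_p_uniform(self):
        rng = np.random.default_rng(7)
        n_high = rng.integers(0, 6, 200)
        act = 1.0 + 0.5 * n_high + rng.normal(0, 1, 200)
        ps = []
        for _ in range(200):
            n_hh = rng.permutation(rng.integers(0, 3, 200))
            ps.append(ancestor_dose_model(act, n_hh, n_high)["hh_p"])
        # null p-values roughly uniform: ~5% below 0.05
        assert 0.0 <= np.mean(np.array(ps) < 0.05) <= 0.12


def _exact_ranksum_p(a, b):
    """Two-sided rank-sum p by exhaustive enumeration of group assignments."""
    pooled = list(a) + list(b)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    obs = sum(ranks[v] for v in a)
    n = len(a)
    stats = [
        sum(sorted(ranks[pooled[i]] for i in comb))
        for comb in itertools.combinations(range(len(pooled)), n)
    ]
    mean = np.mean(stats)
    extreme = sum(abs(s - mean) >= abs(obs - mean) - 1e-9 for s in stats)
    return extreme / len(stats)


class TestRegulationClasses:
    def _scores(self, vals, cls):
        return [
            GeneHHScore(f"g{i}-{cls}", (), v, cls) for i, v in enumerate(vals)
        ]

    def test_identical_distributions_p_one(self):
        genes = self._scores([0.2, 0.5, 0.8], "activated") + \
            self._scores([0.2, 0.5, 0.8], "repressed")
        assert compare_regulation_classes(genes)["p"] == 1.0

    def test_exact_p_matches_enumeration(self):
        # disjoint score ranges, n=8 vs 7: exact rank-sum from enumeration
        a = [0.9, 0.95, 0.8, 0.85, 0.7, 0.75, 0.65, 0.6]
        b = [0.1, 0.2, 0.15, 0.3, 0.25, 0.05, 0.35]
        genes = self._scores(a, "activated") + self._scores(b, "repressed")
        res = compare_regulation_classes(genes)
        assert res["p"] == pytest.approx(_exact_ranksum_p(a, b), rel=1e-9)
        assert res["median_a"] > res["median_b"]

    def test_null_p_roughly_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(300):
            genes = self._scores(rng.uniform(0, 1, 8), "activated") + \
                self._scores(rng.uniform(0, 1, 7), "repressed")
            ps.append(compare_regulation_classes(genes)["p"])
        assert 0.01 <= np.mean(np.array(ps) < 0.05) <= 0.10

    def test_tiny_class_rejected(self):
        genes = self._scores([0.5], "activated") + self._scores([0.1, 0.2], "repressed")
        with pytest.raises(ValueError):
            compare_regulation_classes(genes)


def test_gene_hh_score_construction():
    labels = {"ABplpp": "HH", "ABplap": "LH"}
    gs = gene_hh_score("nhr-67", ["ABplpp", "ABplap"], labels, "activated")
    assert gs.hh_score == 0.5
    with pytest.raises(ValueError, match="regulation class"):
        GeneHHScore("x", (), 0.5, "bogus")
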