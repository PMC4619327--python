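"""Sister asymmetry, significance testing with FDR, polarity classes."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from wntlineage.asymmetry import (
    PolarityThresholds,
    classify_division,
    collect_asymmetries,
    compare_groups,
    derive_thresholds,
    division_table,
    orientation_deviation,
    sister_asymmetry,
)
from wntlineage.asymmetry import test_asymmetry as run_asymmetry_test
from wntlineage.lineage_model import CellRecord, LineageTree
from wntlineage.synthetic_data import SynthParams, simulate_dataset, stage_time


def _pair_tree(anterior: float, posterior: float) -> LineageTree:
    return LineageTree(
        [
            CellRecord("ABa", blot=0.0, end_time=5.0),
            CellRecord("ABaa", blot=anterior),
            CellRecord("ABap", blot=posterior),
        ],
        embryo_id="p",
    )


class TestSisterAsymmetry:
    def test_posterior_minus_anterior(self):
        t = _pair_tree(2.0, 5.0)
        assert sister_asymmetry(t, t.divisions()[0]) == pytest.approx(3.0)

    def test_equal_daughters_zero(self):
        t = _pair_tree(4.0, 4.0)
        assert sister_asymmetry(t, t.divisions()[0]) == 0.0

    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_antisymmetric_under_daughter_swap(self, a, p):
        fwd = sister_asymmetry(_pair_tree(a, p), _pair_tree(a, p).divisions()[0])
        rev = sister_asymmetry(_pair_tree(p, a), _pair_tree(p, a).divisions()[0])
        assert fwd == -rev

    def test_missing_daughter_skipped(self):
        t = LineageTree(
            [CellRecord("ABa", blot=0.0), CellRecord("ABaa", blot=1.0),
             CellRecord("ABap", blot=float("nan"))]
        )
        assert sister_asymmetry(t, t.divisions()[0]) is None

    def test_noise_free_asymmetry_is_exact(self, clean_group):
        trees, _, params = clean_group
        asyms = collect_asymmetries(trees)
        # Low-parent divisions: (mu+a) - (mu-a/2) = 1.5a; High-parent: a(g+0.5)
        lo = 1.5 * params.alpha
        hi = params.alpha * (params.gamma + 0.5)
        assert set(np.round(asyms["asym"], 6)) <= {round(lo, 6), round(hi, 6)}

    def test_recovers_planted_boost(self, wt_group):
        trees, _ = wt_group
        asyms = collect_asymmetries(trees)
        params = SynthParams()
        lo = 1.5 * params.alpha
        # a-p divisions with Low parents dominate; group mean lies between
        # the two planted levels
        mean = asyms.loc[asyms.axis == "a-p", "asym"].mean()
        hi = params.alpha * (params.gamma + 0.5)
        assert lo * 0.9 < mean < hi


def _bh_brute(pvals):
    """Step-up Benjamini-Hochberg by direct definition."""
    m = len(pvals)
    order = np.argsort(pvals)
    q = np.empty(m)
    for rank_idx, i in enumerate(order, start=1):
        q[i] = min(
            min(pvals[j] * m / (list(order).index(j) + 1)
                for j in order[rank_idx - 1:]),
            1.0,
        )
    return q


class TestSignificance:
    def test_zero_asymmetries_not_significant(self):
        df = pd.DataFrame(
            {"division": ["AB"] * 4, "axis": ["a-p"] * 4,
             "embryo_id": list("abcd"), "asym": [0.0] * 4,
             "parent_birth": [0.0] * 4, "division_time": [1.0] * 4}
        )
        out = run_asymmetry_test(df)
        assert out["p_nominal"].iloc[0] == 1.0
        assert not out["significant"].iloc[0]

    def test_bh_hand_computed_example(self):
        # m=4: q = (0.04, 0.04, 0.0533..., 0.5)
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.04, 0.5], method="fdr_bh")[1]
        assert q == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.5])

    @given(
        st.lists(st.integers(1, 100).map(lambda i: i / 100), min_size=1, max_size=6)
    )
    def test_bh_matches_brute_force(self, pvals):
        from statsmodels.stats.multitest import multipletests

        q = multipletests(pvals, method="fdr_bh")[1]
        assert q == pytest.approx(_bh_brute(np.array(pvals)))

    def test_q_at_least_p(self, wt_group):
        trees, _ = wt_group
        tab = division_table(trees)
        assert (tab["q_fdr"] >= tab["p_nominal"] - 1e-12).all()

    def test_most_ap_divisions_significant_at_3sigma_boost(self, wt_group):
        # posterior boost = 3 noise SDs, 8 embryos: >= 90% of a-p divisions
        # reach nominal p < 0.05
        trees, _ = wt_group
        tab = division_table(trees)
        ap = tab[tab.axis == "a-p"]
        assert ap["significant"].mean() >= 0.90

    def test_insufficient_replicates_excluded_and_counted(self):
        df = pd.DataFrame(
            {"division": ["AB", "AB", "ABp"], "axis": ["a-p"] * 3,
             "embryo_id": ["a", "b", "a"], "asym": [1.0, 2.0, 1.0],
             "parent_birth": [0.0] * 3, "division_time": [1.0] * 3}
        )
        out = run_asymmetry_test(df, min_embryos=3)
        assert len(out) == 0 and out.attrs["excluded"] == 2


class TestClassification:
    thr = PolarityThresholds(low_cutoff=10.0, none_cutoff=3.0)

    @pytest.mark.parametrize(
        "asym,expected",
        [
            (0.0, "none"), (3.0, "none"), (-3.0, "none"),  # closed on none side
            (-3.5, "reversed"), (-50.0, "reversed"),
            (5.0, "low"), (10.0, "low"),  # boundary goes to low
            (10.5, "normal"), (100.0, "normal"),
        ],
    )
    def test_posterior_high_reporter(self, asym, expected):
        assert classify_division(asym, self.thr, reporter_sign=+1) == expected

    def test_anterior_high_reporter_mirrors(self):
        # POP-1-type: strongly posterior-higher value is the reversal
        assert classify_division(20.0, self.thr, reporter_sign=-1) == "reversed"
        assert classify_division(-20.0, self.thr, reporter_sign=-1) == "normal"

    def test_derive_thresholds_from_wildtype(self, wt_group):
        trees, _ = wt_group
        tab = division_table(trees)
        unpol = list(tab["division"][:3])  # designated unpolarized reference
        thr = derive_thresholds(tab, unpol, reporter_sign=+1)
        assert thr.none_cutoff >= 0
        ref = tab[tab["division"].isin(unpol)]["asym_mean"].abs().max()
        assert thr.none_cutoff == pytest.approx(ref)

    def test_reversed_divisions_detected(self):
        params = SynthParams(sigma=0.0, embryo_scale_sd=0.0, lr_dv_fraction=0.0,
                             reversed_divisions=("ABpa",))
        trees, _, _ = simulate_dataset(params, n_embryos=3, seed=5)
        tab = division_table(trees)
        thr = PolarityThresholds(low_cutoff=30.0, none_cutoff=10.0)
        by_div = tab.set_index("division")["asym_mean"]
        assert classify_division(by_div["ABpa"], thr, +1) == "reversed"
        assert classify_division(by_div["ABpp"], thr, +1) == "normal"


class TestOrientation:
    def test_identical_vectors(self):
        ang, flag = orientation_deviation([1, 0, 0], [[1, 0, 0], [1, 0, 0]], 10.0)
        assert ang == pytest.approx(0.0) and flag is False

    def test_opposite_vectors(self):
        ang, _ = orientation_deviation([-1, 0, 0], [[1, 0, 0]])
        assert ang == pytest.approx(180.0)

    @pytest.mark.parametrize("deg", [15.0, 45.0, 90.0, 135.0])
    def test_recovers_planted_rotation(self, deg):
        th = np.radians(deg)
        v = [np.cos(th), np.sin(th), 0.0]
        ang, flag = orientation_deviation(v, [[1, 0, 0]], cutoff_degrees=30.0)
        assert ang == pytest.approx(deg)
        assert flag == (deg > 30.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            orientation_deviation([0, 0, 0], [[1, 0, 0]])


class TestCompareGroups:
    def test_identical_groups_null(self, wt_group):
        trees, _ = wt_group
        asyms = collect_asymmetries(trees)
        out = compare_groups(asyms, asyms)
        assert out["percent_diff"].iloc[0] == pytest.approx(0.0)
        assert out["p"].iloc[0] > 0.99

    def test_recovers_planted_30pct_reduction(self):
        base = SynthParams(lr_dv_fraction=0.0)
        lowered = SynthParams(lr_dv_fraction=0.0, alpha=base.alpha * 0.7,
                              gamma=1 + (base.gamma - 1) / 0.7)
        a, _, _ = simulate_dataset(base, n_embryos=8, seed=21)
        b, _, _ = simulate_dataset(lowered, n_embryos=8, seed=22)
        out = compare_groups(collect_asymmetries(a), collect_asymmetries(b))
        assert out["percent_diff"].iloc[0] == pytest.approx(-30.0, abs=6.0)
        assert out["p"].iloc[0] < 1e-6

    def test_stratified_early_reduction(self):
        # ligand-mutant-like condition: boost halved before the 28-cell stage
        wt_p = SynthParams(lr_dv_fraction=0.0)
        mut_p = SynthParams(lr_dv_fraction=0.0, alpha_early_factor=0.5)
        wt, _, _ = simulate_dataset(wt_p, n_embryos=8, seed=31)
        mut, _, _ = simulate_dataset(mut_p, n_embryos=8, seed=32)
        t28 = np.mean([stage_time(t, 28) for t in wt])
        strat = lambda row: "early" if row["parent_birth"] <= t28 else "late"
        out = compare_groups(
            collect_asymmetries(wt), collect_asymmetries(mut), stratifier=strat
        ).set_index("stratum")
        assert out.loc["early", "percent_diff"] < -20
        assert out.loc["early", "p"] < 1e-4
        assert abs(out.loc["late", "percent_diff"]) < 10

    def test_class_count_association(self):
        out = compare_groups(
            collect_asymmetries([]) if False else pd.DataFrame(
                {"division": ["x"], "axis": ["a-p"], "embryo_id": ["a"],
                 "asym": [1.0], "parent_birth": [0.0], "division_time": [1.0]}
            ),
            pd.DataFrame(
                {"division": ["x"], "axis": ["a-p"], "embryo_id": ["a"],
                 "asym": [1.0], "parent_birth": [0.0], "division_time": [1.0]}
            ),
            classes_a=["normal"] * 40 + ["reversed"] * 2,
            classes_b=["normal"] * 20 + ["reversed"] * 20,
        )
        ct = out.attrs["class_test"]
        # one inflated class: exact test flags the association
        assert ct["test"] == "fisher" and ct["p"] < 1e-4

    def test_empty_stratum_reported_not_tested(self):
        a = pd.DataFrame(
            {"division": ["x"], "axis": ["a-p"], "embryo_id": ["a"],
             "asym": [1.0], "parent_birth": [0.0], "division_time": [1.0]}
        )
        b = a.assign(parent_birth=100.0)
        strat = lambda row: "early" if row["parent_birth"] < 50 else "late"
        out = compare_groups(a, b, stratifier=strat).set_index("stratum")
        assert np.isnan(out.loc["early", "p"]) and out.loc["early", "n_b"] == 0
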