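"""Climate profiles, PGLS contrasts, BM reconstruction, crossings and lags."""

import numpy as np
import pandas as pd
import pytest

from biomepool import parse_newick
from biomepool.climate import (
    ThresholdSpec,
    assign_groups,
    bm_ancestral_bayes,
    bm_ancestral_ml,
    lag_time,
    pgls_group_test,
    species_climate_means,
    threshold_crossing_age,
)
from biomepool.simulate import simulate_bd_tree, simulate_bm_traits
from biomepool.trees import TreeError


class TestClimateMeans:
    def test_single_record(self):
        occ = pd.DataFrame({"species": ["a"], "bio12": [1500.0],
                            "bio17": [60.0]})
        prof = species_climate_means(occ)
        assert prof.loc["a", "bio12"] == 1500.0
        assert prof.loc["a", "bio17"] == 60.0

    def test_arithmetic_mean(self):
        occ = pd.DataFrame({"species": ["a", "a"], "bio12": [100.0, 300.0]})
        assert species_climate_means(occ).loc["a", "bio12"] == 200.0

    def test_non_numeric_rows_rejected_with_warning(self):
        occ = pd.DataFrame({"species": ["a", "a", "b"],
                            "bio12": [100.0, "oops", "bad"]})
        with pytest.warns(UserWarning):
            prof = species_climate_means(occ)
        assert list(prof.index) == ["a"]
        assert prof.loc["a", "n_records"] == 1


class TestGroups:
    def test_labels(self):
        table = pd.DataFrame(
            {"SA": [0, 0, 1], "CA": [0, 1, 0], "Me": [1, 1, 0]},
            index=["endemic_sp", "wide_sp", "out_sp"])
        labels = assign_groups(table, "Me")
        assert labels["endemic_sp"] == "endemic"
        assert labels["wide_sp"] == "widespread"
        assert labels["out_sp"] == "non_focal"

    def test_all_zero_row_named_in_error(self):
        table = pd.DataFrame({"SA": [0], "Me": [0]}, index=["ghost"])
        with pytest.raises(ValueError, match="ghost"):
            assign_groups(table, "Me")

    def test_unknown_focal(self):
        table = pd.DataFrame({"SA": [1]}, index=["x"])
        with pytest.raises(ValueError):
            assign_groups(table, "Me")


class TestPGLS:
    def test_star_tree_equals_ols(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(2)
        star = parse_newick("(" + ",".join(f"S{i}:1" for i in range(12)) + ");")
        idx = [f"S{i}" for i in range(12)]
        labels = pd.Series(["endemic"] * 4 + ["widespread"] * 4
                           + ["non_focal"] * 4, index=idx)
        prof = pd.DataFrame({"bio12": rng.normal(1000, 100, 12)}, index=idx)
        res = pgls_group_test(star, prof, labels, "bio12")
        X = np.column_stack([np.ones(12),
                             (labels == "endemic").to_numpy(float),
                             (labels == "widespread").to_numpy(float)])
        ols = sm.OLS(prof["bio12"].to_numpy(), X).fit()
        assert np.abs(res.coefficients["coef"].to_numpy() - ols.params).max() < 1e-8

    def test_absent_group_is_explicit_error(self):
        star = parse_newick("(" + ",".join(f"S{i}:1" for i in range(6)) + ");")
        idx = [f"S{i}" for i in range(6)]
        labels = pd.Series(["endemic"] * 6, index=idx)
        prof = pd.DataFrame({"bio12": np.arange(6.0)}, index=idx)
        with pytest.raises(ValueError):
            pgls_group_test(star, prof, labels, "bio12")

    def test_group_shift_detected_with_high_power(self):
        tree = simulate_bd_tree(0.2, 0.0, 100, seed=1)
        sigma2 = 100.0
        shift = 3 * np.sqrt(sigma2 * tree.root_age)
        labels = pd.Series(["endemic"] * 20 + ["widespread"] * 20
                           + ["non_focal"] * 60, index=tree.tip_labels)
        detected = 0
        n_rep = 30
        for rep in range(n_rep):
            vals = simulate_bm_traits(tree, sigma2, 0.0, seed=rep)
            y = {tree.labels[i]: vals[i] for i in tree.tip_indices}
            for lab in labels.index[labels == "endemic"]:
                y[lab] -= shift
            prof = pd.DataFrame({"bio12": pd.Series(y)})
            res = pgls_group_test(tree, prof, labels, "bio12")
            c = res.contrasts
            p = c[(c.group_a == "non_focal")
                  & (c.group_b == "endemic")]["p"].iloc[0]
            detected += p < 0.05
        assert detected >= int(0.9 * n_rep)


class TestBMAncestral:
    def test_two_tip_midpoint(self, cherry):
        fit = bm_ancestral_ml(cherry, {"A": 1000.0, "B": 2000.0})
        assert fit.node_values[cherry.root] == pytest.approx(1500.0)

    def test_constant_tips_zero_variance(self, four_tip):
        fit = bm_ancestral_ml(four_tip, {l: 7.0 for l in four_tip.tip_labels})
        assert np.allclose(fit.node_values, 7.0)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_root_matches_closed_form_gls(self, four_tip):
        rng = np.random.default_rng(0)
        y = {l: rng.normal(0, 1) for l in four_tip.tip_labels}
        fit = bm_ancestral_ml(four_tip, y)
        C = four_tip.shared_depth_matrix()
        yv = np.array([y[four_tip.labels[i]] for i in four_tip.tip_indices])
        one = np.ones(len(yv))
        closed = one @ np.linalg.solve(C, yv) / (one @ np.linalg.solve(C, one))
        assert fit.node_values[four_tip.root] == pytest.approx(closed, abs=1e-6)

    def test_tip_order_and_constant_shift_invariance(self):
        t1 = parse_newick("((A:1,B:1):1,C:2);")
        t2 = parse_newick("(C:2,(B:1,A:1):1);")
        y = {"A": 3.0, "B": 5.0, "C": 11.0}
        f1, f2 = bm_ancestral_ml(t1, y), bm_ancestral_ml(t2, y)
        assert f1.node_values[t1.root] == pytest.approx(f2.node_values[t2.root])
        y_shift = {k: v + 100.0 for k, v in y.items()}
        f3 = bm_ancestral_ml(t1, y_shift)
        assert f3.node_values[t1.root] == pytest.approx(
            f1.node_values[t1.root] + 100.0)
        assert f3.sigma2 == pytest.approx(f1.sigma2)

    def test_rmse_decreases_with_tip_count(self):
        # trees rescaled to a common depth so tip count means denser sampling
        from biomepool.trees import DatedTree
        sigma2 = 50.0
        depth = 20.0
        rmses = []
        for n in (25, 100):
            errs = []
            for rep in range(40):
                raw = simulate_bd_tree(0.2, 0.0, n, seed=500 * n + rep)
                s = depth / raw.root_age
                tree = DatedTree(raw.parent.copy(), raw.lengths * s,
                                 list(raw.labels))
                vals = simulate_bm_traits(tree, sigma2, 0.0, seed=rep)
                tips = {tree.labels[i]: vals[i] for i in tree.tip_indices}
                fit = bm_ancestral_ml(tree, tips)
                internal = [k for k in range(tree.n_nodes)
                            if not tree.is_tip(k) and k != tree.root]
                errs.extend(fit.node_values[internal] - vals[internal])
            errs = np.asarray(errs)
            assert abs(np.median(errs)) < 2.0  # near-zero median bias
            rmses.append(np.sqrt(np.mean(errs ** 2)))
        assert rmses[1] < rmses[0]

    def test_missing_tip_value_raises(self, cherry):
        with pytest.raises(TreeError):
            bm_ancestral_ml(cherry, {"A": 1.0})


class TestBMBayes:
    def test_concordant_with_ml_under_flat_priors(self):
        rng = np.random.default_rng(31)
        for rep in range(5):
            tree = simulate_bd_tree(0.3, 0.0, 8, seed=600 + rep)
            tips = {l: rng.normal(100, 20) for l in tree.tip_labels}
            ml = bm_ancestral_ml(tree, tips)
            bayes = bm_ancestral_bayes(tree, tips, n_iter=2000, seed=rep)
            internal = [k for k in range(tree.n_nodes) if not tree.is_tip(k)]
            for k in internal:
                sd = max(bayes["node_sds"][k], 1e-6)
                assert abs(bayes["node_means"][k] - ml.node_values[k]) < 2 * sd

    def test_seed_reproducibility(self, four_tip):
        tips = {"A": 1.0, "B": 4.0, "C": 2.0, "D": 9.0}
        b1 = bm_ancestral_bayes(four_tip, tips, n_iter=500, seed=3)
        b2 = bm_ancestral_bayes(four_tip, tips, n_iter=500, seed=3)
        assert np.array_equal(b1["node_means"], b2["node_means"])
        assert b1["acceptance_rate"] == 1.0

    def test_constant_tips_concentrate(self, four_tip):
        b = bm_ancestral_bayes(four_tip, {l: 5.0 for l in four_tip.tip_labels},
                               n_iter=500, seed=1)
        assert np.allclose(b["node_means"], 5.0, atol=1e-3)


class TestCrossingAndLag:
    def test_linear_interpolation(self):
        tree = parse_newick("(A:30,B:30);")
        vals = np.zeros(tree.n_nodes)
        vals[tree.root] = 2000.0
        vals[tree.node_of("A")] = 800.0
        vals[tree.node_of("B")] = 2000.0
        # crossing from 2000@30 to 800@0 at theta=1800: age 30*(1-200/1200)=25
        cr = threshold_crossing_age(tree, vals, "A", ThresholdSpec("bio12", 1800))
        assert cr.crossing_age == pytest.approx(25.0)

    def test_root_already_below(self):
        tree = parse_newick("(A:10,B:10);")
        vals = np.full(tree.n_nodes, 1500.0)
        cr = threshold_crossing_age(tree, vals, "A", ThresholdSpec("bio12", 1800))
        assert cr.crossing_age == pytest.approx(tree.root_age)
        assert cr.branch is None

    def test_never_below_is_none(self):
        tree = parse_newick("(A:10,B:10);")
        vals = np.full(tree.n_nodes, 2500.0)
        cr = threshold_crossing_age(tree, vals, "A", ThresholdSpec("bio12", 1800))
        assert cr.crossing_age is None

    def test_lag_classes(self):
        tree = parse_newick("((A:5,B:5):10,C:15);")
        x = tree.mrca(tree.node_of("A"), tree.node_of("B"))
        theta = ThresholdSpec("bio12", 1800)
        restriction = {"parent": x, "child": tree.node_of("A"),
                       "event_age": 18.0}
        from biomepool.climate import CrossingRecord
        pre = lag_time(restriction,
                       CrossingRecord(tree.node_of("A"), theta, 40.0,
                                      (tree.root, x)))
        assert pre.klass == "pre_adapted" and pre.lag == pytest.approx(22.0)
        conc = lag_time(restriction,
                        CrossingRecord(tree.node_of("A"), theta, 3.0,
                                       (x, tree.node_of("A"))))
        assert conc.klass == "concurrent"
        insitu = lag_time(restriction,
                          CrossingRecord(tree.node_of("A"), theta, 10.0,
                                         (tree.root, x)))
        assert insitu.klass == "in_situ" and insitu.lag == pytest.approx(-8.0)
        none_cr = lag_time(restriction,
                           CrossingRecord(tree.node_of("A"), theta, None, None))
        assert none_cr.klass == "in_situ" and none_cr.lag is None

    def test_mismatched_lineage_raises(self):
        tree = parse_newick("(A:5,B:5);")
        from biomepool.climate import CrossingRecord
        theta = ThresholdSpec("bio12", 1800)
        with pytest.raises(ValueError):
            lag_time({"parent": tree.root, "child": tree.node_of("A"),
                      "event_age": 2.0},
                     CrossingRecord(tree.node_of("B"), theta, 3.0, None))
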