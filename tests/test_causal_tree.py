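import json

import numpy as np
import pytest

from treefx import (
    CausalTree,
    FitConfig,
    FitError,
    LeafStats,
    SimulationConfig,
    TreeNode,
    ValidationError,
    assign_leaf,
    best_split,
    cost_complexity_path,
    cv_select_alpha,
    emse_criterion,
    fit_causal_tree,
    generate_trial,
    grow_tree,
    leaf_stats,
    transformed_outcome,
    tree_from_json,
    tree_to_json,
    tree_to_rules,
)
from treefx.causal_tree import _label_leaves, rules_text
from treefx.report import prepare_outcome

from conftest import make_dataset


def brute_stats(y, w):
    """Direct mean/variance recomputation (independent of leaf_stats)."""
    y1 = [v for v, a in zip(y, w) if a == 1]
    y0 = [v for v, a in zip(y, w) if a == 0]
    m1 = sum(y1) / len(y1)
    m0 = sum(y0) / len(y0)
    v1 = sum((v - m1) ** 2 for v in y1) / (len(y1) - 1) if len(y1) > 1 else 0.0
    v0 = sum((v - m0) ** 2 for v in y0) / (len(y0) - 1) if len(y0) > 1 else 0.0
    return len(y1), len(y0), m1, m0, v1, v0, m1 - m0


def exhaustive_best_split(X: dict, y, w, min_per_arm, p):
    """Naive search over every admissible midpoint split (oracle)."""
    y = np.asarray(y, float)
    w = np.asarray(w, int)
    n = len(y)
    parent = emse_criterion([leaf_stats(y, w)], n, p)
    best = None  # (gain, feat_idx, threshold, feature)
    for fi, (name, x) in enumerate(X.items()):
        x = np.asarray(x, float)
        vals = sorted(set(x))
        for a, b in zip(vals[:-1], vals[1:]):
            thr = (a + b) / 2.0
            lo = x < thr
            for side in (lo, ~lo):
                for arm in (0, 1):
                    if ((w == arm) & side).sum() < min_per_arm:
                        break
                else:
                    continue
                break
            else:
                crit = emse_criterion(
                    [leaf_stats(y[lo], w[lo]), leaf_stats(y[~lo], w[~lo])], n, p
                )
                gain = crit - parent
                if gain > 0 and (
                    best is None
                    or gain > best[0] + 1e-15
                    or (abs(gain - best[0]) <= 1e-15 and (fi, thr) < (best[1], best[2]))
                ):
                    best = (gain, fi, thr, name)
    return best


class TestLeafStats:
    def test_arithmetic(self):
        st = leaf_stats([2, 4, 1, 3], [1, 1, 0, 0])
        assert st.tau_hat == 1.0 and st.mean1 == 3.0 and st.mean0 == 2.0

    def test_symmetry(self):
        st = leaf_stats([5, 7, 5, 7], [1, 1, 0, 0])
        assert st.tau_hat == 0.0

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=10)
        w = np.array([1, 0, 1, 0, 1, 0, 1, 0, 1, 0])
        st = leaf_stats(y, w)
        n1, n0, m1, m0, v1, v0, tau = brute_stats(list(y), list(w))
        assert (st.n1, st.n0) == (n1, n0)
        np.testing.assert_allclose([st.mean1, st.mean0, st.var1, st.var0, st.tau_hat],
                                   [m1, m0, v1, v0, tau], rtol=1e-12)

    def test_empty_arm_error(self):
        with pytest.raises(ValidationError):
            leaf_stats([1.0, 2.0], [1, 1])

    def test_single_observation_arm_degenerate(self):
        st = leaf_stats([1.0, 2.0, 3.0], [1, 0, 0])
        assert st.degenerate1 and st.var1 == 0.0 and not st.degenerate0


class TestEmseCriterion:
    def test_constant_data_zero(self):
        st = leaf_stats([3.0] * 6, [1, 1, 1, 0, 0, 0])
        assert emse_criterion([st], 6, 0.5) == 0.0

    def test_two_leaf_closed_form(self):
        left = leaf_stats([-1, -1, 0, 0], [1, 1, 0, 0])
        right = leaf_stats([1, 1, 0, 0], [1, 1, 0, 0])
        np.testing.assert_allclose(emse_criterion([left, right], 8, 0.5), 1.0)
        root = leaf_stats([-1, -1, 1, 1, 0, 0, 0, 0], [1, 1, 1, 1, 0, 0, 0, 0])
        np.testing.assert_allclose(emse_criterion([root], 8, 0.5), -2.0 / 3.0)

    def test_formula_oracle(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=24)
        w = rng.permutation([1] * 12 + [0] * 12)
        cut = rng.integers(4, 20)
        parts = [(y[:cut], w[:cut]), (y[cut:], w[cut:])]
        leaves = [leaf_stats(yy, ww) for yy, ww in parts]
        p = 0.4
        expected = 0.0
        for yy, ww in parts:
            n1, n0, m1, m0, v1, v0, tau = brute_stats(list(yy), list(ww))
            expected += (n1 + n0) * tau**2 / 24 - (2 / 24) * (v1 / p + v0 / (1 - p))
        np.testing.assert_allclose(emse_criterion(leaves, 24, p), expected, rtol=1e-12)

    def test_p_out_of_range(self):
        st = leaf_stats([1, 2], [1, 0])
        with pytest.raises(ValidationError):
            emse_criterion([st], 2, 1.0)


class TestBestSplit:
    def test_perfect_separation(self):
        X = {"f": np.array([0, 0, 0, 0, 1, 1, 1, 1], float)}
        y = np.array([-1, -1, 0, 0, 1, 1, 0, 0], float)
        w = np.array([1, 1, 0, 0, 1, 1, 0, 0])
        cand = best_split(X, y, w, FitConfig(min_per_arm=1), 0.5, ["f"])
        assert cand.feature == "f" and cand.threshold == 0.5
        np.testing.assert_allclose(cand.gain, 5.0 / 3.0)

    def test_none_when_children_too_small(self):
        # any split strands one arm below the minimum
        X = {"f": np.arange(8, dtype=float)}
        y = np.array([-1, -1, 0, 0, 1, 1, 0, 0], float)
        w = np.array([1, 1, 1, 1, 0, 0, 0, 0])  # arms separated along f
        assert best_split(X, y, w, FitConfig(min_per_arm=2), 0.5, ["f"]) is None

    def test_too_few_overall_returns_none(self):
        X = {"f": np.arange(6, dtype=float)}
        y = np.zeros(6)
        w = np.array([1, 1, 1, 0, 0, 0])
        assert best_split(X, y, w, FitConfig(min_per_arm=2), 0.5, ["f"]) is None

    def test_exhaustive_oracle(self):
        rng = np.random.default_rng(11)
        n = 30
        X = {f"x{j}": rng.normal(size=n) for j in range(4)}
        w = rng.permutation([1] * 15 + [0] * 15)
        y = rng.normal(size=n) + w * (X["x2"] > 0)
        p = 0.5
        cfg = FitConfig(min_per_arm=3)
        cand = best_split(X, y, w, cfg, p, list(X))
        oracle = exhaustive_best_split(X, y, w, 3, p)
        assert cand.feature == oracle[3]
        np.testing.assert_allclose(cand.threshold, oracle[2], rtol=1e-12)
        np.testing.assert_allclose(cand.gain, oracle[0], rtol=1e-9)

    def test_all_missing_feature_skipped(self):
        X = {"bad": np.full(8, np.nan), "f": np.array([0, 0, 0, 0, 1, 1, 1, 1], float)}
        y = np.array([-1, -1, 0, 0, 1, 1, 0, 0], float)
        w = np.array([1, 1, 0, 0, 1, 1, 0, 0])
        cand = best_split(X, y, w, FitConfig(min_per_arm=1), 0.5, ["bad", "f"])
        assert cand.feature == "f"


class TestGrowTree:
    def test_size_bound_root_only(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.normal(size=12), [1] * 6 + [0] * 6,
                          {"x": rng.normal(size=12)})
        tree = grow_tree(ds, FitConfig(min_per_arm=5))
        assert tree.root.is_leaf and tree.n_leaves == 1

    def test_too_few_per_arm_error(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.normal(size=7), [1] * 4 + [0] * 3,
                          {"x": rng.normal(size=7)})
        with pytest.raises(FitError, match="too few"):
            grow_tree(ds, FitConfig(min_per_arm=5))

    def test_planted_threshold_recovery(self):
        rng = np.random.default_rng(2)
        n = 200
        X = {f"x{j}": rng.normal(size=n) for j in range(3)}
        # coarse measurement grid, as for rounded serum markers: midpoint
        # thresholds then identify the planted cut
        X["planted"] = np.round(rng.uniform(size=n), 1)
        w = rng.permutation([1] * 100 + [0] * 100)
        tau = np.where(X["planted"] >= 0.5, 4.0, -4.0)
        y = w * tau + rng.normal(scale=1.0, size=n)
        ds = make_dataset(y, w, X)
        tree = grow_tree(ds, FitConfig())
        assert tree.root.feature == "planted"
        below = X["planted"][X["planted"] < 0.5].max()
        above = X["planted"][X["planted"] >= 0.5].min()
        assert below < tree.root.threshold < above

    def test_min_per_arm_in_all_leaves(self, fitted_default_tree):
        for leaf in fitted_default_tree.leaves():
            assert leaf.stats.n1 >= 5 and leaf.stats.n0 >= 5

    def test_missing_covariate_rejected(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=20)
        x[3] = np.nan
        ds = make_dataset(rng.normal(size=20), [1, 0] * 10, {"x": x})
        with pytest.raises(FitError, match="missing"):
            grow_tree(ds, FitConfig(min_per_arm=2))


class TestTransformedOutcome:
    def test_formula(self):
        assert transformed_outcome([3.0], [1], 0.5)[0] == 6.0
        assert transformed_outcome([3.0], [0], 0.5)[0] == -6.0

    def test_mean_is_tau(self):
        ystar = transformed_outcome([2, 4, 1, 3], [1, 1, 0, 0], 0.5)
        np.testing.assert_allclose(ystar, [4, 8, -2, -6])
        np.testing.assert_allclose(ystar.mean(), 1.0)

    def test_mean_matches_root_tau_12_digits(self):
        ds = prepare_outcome(generate_trial(SimulationConfig(seed=5)), 24)
        p = float((ds.arm == 1).mean())
        ystar = transformed_outcome(ds.delta_ppfvc, ds.arm, p)
        st = leaf_stats(ds.delta_ppfvc, ds.arm)
        np.testing.assert_allclose(ystar.mean(), st.tau_hat, rtol=1e-12)

    def test_p_out_of_range(self):
        with pytest.raises(ValidationError):
            transformed_outcome([1.0], [1], 0.0)


def build_three_leaf_tree():
    """Hand-built tree with fully specified stats for pruning oracles."""
    leaf_r = TreeNode(1, LeafStats(10, 10, 5.0, 0.0, 1.0, 1.0, 5.0))
    leaf_1 = TreeNode(3, LeafStats(5, 5, 2.0, 0.0, 1.0, 1.0, 2.0))
    leaf_2 = TreeNode(4, LeafStats(5, 5, -2.0, 0.0, 1.0, 1.0, -2.0))
    node_b = TreeNode(2, LeafStats(10, 10, 0.0, 0.0, 5.0, 5.0, 0.0),
                      feature="KL6", threshold=364.0, low=leaf_2, high=leaf_1)
    root = TreeNode(0, LeafStats(20, 20, 2.5, 0.0, 8.0, 8.0, 2.5),
                    feature="CRP", threshold=0.055, low=node_b, high=leaf_r)
    tree = CausalTree(root=root, n_train=40, p_treated=0.5, config=FitConfig())
    _label_leaves(tree)
    return tree


class TestCostComplexityPath:
    def test_root_only_degenerate(self):
        root = TreeNode(0, LeafStats(5, 5, 1.0, 0.0, 1.0, 1.0, 1.0))
        tree = CausalTree(root=root, n_train=10, p_treated=0.5, config=FitConfig())
        path = cost_complexity_path(tree)
        assert len(path) == 1 and path[0][0] == 0.0

    def test_manual_weakest_link(self):
        # independent recomputation: risk r(leaf) = -(n tau^2/N - (2/N)(v1/p+v0/(1-p)))
        def r(n1, n0, tau, v1, v0, N=40, p=0.5):
            return -((n1 + n0) * tau**2 / N - (2 / N) * (v1 / p + v0 / (1 - p)))

        g_b = (r(10, 10, 0.0, 5.0, 5.0) - (r(5, 5, 2, 1, 1) + r(5, 5, -2, 1, 1))) / 1
        r_sub_root = r(10, 10, 5, 1, 1) + r(5, 5, 2, 1, 1) + r(5, 5, -2, 1, 1)
        g_root_3 = (r(20, 20, 2.5, 8, 8) - r_sub_root) / 2
        assert g_b < g_root_3  # inner node is the weakest link
        g_root_2 = (r(20, 20, 2.5, 8, 8) - (r(10, 10, 5, 1, 1) + r(10, 10, 0, 5, 5))) / 1

        path = cost_complexity_path(build_three_leaf_tree())
        alphas = [a for a, _ in path]
        sizes = [t.n_leaves for _, t in path]
        assert sizes == [3, 2, 1]
        np.testing.assert_allclose(alphas, [0.0, g_b, g_root_2], rtol=1e-12)

    def test_structural_properties(self, fitted_default_tree, default_trial_2000):
        tree = grow_tree(default_trial_2000, FitConfig(seed=1, max_depth=4))
        path = cost_complexity_path(tree)
        alphas = [a for a, _ in path]
        sizes = [t.n_leaves for _, t in path]
        assert all(a < b for a, b in zip(alphas, alphas[1:]))
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] == 1
        # nesting: leaf sets shrink by collapsing internal nodes only
        for (_, big), (_, small) in zip(path, path[1:]):
            big_ids = {n.id for n in big.root.leaves()}
            internal_big = {n.id for n in big.root.internal_nodes()}
            small_ids = {n.id for n in small.root.leaves()}
            # every leaf of the smaller subtree is a surviving leaf or a
            # collapsed internal node of the previous one
            assert small_ids <= big_ids | internal_big

    def test_leaf_sizes_sum_to_n_train(self, fitted_default_tree):
        total = sum(l.stats.n for l in fitted_default_tree.leaves())
        assert total == fitted_default_tree.n_train


class TestCvAndFit:
    def test_degenerate_root_only(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=12)
        ds = make_dataset(y, [1] * 6 + [0] * 6, {"x": rng.normal(size=12)})
        cfg = FitConfig(min_per_arm=5, n_folds=2)
        alpha, curve = cv_select_alpha(ds, cfg)
        assert alpha == 0.0 and len(curve) == 1
        tree = fit_causal_tree(ds, cfg)
        assert tree.n_leaves == 1

    def test_default_synthetic_three_leaves(self, fitted_default_tree):
        assert fitted_default_tree.n_leaves == 3
        assert fitted_default_tree.root.feature == "CRP"

    def test_homogeneous_effect_one_leaf(self):
        cfg = SimulationConfig(
            n=500, seed=5, leaf_effects=(2.0, 2.0, 2.0),
            control_means=(-2.0, -2.0, -2.0),
        )
        ds = prepare_outcome(generate_trial(cfg), 24)
        tree = fit_causal_tree(ds, FitConfig(seed=5))
        assert tree.n_leaves == 1

    def test_refit_bit_identical(self, default_trial_2000):
        t1 = fit_causal_tree(default_trial_2000, FitConfig(seed=1))
        t2 = fit_causal_tree(default_trial_2000, FitConfig(seed=1))
        assert tree_to_json(t1) == tree_to_json(t2)

    def test_honest_half_mode(self, default_trial_2000):
        tree = fit_causal_tree(
            default_trial_2000, FitConfig(seed=1, estimate_mode="honest_half")
        )
        # estimation half carries roughly half the patients
        total = sum(l.stats.n for l in tree.leaves())
        assert abs(total - default_trial_2000.n // 2) <= 1
        for leaf in tree.leaves():
            assert leaf.stats.n1 >= 1 and leaf.stats.n0 >= 1

    def test_fold_count_validation(self):
        rng = np.random.default_rng(0)
        ds = make_dataset(rng.normal(size=8), [1] * 4 + [0] * 4,
                          {"x": rng.normal(size=8)})
        with pytest.raises(ValidationError, match="n_folds"):
            cv_select_alpha(ds, FitConfig(min_per_arm=1, n_folds=5))


class TestAssignAndRules:
    def test_fig_shaped_routing(self):
        tree = build_three_leaf_tree()
        rec = {"CRP": 0.2, "KL6": 500.0}
        assert assign_leaf(tree, rec) == 1
        assert assign_leaf(tree, {"CRP": 0.0, "KL6": 500.0}) == 2
        assert assign_leaf(tree, {"CRP": 0.0, "KL6": 100.0}) == 3

    def test_boundary_goes_high(self):
        tree = build_three_leaf_tree()
        assert assign_leaf(tree, {"CRP": 0.055, "KL6": 0.0}) == 1
        assert assign_leaf(tree, {"CRP": 0.0, "KL6": 364.0}) == 2

    def test_missing_feature_error(self):
        tree = build_three_leaf_tree()
        with pytest.raises(ValidationError, match="CRP"):
            assign_leaf(tree, {"KL6": 100.0})
        with pytest.raises(ValidationError, match="KL6"):
            assign_leaf(tree, {"CRP": 0.0, "KL6": float("nan")})

    def test_rule_strings(self):
        rules, _ = tree_to_rules(build_three_leaf_tree())
        texts = {r["leaf_label"]: r["rule"] for r in rules}
        assert texts[1] == "CRP >= 0.055"
        assert texts[2] == "CRP < 0.055 and KL6 >= 364"
        assert texts[3] == "CRP < 0.055 and KL6 < 364"

    def test_root_only_rule(self):
        root = TreeNode(0, LeafStats(5, 5, 1.0, 0.0, 1.0, 1.0, 1.0))
        tree = CausalTree(root=root, n_train=10, p_treated=0.5, config=FitConfig())
        _label_leaves(tree)
        rules, _ = tree_to_rules(tree)
        assert rules[0]["rule"] == "(all patients)"
        assert "Leaf 1: (all patients)" in rules_text(tree)

    def test_json_roundtrip_routing(self, fitted_default_tree):
        tree = fitted_default_tree
        tree2 = tree_from_json(tree_to_json(tree))
        rng = np.random.default_rng(4)
        for _ in range(1000):
            rec = {"CRP": float(rng.uniform(0, 2)), "KL6": float(rng.uniform(0, 5000))}
            assert assign_leaf(tree, rec) == assign_leaf(tree2, rec)

    def test_json_schema_fields(self, fitted_default_tree):
        doc = json.loads(tree_to_json(fitted_default_tree))
        assert set(doc) >= {"n_train", "p_treated", "alpha_selected", "config", "nodes"}
        for rec in doc["nodes"]:
            assert set(rec) >= {"id", "type", "feature", "threshold", "children",
                                "n1", "n0", "tau", "ci_low", "ci_high", "leaf_label"}
            if rec["type"] == "leaf":
                assert rec["children"] is None and rec["leaf_label"] is not None
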