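"""Honest causal tree for conditional treatment effects.

Grows a binary partition by maximizing an expected-mean-squared-error
criterion for the within-leaf treatment effect (difference in arm means),
subject to a per-arm minimum terminal-node size; builds the weakest-link
cost-complexity path; and selects the pruning penalty by k-fold
cross-validation on a transformed-outcome squared-error risk.

Conventions
-----------
* Split rule ``feature < threshold`` routes to the low child; values at
  or above the threshold route high.  Thresholds are midpoints of
  adjacent distinct observed values (binary features: 0.5).
* The treated share ``p`` entering the criterion is the root-level
  empirical share, held fixed for the whole fit.
* Leaf labels enumerate leaves 1..L depth-first, high side before low.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import FitError, ValidationError
from .trial_data import TrialDataset

__all__ = [
    "LeafStats",
    "SplitCandidate",
    "TreeNode",
    "CausalTree",
    "FitConfig",
    "leaf_stats",
    "emse_criterion",
    "best_split",
    "grow_tree",
    "transformed_outcome",
    "cost_complexity_path",
    "prune_at_alpha",
    "cv_select_alpha",
    "fit_causal_tree",
    "assign_leaf",
    "tree_to_rules",
    "tree_to_json",
    "tree_from_json",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LeafStats:
    """Per-arm summary of one node: counts, means, sample variances, effect."""

    n1: int
    n0: int
    mean1: float
    mean0: float
    var1: float
    var0: float
    tau_hat: float
    degenerate1: bool = False  # arm count < 2, variance recorded as 0
    degenerate0: bool = False

    @property
    def n(self) -> int:
        return self.n1 + self.n0


@dataclass(frozen=True)
class SplitCandidate:
    feature: str
    threshold: float
    gain: float
    left_stats: LeafStats
    right_stats: LeafStats


@dataclass
class TreeNode:
    """Internal node (feature/threshold + two children) or leaf."""

    id: int
    stats: LeafStats
    feature: str | None = None
    threshold: float | None = None
    low: "TreeNode | None" = None  # feature < threshold
    high: "TreeNode | None" = None  # feature >= threshold
    leaf_label: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def leaves(self) -> Iterator["TreeNode"]:
        if self.is_leaf:
            yield self
        else:
            yield from self.high.leaves()
            yield from self.low.leaves()

    def internal_nodes(self) -> Iterator["TreeNode"]:
        if not self.is_leaf:
            yield self
            yield from self.high.internal_nodes()
            yield from self.low.internal_nodes()

    def copy(self) -> "TreeNode":
        if self.is_leaf:
            return TreeNode(self.id, self.stats, leaf_label=self.leaf_label)
        return TreeNode(
            self.id,
            self.stats,
            feature=self.feature,
            threshold=self.threshold,
            low=self.low.copy(),
            high=self.high.copy(),
            leaf_label=self.leaf_label,
        )


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs of the tree procedure; defaults match the trial analysis."""

    min_per_arm: int = 5
    n_folds: int = 5
    estimate_mode: str = "full_sample"  # or "honest_half"
    max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_per_arm < 1:
            raise ValidationError("min_per_arm must be >= 1")
        if self.n_folds < 2:
            raise ValidationError("n_folds must be >= 2")
        if self.estimate_mode not in ("full_sample", "honest_half"):
            raise ValidationError(f"unknown estimate_mode {self.estimate_mode!r}")


@dataclass
class CausalTree:
    root: TreeNode
    n_train: int
    p_treated: float
    config: FitConfig
    alpha_selected: float | None = None
    cv_curve: list[tuple[float, float]] = field(default_factory=list)

    def leaves(self) -> list[TreeNode]:
        return list(self.root.leaves())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.root.leaves())


# ---------------------------------------------------------------------------
# node statistics and splitting criterion


def leaf_stats(y: Sequence[float], w: Sequence[int]) -> LeafStats:
    """Arm-wise means/variances and tau_hat = mean1 - mean0 for one node."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=int)
    if y.shape != w.shape:
        raise ValidationError("y and w must have equal length")
    y1, y0 = y[w == 1], y[w == 0]
    if len(y1) == 0 or len(y0) == 0:
        raise ValidationError("both arms must be represented in a node")
    mean1, mean0 = float(y1.mean()), float(y0.mean())
    deg1, deg0 = len(y1) < 2, len(y0) < 2
    var1 = 0.0 if deg1 else float(y1.var(ddof=1))
    var0 = 0.0 if deg0 else float(y0.var(ddof=1))
    return LeafStats(
        n1=len(y1), n0=len(y0), mean1=mean1, mean0=mean0,
        var1=var1, var0=var0, tau_hat=mean1 - mean0,
        degenerate1=deg1, degenerate0=deg0,
    )


def _leaf_criterion(st: LeafStats, n_total: int, p: float) -> float:
    effect = st.n * st.tau_hat**2 / n_total
    penalty = (2.0 / n_total) * (st.var1 / p + st.var0 / (1.0 - p))
    return effect - penalty


def emse_criterion(leaves: Sequence[LeafStats], n_total: int, p: float) -> float:
    """Negated estimated EMSE of a leaf partition; larger is better.

    ``(1/n) * sum n_l tau_l^2  -  (2/n) * sum (var1_l/p + var0_l/(1-p))``,
    i.e. the honest criterion with estimation-sample size taken equal to
    the training size.
    """
    if not 0.0 < p < 1.0:
        raise ValidationError(f"treated share p must be in (0,1), got {p}")
    if not leaves:
        raise ValidationError("at least one leaf required")
    return float(sum(_leaf_criterion(st, n_total, p) for st in leaves))


def _stats_from_moments(n1, n0, s1, s0, q1, q0) -> LeafStats:
    mean1 = s1 / n1
    mean0 = s0 / n0
    deg1, deg0 = n1 < 2, n0 < 2
    var1 = 0.0 if deg1 else max(0.0, (q1 - s1 * s1 / n1) / (n1 - 1))
    var0 = 0.0 if deg0 else max(0.0, (q0 - s0 * s0 / n0) / (n0 - 1))
    return LeafStats(int(n1), int(n0), float(mean1), float(mean0),
                     float(var1), float(var0), float(mean1 - mean0), deg1, deg0)


def best_split(
    X: Mapping[str, np.ndarray] | "pd.DataFrame",
    y: np.ndarray,
    w: np.ndarray,
    cfg: FitConfig,
    p: float,
    feature_names: Sequence[str] | None = None,
) -> SplitCandidate | None:
    """Exhaustive best admissible split of one node, or None.

    Scans every feature (in catalog order) and every midpoint between
    adjacent distinct observed values; keeps candidates whose children
    each hold >= min_per_arm patients of each arm; returns the candidate
    maximizing the children's EMSE criterion, requiring positive gain
    over the unsplit node.  Ties resolve to the earlier feature, then
    the smaller threshold.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=int)
    n = len(y)
    m = cfg.min_per_arm
    if (w == 1).sum() < 2 * m or (w == 0).sum() < 2 * m:
        return None
    if feature_names is None:
        feature_names = list(X.keys()) if isinstance(X, Mapping) else list(X.columns)

    parent = leaf_stats(y, w)
    parent_crit = emse_criterion([parent], n, p)

    w1 = (w == 1).astype(float)
    w0 = 1.0 - w1
    best: SplitCandidate | None = None
    best_key: tuple[float, int, float] | None = None  # (-gain, feat_idx, threshold)

    for fi, name in enumerate(feature_names):
        x = np.asarray(X[name], dtype=float)
        if np.isnan(x).all():
            logger.warning("feature %s all-missing in node; skipped", name)
            continue
        order = np.argsort(x, kind="mergesort")
        xs, ys = x[order], y[order]
        w1s, w0s = w1[order], w0[order]
        cuts = np.nonzero(xs[1:] > xs[:-1])[0]  # split after position i
        if len(cuts) == 0:
            continue
        c1 = np.cumsum(w1s)
        c0 = np.cumsum(w0s)
        s1 = np.cumsum(w1s * ys)
        s0 = np.cumsum(w0s * ys)
        q1 = np.cumsum(w1s * ys * ys)
        q0 = np.cumsum(w0s * ys * ys)
        n1L, n0L = c1[cuts], c0[cuts]
        n1R, n0R = c1[-1] - n1L, c0[-1] - n0L
        ok = (n1L >= m) & (n0L >= m) & (n1R >= m) & (n0R >= m)
        if not ok.any():
            continue
        k = cuts[ok]
        n1L, n0L, n1R, n0R = n1L[ok], n0L[ok], n1R[ok], n0R[ok]
        s1L, s0L, q1L, q0L = s1[k], s0[k], q1[k], q0[k]
        s1R, s0R = s1[-1] - s1L, s0[-1] - s0L
        q1R, q0R = q1[-1] - q1L, q0[-1] - q0L

        def _crit(n1, n0, s1_, s0_, q1_, q0_):
            tau = s1_ / n1 - s0_ / n0
            var1 = np.where(n1 >= 2, np.maximum(0.0, (q1_ - s1_**2 / n1) / np.maximum(n1 - 1, 1)), 0.0)
            var0 = np.where(n0 >= 2, np.maximum(0.0, (q0_ - s0_**2 / n0) / np.maximum(n0 - 1, 1)), 0.0)
            return (n1 + n0) * tau**2 / n - (2.0 / n) * (var1 / p + var0 / (1.0 - p))

        crit = _crit(n1L, n0L, s1L, s0L, q1L, q0L) + _crit(n1R, n0R, s1R, s0R, q1R, q0R)
        gains = crit - parent_crit
        j = int(np.argmax(gains))  # first (smallest-threshold) max within feature
        if gains[j] <= 0.0:
            continue
        thr = float((xs[k[j]] + xs[k[j] + 1]) / 2.0)
        key = (-float(gains[j]), fi, thr)
        if best_key is None or key < best_key:
            mask_low = x < thr
            best = SplitCandidate(
                feature=name,
                threshold=thr,
                gain=float(gains[j]),
                left_stats=leaf_stats(y[mask_low], w[mask_low]),
                right_stats=leaf_stats(y[~mask_low], w[~mask_low]),
            )
            best_key = key
    return best


# ---------------------------------------------------------------------------
# growing


def _check_complete(X: "pd.DataFrame") -> None:
    na = X.isna()
    if na.to_numpy().any():
        bad = [c for c in X.columns if na[c].any()]
        raise FitError(f"covariates with missing values at fit time: {bad}")


def grow_tree(ds: TrialDataset, cfg: FitConfig) -> CausalTree:
    """Grow the maximal tree by recursive depth-first splitting."""
    if ds.delta_ppfvc is None:
        raise FitError("outcome (delta_ppfvc) not computed")
    X = ds.covariates
    _check_complete(X)
    y = np.asarray(ds.delta_ppfvc, dtype=float)
    w = np.asarray(ds.arm, dtype=int)
    feature_names = [s.name for s in ds.catalog]
    return _grow(X, y, w, cfg, feature_names)


def _grow(X, y, w, cfg: FitConfig, feature_names) -> CausalTree:
    n1, n0 = int((w == 1).sum()), int((w == 0).sum())
    if n1 < cfg.min_per_arm or n0 < cfg.min_per_arm:
        raise FitError(
            f"too few patients per arm (treated {n1}, control {n0}, "
            f"minimum {cfg.min_per_arm})"
        )
    p = n1 / (n1 + n0)
    counter = [0]

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        node = TreeNode(id=counter[0], stats=leaf_stats(y[idx], w[idx]))
        counter[0] += 1
        if cfg.max_depth is not None and depth >= cfg.max_depth:
            return node
        sub = {name: X[name].to_numpy(float)[idx] for name in feature_names}
        cand = best_split(sub, y[idx], w[idx], cfg, p, feature_names)
        if cand is None:
            return node
        node.feature = cand.feature
        node.threshold = cand.threshold
        xvals = X[cand.feature].to_numpy(float)[idx]
        low_idx = idx[xvals < cand.threshold]
        high_idx = idx[xvals >= cand.threshold]
        node.high = build(high_idx, depth + 1)
        node.low = build(low_idx, depth + 1)
        return node

    root = build(np.arange(len(y)), 0)
    tree = CausalTree(root=root, n_train=len(y), p_treated=p, config=cfg)
    _label_leaves(tree)
    return tree


def _label_leaves(tree: CausalTree) -> None:
    for k, leaf in enumerate(tree.root.leaves(), start=1):
        leaf.leaf_label = k


# ---------------------------------------------------------------------------
# transformed outcome and pruning


def transformed_outcome(y: Sequence[float], w: Sequence[int], p: float) -> np.ndarray:
    """Per-patient unbiased effect proxy y* = w y/p - (1-w) y/(1-p)."""
    if not 0.0 < p < 1.0:
        raise ValidationError(f"treated share p must be in (0,1), got {p}")
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    return w * y / p - (1.0 - w) * y / (1.0 - p)


def _subtree_risk_and_leaves(node: TreeNode, n_total: int, p: float) -> tuple[float, int]:
    if node.is_leaf:
        return -_leaf_criterion(node.stats, n_total, p), 1
    rh, lh = _subtree_risk_and_leaves(node.high, n_total, p)
    rl, ll = _subtree_risk_and_leaves(node.low, n_total, p)
    return rh + rl, lh + ll


def cost_complexity_path(tree: CausalTree) -> list[tuple[float, CausalTree]]:
    """Weakest-link pruning sequence [(alpha, subtree)], alpha strictly increasing.

    Node risk is the negated EMSE criterion of its leaf set (additive over
    leaves at the fixed training size).  The sequence starts at the full
    tree (alpha 0) and ends at the root-only tree.
    """
    n_total, p = tree.n_train, tree.p_treated
    current = tree.root.copy()
    path: list[tuple[float, CausalTree]] = []

    def snapshot(alpha: float) -> None:
        if path:  # alphas must strictly increase (ties collapse in one step)
            alpha = max(alpha, float(np.nextafter(path[-1][0], np.inf)))
        sub = CausalTree(
            root=current.copy(), n_train=n_total, p_treated=p, config=tree.config
        )
        _label_leaves(sub)
        path.append((alpha, sub))

    snapshot(0.0)
    while not current.is_leaf:
        links: list[tuple[float, TreeNode]] = []
        for node in current.internal_nodes():
            r_leaf = -_leaf_criterion(node.stats, n_total, p)
            r_sub, n_leaves = _subtree_risk_and_leaves(node, n_total, p)
            links.append(((r_leaf - r_sub) / (n_leaves - 1), node))
        alpha = min(g for g, _ in links)
        # collapse every link at (numerically) the minimal alpha; repeat for
        # ancestors whose g drops to alpha after the collapse
        changed = True
        while changed:
            changed = False
            for node in list(current.internal_nodes()):
                r_leaf = -_leaf_criterion(node.stats, n_total, p)
                r_sub, n_leaves = _subtree_risk_and_leaves(node, n_total, p)
                g = (r_leaf - r_sub) / (n_leaves - 1)
                if g <= alpha + 1e-12 * (1.0 + abs(alpha)):
                    node.feature = None
                    node.threshold = None
                    node.low = None
                    node.high = None
                    changed = True
        snapshot(max(alpha, 0.0))
    return path


def prune_at_alpha(path: list[tuple[float, CausalTree]], alpha: float) -> CausalTree:
    """Smallest subtree on the path optimal at the given penalty."""
    chosen = path[0][1]
    for a, sub in path:
        if a <= alpha + 1e-12 * (1.0 + abs(alpha)):
            chosen = sub
        else:
            break
    return chosen


def _alpha_grid(path: list[tuple[float, CausalTree]]) -> list[float]:
    alphas = [a for a, _ in path]
    if len(alphas) == 1:
        return [0.0]
    grid = [math.sqrt(alphas[k] * alphas[k + 1]) for k in range(len(alphas) - 1)]
    grid.append(alphas[-1])
    return grid


def _predict_tau(root: TreeNode, X: "pd.DataFrame", idx: np.ndarray) -> np.ndarray:
    cols = {name: X[name].to_numpy(float) for name in X.columns}
    out = np.empty(len(idx), dtype=float)
    for k, i in enumerate(idx):
        node = root
        while not node.is_leaf:
            node = node.low if cols[node.feature][i] < node.threshold else node.high
        out[k] = node.stats.tau_hat
    return out


def _stratified_folds(w: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    fold = np.empty(len(w), dtype=int)
    for arm in (0, 1):
        idx = np.nonzero(w == arm)[0]
        if len(idx) < n_folds:
            raise ValidationError(
                f"n_folds {n_folds} exceeds arm-{arm} size {len(idx)}"
            )
        perm = rng.permutation(idx)
        fold[perm] = np.arange(len(perm)) % n_folds
    return fold


def cv_select_alpha(
    ds: TrialDataset,
    cfg: FitConfig,
    tree: CausalTree | None = None,
) -> tuple[float, list[tuple[float, float]]]:
    """Cross-validated complexity selection.

    Folds are stratified by arm with ``cfg.seed``.  Per fold, a tree is
    grown on the training folds; each alpha on the master grid (geometric
    means of consecutive path alphas of the full-data tree) is scored by
    the validation transformed-outcome squared error against the training
    subtree's leaf effects.  Returns the alpha minimizing the CV risk
    normalized by the root-only CV risk (ties -> largest alpha) together
    with the (alpha, normalized risk) curve.
    """
    if ds.delta_ppfvc is None:
        raise FitError("outcome (delta_ppfvc) not computed")
    y = np.asarray(ds.delta_ppfvc, dtype=float)
    w = np.asarray(ds.arm, dtype=int)
    X = ds.covariates
    feature_names = [s.name for s in ds.catalog]
    if tree is None:
        tree = grow_tree(ds, cfg)
    master_path = cost_complexity_path(tree)
    grid = _alpha_grid(master_path)
    if len(grid) == 1:
        return grid[0], [(grid[0], 1.0)]

    folds = _stratified_folds(w, cfg.n_folds, cfg.seed)
    risk = np.zeros(len(grid))
    risk_root = 0.0
    for f in range(cfg.n_folds):
        tr = np.nonzero(folds != f)[0]
        va = np.nonzero(folds == f)[0]
        if len(np.unique(w[va])) < 2 or len(np.unique(w[tr])) < 2:
            raise FitError(f"fold {f} contains a single arm")
        ds_tr_X = X.iloc[tr].reset_index(drop=True)
        fold_tree = _grow(ds_tr_X, y[tr], w[tr], cfg, feature_names)
        fold_path = cost_complexity_path(fold_tree)
        p_tr = fold_tree.p_treated
        ystar = transformed_outcome(y[va], w[va], p_tr)
        for gi, alpha in enumerate(grid):
            sub = prune_at_alpha(fold_path, alpha)
            tau = _predict_tau(sub.root, X, va)
            risk[gi] += float(np.sum((ystar - tau) ** 2))
        root_tau = fold_tree.root.stats.tau_hat
        risk_root += float(np.sum((ystar - root_tau) ** 2))
    if risk_root <= 0.0:
        risk_root = 1.0
    curve = [(float(a), float(r / risk_root)) for a, r in zip(grid, risk)]
    best = min(risk)
    # ties -> largest alpha (simplest tree among minimizers)
    sel = max(a for a, r in zip(grid, risk) if r <= best * (1.0 + 1e-12))
    return float(sel), curve


# ---------------------------------------------------------------------------
# full fit


def _route_index(root: TreeNode, X: "pd.DataFrame", idx: np.ndarray) -> dict[int, list[int]]:
    cols = {name: X[name].to_numpy(float) for name in X.columns}
    buckets: dict[int, list[int]] = {}
    for i in idx:
        node = root
        while not node.is_leaf:
            node = node.low if cols[node.feature][i] < node.threshold else node.high
        buckets.setdefault(node.id, []).append(int(i))
    return buckets


def _reestimate(root: TreeNode, X, y, w, idx: np.ndarray) -> None:
    buckets = _route_index(root, X, idx)
    for leaf in root.leaves():
        got = buckets.get(leaf.id, [])
        ww = w[got] if got else np.array([], dtype=int)
        if len(got) == 0 or (ww == 1).sum() == 0 or (ww == 0).sum() == 0:
            raise FitError(
                "honest estimation sample leaves a terminal node without both arms"
            )
        leaf.stats = leaf_stats(y[got], w[got])


def fit_causal_tree(ds: TrialDataset, cfg: FitConfig | None = None) -> CausalTree:
    """Grow, build the cost-complexity path, CV-select alpha, prune, estimate.

    ``estimate_mode='full_sample'`` reports leaf effects on all patients
    reaching the leaf; ``'honest_half'`` learns the structure on an
    arm-stratified half and re-estimates leaf effects on the other half.
    """
    cfg = cfg or FitConfig()
    if ds.delta_ppfvc is None:
        raise FitError("outcome (delta_ppfvc) not computed")
    _check_complete(ds.covariates)

    if cfg.estimate_mode == "honest_half":
        w = np.asarray(ds.arm, dtype=int)
        rng = np.random.default_rng(cfg.seed)
        struct_idx: list[int] = []
        est_idx: list[int] = []
        for arm in (0, 1):
            idx = rng.permutation(np.nonzero(w == arm)[0])
            half = len(idx) // 2
            struct_idx += list(idx[:half])
            est_idx += list(idx[half:])
        struct_idx = np.sort(np.asarray(struct_idx))
        est_idx = np.sort(np.asarray(est_idx))
        sub = TrialDataset(
            patient_id=tuple(ds.patient_id[i] for i in struct_idx),
            arm=w[struct_idx],
            ppfvc=ds.ppfvc.iloc[struct_idx].reset_index(drop=True),
            covariates=ds.covariates.iloc[struct_idx].reset_index(drop=True),
            catalog=ds.catalog,
            delta_ppfvc=np.asarray(ds.delta_ppfvc)[struct_idx],
        )
        tree = grow_tree(sub, cfg)
        alpha, curve = cv_select_alpha(sub, cfg, tree)
        pruned = prune_at_alpha(cost_complexity_path(tree), alpha)
        _reestimate(
            pruned.root, ds.covariates, np.asarray(ds.delta_ppfvc, float), w, est_idx
        )
    else:
        tree = grow_tree(ds, cfg)
        alpha, curve = cv_select_alpha(ds, cfg, tree)
        pruned = prune_at_alpha(cost_complexity_path(tree), alpha)

    pruned.alpha_selected = float(alpha)
    pruned.cv_curve = curve
    pruned.config = cfg
    _label_leaves(pruned)
    return pruned


# ---------------------------------------------------------------------------
# routing, rules, serialization


def assign_leaf(tree: CausalTree, record: Mapping[str, float]) -> int:
    """Route one covariate record to its leaf label (>= threshold goes high)."""
    node = tree.root
    while not node.is_leaf:
        if node.feature not in record:
            raise ValidationError(f"record missing routed feature {node.feature!r}")
        v = record[node.feature]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValidationError(f"record missing routed feature {node.feature!r}")
        node = node.low if v < node.threshold else node.high
    return node.leaf_label


def _welch_ci(st: LeafStats, level: float = 0.95) -> tuple[float, float]:
    from scipy import stats as sps

    if st.var1 == 0.0 and st.var0 == 0.0:
        return st.tau_hat, st.tau_hat
    se2 = st.var1 / st.n1 + st.var0 / st.n0
    se = math.sqrt(se2)
    df = se2**2 / (
        (st.var1 / st.n1) ** 2 / max(st.n1 - 1, 1)
        + (st.var0 / st.n0) ** 2 / max(st.n0 - 1, 1)
    )
    tcrit = sps.t.ppf(0.5 + level / 2.0, df)
    return st.tau_hat - tcrit * se, st.tau_hat + tcrit * se


def _leaf_conditions(tree: CausalTree) -> dict[int, list[tuple[str, str, float]]]:
    """Per leaf-label list of (feature, op, threshold) with merged intervals."""
    out: dict[int, list[tuple[str, str, float]]] = {}

    def walk(node: TreeNode, lo: dict[str, float], hi: dict[str, float]) -> None:
        if node.is_leaf:
            conds: list[tuple[str, str, float]] = []
            for f in sorted(set(lo) | set(hi)):
                if f in lo:
                    conds.append((f, ">=", lo[f]))
                if f in hi:
                    conds.append((f, "<", hi[f]))
            out[node.leaf_label] = conds
            return
        lo2 = dict(lo)
        lo2[node.feature] = max(lo.get(node.feature, -math.inf), node.threshold)
        walk(node.high, lo2, hi)
        hi2 = dict(hi)
        hi2[node.feature] = min(hi.get(node.feature, math.inf), node.threshold)
        walk(node.low, lo, hi2)

    walk(tree.root, {}, {})
    return out


def _fmt_num(v: float) -> str:
    return format(v, "g")


def tree_to_rules(tree: CausalTree) -> tuple[list[dict], str]:
    """Per-leaf rule records and the tree's JSON text.

    Each record: leaf_label, rule (conjunction string), n1, n0, tau,
    ci_low, ci_high.  The JSON round-trips through
    :func:`tree_from_json` with identical routing.
    """
    conds = _leaf_conditions(tree)
    rules = []
    for leaf in tree.root.leaves():
        cs = conds[leaf.leaf_label]
        rule = " and ".join(f"{f} {op} {_fmt_num(t)}" for f, op, t in cs) or "(all patients)"
        lo, hi = _welch_ci(leaf.stats)
        rules.append(
            {
                "leaf_label": leaf.leaf_label,
                "rule": rule,
                "conditions": [(f, op, t) for f, op, t in cs],
                "n1": leaf.stats.n1,
                "n0": leaf.stats.n0,
                "tau": leaf.stats.tau_hat,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return rules, tree_to_json(tree)


def rules_text(tree: CausalTree) -> str:
    """One line per leaf: 'Leaf k: <rule> | n=<n1>+<n0> | effect=<tau> (lo, hi)'."""
    rules, _ = tree_to_rules(tree)
    lines = [
        "Leaf {leaf_label}: {rule} | n={n1}+{n0} | effect={tau:.2f} ({ci_low:.2f}, {ci_high:.2f})".format(**r)
        for r in rules
    ]
    return "\n".join(lines) + "\n"


def tree_to_json(tree: CausalTree) -> str:
    nodes = []

    def walk(node: TreeNode) -> None:
        lo, hi = _welch_ci(node.stats)
        rec = {
            "id": node.id,
            "type": "leaf" if node.is_leaf else "split",
            "feature": node.feature,
            "threshold": node.threshold,
            "children": None if node.is_leaf else [node.low.id, node.high.id],
            "n1": node.stats.n1,
            "n0": node.stats.n0,
            "mean1": node.stats.mean1,
            "mean0": node.stats.mean0,
            "var1": node.stats.var1,
            "var0": node.stats.var0,
            "tau": node.stats.tau_hat,
            "ci_low": lo,
            "ci_high": hi,
            "leaf_label": node.leaf_label,
        }
        nodes.append(rec)
        if not node.is_leaf:
            walk(node.low)
            walk(node.high)

    walk(tree.root)
    doc = {
        "n_train": tree.n_train,
        "p_treated": tree.p_treated,
        "alpha_selected": tree.alpha_selected,
        "config": asdict(tree.config),
        "nodes": nodes,
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def tree_from_json(text: str) -> CausalTree:
    doc = json.loads(text)
    by_id = {rec["id"]: rec for rec in doc["nodes"]}

    def build(rec: dict) -> TreeNode:
        stats = LeafStats(
            n1=rec["n1"], n0=rec["n0"], mean1=rec["mean1"], mean0=rec["mean0"],
            var1=rec["var1"], var0=rec["var0"], tau_hat=rec["tau"],
        )
        node = TreeNode(id=rec["id"], stats=stats, leaf_label=rec["leaf_label"])
        if rec["type"] == "split":
            node.feature = rec["feature"]
            node.threshold = rec["threshold"]
            low_id, high_id = rec["children"]
            node.low = build(by_id[low_id])
            node.high = build(by_id[high_id])
        return node

    root = build(doc["nodes"][0])
    cfg = FitConfig(**doc["config"])
    return CausalTree(
        root=root,
        n_train=doc["n_train"],
        p_treated=doc["p_treated"],
        config=cfg,
        alpha_selected=doc["alpha_selected"],
    )
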