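"""Exact Shapley values and pairwise Shapley interaction values for
gradient-boosted tree ensembles.

The conditional expectation ``v(S) = E[f(x) | x_S]`` is evaluated per tree by
path-dependent traversal: at a split on a feature inside the coalition S the
branch is chosen by the instance, otherwise both children are averaged with
their training-cover weights.  Because a single tree depends only on the
features it actually splits on, the coalition lattice is enumerated per tree
over that (small) used-feature set, and Shapley values / interaction values
are accumulated across trees by linearity.

Conventions follow the additive decomposition

    f(x) = phi0 + sum_i sum_j Phi_ij(x),

with a symmetric interaction matrix whose off-diagonal entries are the
pairwise Shapley interaction values (split equally between (i, j) and
(j, i)) and whose diagonal holds the pure main effects
``Phi_ii = phi_i - sum_{j != i} Phi_ij``.  Row sums of Phi recover the
total per-feature Shapley values phi_i, and the whole matrix sums to
``f(x) - phi0`` exactly — the additivity contract asserted throughout the
test-suite.

Supported models: xgboost (XGBClassifier/XGBRegressor), lightgbm
(LGBMClassifier/LGBMRegressor) and sklearn GradientBoosting models.  The
per-class baseline offset is recovered empirically by comparing raw tree
sums against the model's own margin output and verified to be constant.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import factorial
import numpy as np

from .errors import CapabilityError, DomainError

__all__ = ["TreeEnsemble", "ShapDecomposition", "extract_ensemble", "shap_interactions"]

_MAX_USED_FEATURES = 16  # 2^16 coalitions per tree is the enumeration ceiling


@dataclass
class _Tree:
    """Flat arrays for one regression tree."""

    left: np.ndarray      # child ids, -1 at leaves
    right: np.ndarray
    feature: np.ndarray   # split feature, -1 at leaves
    threshold: np.ndarray
    value: np.ndarray     # leaf contribution (0 at internal nodes)
    cover: np.ndarray     # training weight per node
    strict: bool          # True: go left when x <  threshold (xgboost)
                          # False: go left when x <= threshold (lightgbm, sklearn)
    cast32: bool = False  # xgboost and sklearn trees compare features in
                          # float32; lightgbm compares raw doubles

    def go_left(self, xcol: np.ndarray, node: int) -> np.ndarray:
        x = xcol.astype(np.float32) if self.cast32 else xcol
        thr = np.float32(self.threshold[node]) if self.strict else self.threshold[node]
        return x < thr if self.strict else x <= thr


@dataclass
class TreeEnsemble:
    """Trees grouped by output class plus the per-class margin intercept."""

    trees: list[list[_Tree]]   # [class][tree]
    intercepts: np.ndarray     # (n_classes,)
    n_features: int

    @property
    def n_classes(self) -> int:
        return len(self.trees)

    def margin(self, X: np.ndarray) -> np.ndarray:
        """Raw margin per class computed from the extracted trees."""
        X = np.asarray(X, dtype=float)
        out = np.tile(self.intercepts, (X.shape[0], 1))
        for c, trees in enumerate(self.trees):
            for t in trees:
                out[:, c] += _predict_tree(t, X)
        return out


def _predict_tree(t: _Tree, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    for r in range(X.shape[0]):
        i = 0
        while t.feature[i] >= 0:
            left = bool(t.go_left(X[r : r + 1, t.feature[i]], i)[0])
            i = t.left[i] if left else t.right[i]
        out[r] = t.value[i]
    return out


# ---------------------------------------------------------------------------
# model extraction

def _from_xgboost(model) -> tuple[list[list[_Tree]], int]:
    booster = model.get_booster()
    dumps = booster.get_dump(dump_format="json", with_stats=True)
    cfg = json.loads(booster.save_config())
    n_classes = int(
        cfg["learner"]["learner_model_param"].get("num_class", "0") or 0
    )
    groups = max(n_classes, 1)

    def build(node_json) -> _Tree:
        nodes: dict[int, dict] = {}

        def walk(nd):
            nodes[nd["nodeid"]] = nd
            for ch in nd.get("children", []):
                walk(ch)

        walk(node_json)
        size = max(nodes) + 1
        left = np.full(size, -1, dtype=np.int64)
        right = np.full(size, -1, dtype=np.int64)
        feat = np.full(size, -1, dtype=np.int64)
        thr = np.zeros(size)
        val = np.zeros(size)
        cov = np.zeros(size)
        for nid, nd in nodes.items():
            cov[nid] = nd.get("cover", 1.0)
            if "leaf" in nd:
                val[nid] = nd["leaf"]
            else:
                feat[nid] = int(str(nd["split"]).lstrip("f"))
                thr[nid] = nd["split_condition"]
                left[nid] = nd["yes"]
                right[nid] = nd["no"]
        return _Tree(left, right, feat, thr, val, cov, strict=True, cast32=True)

    trees: list[list[_Tree]] = [[] for _ in range(groups)]
    for i, d in enumerate(dumps):
        trees[i % groups].append(build(json.loads(d)))
    return trees, groups


def _from_lightgbm(model) -> tuple[list[list[_Tree]], int]:
    booster = model.booster_ if hasattr(model, "booster_") else model
    dump = booster.dump_model()
    groups = int(dump.get("num_tree_per_iteration", 1))

    def build(root: dict) -> _Tree:
        nodes: list[dict] = []

        def walk(nd) -> int:
            my = len(nodes)
            nodes.append({})
            if "leaf_value" in nd and "split_feature" not in nd:
                nodes[my] = {
                    "leaf": nd["leaf_value"],
                    "cover": nd.get("leaf_count", 1),
                }
            else:
                li = walk(nd["left_child"])
                ri = walk(nd["right_child"])
                nodes[my] = {
                    "feature": nd["split_feature"],
                    "threshold": nd["threshold"],
                    "left": li,
                    "right": ri,
                    "cover": nd.get("internal_count", 1),
                }
            return my

        walk(root)
        size = len(nodes)
        left = np.full(size, -1, dtype=np.int64)
        right = np.full(size, -1, dtype=np.int64)
        feat = np.full(size, -1, dtype=np.int64)
        thr = np.zeros(size)
        val = np.zeros(size)
        cov = np.zeros(size)
        for i, nd in enumerate(nodes):
            cov[i] = nd["cover"]
            if "leaf" in nd:
                val[i] = nd["leaf"]
            else:
                feat[i] = nd["feature"]
                thr[i] = nd["threshold"]
                left[i] = nd["left"]
                right[i] = nd["right"]
        return _Tree(left, right, feat, thr, val, cov, strict=False)

    trees: list[list[_Tree]] = [[] for _ in range(groups)]
    for info in dump["tree_info"]:
        st = info["tree_structure"]
        if "split_feature" not in st and "leaf_value" not in st:
            # constant tree: lightgbm encodes it with 'leaf_value' at root
            st = {"leaf_value": st.get("leaf_const", 0.0)}
        trees[info["tree_index"] % groups].append(build(st))
    return trees, groups


def _from_sklearn_gbm(model) -> tuple[list[list[_Tree]], int]:
    ests = model.estimators_  # (n_stages, n_groups)
    groups = ests.shape[1]
    lr = model.learning_rate
    trees: list[list[_Tree]] = [[] for _ in range(groups)]
    for stage in ests:
        for c, est in enumerate(stage):
            t = est.tree_
            trees[c].append(
                _Tree(
                    t.children_left.astype(np.int64),
                    t.children_right.astype(np.int64),
                    t.feature.astype(np.int64),
                    t.threshold.copy(),
                    np.where(t.children_left == -1, t.value[:, 0, 0] * lr, 0.0),
                    t.weighted_n_node_samples.copy(),
                    strict=False,
                    cast32=True,
                )
            )
    return trees, groups


def _raw_margin(model, X: np.ndarray) -> np.ndarray:
    mod = type(model).__module__
    if mod.startswith("xgboost"):
        m = model.predict(X, output_margin=True)
    elif mod.startswith("lightgbm"):
        m = model.predict(X, raw_score=True)
    elif hasattr(model, "decision_function"):
        m = model.decision_function(X)
    elif hasattr(model, "predict"):
        m = model.predict(X)
    else:  # pragma: no cover
        raise CapabilityError(f"cannot obtain a margin from {type(model).__name__}")
    m = np.asarray(m, dtype=float)
    return m[:, None] if m.ndim == 1 else m


def extract_ensemble(model, X_check: np.ndarray | None = None) -> TreeEnsemble:
    """Convert a fitted GBDT into the unified array representation.

    The per-class intercept is the (verified constant) difference between the
    model's margin and the raw sum of extracted tree contributions.
    """
    mod = type(model).__module__
    if mod.startswith("xgboost"):
        trees, groups = _from_xgboost(model)
    elif mod.startswith("lightgbm"):
        trees, groups = _from_lightgbm(model)
    elif hasattr(model, "estimators_") and hasattr(model, "learning_rate"):
        trees, groups = _from_sklearn_gbm(model)
    else:
        raise CapabilityError(
            f"{type(model).__name__} is not a supported tree ensemble"
        )
    n_features = int(getattr(model, "n_features_in_", 0))
    if X_check is None:
        X_check = np.zeros((2, n_features))
    X_check = np.asarray(X_check, dtype=float)[:8]
    margins = _raw_margin(model, X_check)
    raw = np.zeros((X_check.shape[0], groups))
    for c in range(groups):
        for t in trees[c]:
            raw[:, c] += _predict_tree(t, X_check)
    diff = margins - raw
    # the library accumulates leaves in float32, so the per-row offset is
    # constant only up to float32 rounding noise
    spread = np.abs(diff - diff.mean(axis=0)).max() if diff.size else 0.0
    if spread > 1e-4:
        raise DomainError(
            f"tree extraction inconsistent with model margin (spread {spread:.2e})"
        )
    ens = TreeEnsemble(trees, diff.mean(axis=0), n_features or X_check.shape[1])
    return ens


# ---------------------------------------------------------------------------
# Shapley computation

def _subset_values(t: _Tree, X: np.ndarray, used: np.ndarray) -> np.ndarray:
    """v(S, x) for every coalition S over this tree's used features.

    Returns an (n_rows, 2**u) array; column ``mask`` holds the
    path-dependent conditional expectation with exactly the features whose
    bits are set in ``mask`` revealed.
    """
    u = used.size
    local = {f: i for i, f in enumerate(used)}
    n = X.shape[0]
    out = np.empty((n, 1 << u))
    for mask in range(1 << u):
        def rec(node: int) -> np.ndarray:
            f = t.feature[node]
            if f < 0:
                return np.full(n, t.value[node])
            lo, hi = t.left[node], t.right[node]
            if (mask >> local[f]) & 1:
                return np.where(t.go_left(X[:, f], node), rec(lo), rec(hi))
            wl = t.cover[lo] / (t.cover[lo] + t.cover[hi])
            return wl * rec(lo) + (1.0 - wl) * rec(hi)

        out[:, mask] = rec(0)
    return out


def _shapley_weights(u: int) -> tuple[np.ndarray, np.ndarray]:
    """W1[|S|] for values and W2[|S|] for pairwise interactions (u players)."""
    w1 = np.array(
        [factorial(s) * factorial(u - s - 1) / factorial(u) for s in range(u)]
    )
    if u >= 2:
        w2 = np.array(
            [
                factorial(s) * factorial(u - s - 2) / (2.0 * factorial(u - 1))
                for s in range(u - 1)
            ]
        )
    else:
        w2 = np.zeros(0)
    return w1, w2


@dataclass
class ShapDecomposition:
    """Additive decomposition of per-row margins for one output class.

    ``interactions[r]`` is symmetric with pure main effects on the diagonal;
    ``phi0 + interactions[r].sum()`` equals the model margin ``margins[r]``.
    """

    phi0: float
    values: np.ndarray        # (n, d) total per-feature Shapley values
    interactions: np.ndarray  # (n, d, d)
    margins: np.ndarray       # (n,)

    def additivity_residual(self) -> float:
        recon = self.phi0 + self.interactions.sum(axis=(1, 2))
        return float(np.abs(recon - self.margins).max())


def shap_interactions(
    ensemble: TreeEnsemble, X: np.ndarray, class_index: int = 0
) -> ShapDecomposition:
    """Exact Shapley values and interaction values for one margin surface."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    phi = np.zeros((n, d))
    inter = np.zeros((n, d, d))
    phi0 = float(ensemble.intercepts[class_index])
    for t in ensemble.trees[class_index]:
        used = np.unique(t.feature[t.feature >= 0])
        u = used.size
        if u == 0:  # constant tree contributes only to the baseline
            phi0 += float(t.value[t.feature < 0][0]) if t.value.size else 0.0
            continue
        if u > _MAX_USED_FEATURES:
            raise DomainError(
                f"tree uses {u} distinct features; exact interaction "
                f"enumeration is capped at {_MAX_USED_FEATURES}"
            )
        v = _subset_values(t, X, used)
        phi0 += float(v[0, 0])  # v(empty) is row-independent
        w1, w2 = _shapley_weights(u)
        bits = [1 << i for i in range(u)]
        sizes = np.array([bin(m).count("1") for m in range(1 << u)])
        for m in range(1 << u):
            sz = sizes[m]
            wm = w1[sz] if sz < u else 0.0
            for i in range(u):
                if not (m >> i) & 1 and sz < u:
                    phi[:, used[i]] += wm * (v[:, m | bits[i]] - v[:, m])
        if u >= 2:
            for i in range(u):
                for j in range(i + 1, u):
                    bi, bj = bits[i], bits[j]
                    rest = [m for m in range(1 << u) if not (m & bi) and not (m & bj)]
                    gi, gj = used[i], used[j]
                    for m in rest:
                        contrib = w2[sizes[m]] * (
                            v[:, m | bi | bj] - v[:, m | bi] - v[:, m | bj] + v[:, m]
                        )
                        inter[:, gi, gj] += contrib
                        inter[:, gj, gi] += contrib
    # pure main effects on the diagonal: phi_i minus interaction row sums
    offdiag = inter.sum(axis=2)
    for i in range(d):
        inter[:, i, i] = phi[:, i] - offdiag[:, i]
    margins = ensemble.margin(X)[:, class_index]
    return ShapDecomposition(phi0, phi, inter, margins)


def shap_values_for_model(
    model, X: np.ndarray, class_index: int = 0
) -> ShapDecomposition:
    """Convenience wrapper: extract the ensemble, then decompose."""
    ens = extract_ensemble(model, X_check=X[:8])
    return shap_interactions(ens, X, class_index=class_index)
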