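"""From-scratch CART binary classification trees.

Greedy axis-aligned recursive partitioning with the Gini criterion,
count-weighted impurity decrease, Mean-Decrease-in-Gini feature importance,
and cross-validated depth selection.  Everything is deterministic given the
inputs and the documented tie rule: when two candidate splits yield the same
impurity decrease, the lower feature index wins, then the smaller threshold.

Routing semantics are ``value < threshold -> left``, ``value >= threshold ->
right``, so a printed boundary like 7.4 behaves as "7.4 or larger goes to
the positive branch".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreeParams",
    "TreeNode",
    "TreeModel",
    "gini_impurity",
    "best_split",
    "grow_tree",
    "predict",
    "select_depth_by_cv",
    "rule_classifier",
    "AMW_THRESHOLD",
    "MLOGP_THRESHOLD",
]

#: Decision thresholds of the published screening rule.
AMW_THRESHOLD = 7.4
MLOGP_THRESHOLD = -0.454


def gini_impurity(class_counts: Sequence[int]) -> float:
    """Binary Gini impurity ``1 - p+^2 - p-^2`` for ``(n_pos, n_neg)``.

    0 for a pure node, 0.5 at a 50/50 mix.  Raises on an empty node.
    """
    n_pos, n_neg = class_counts
    total = n_pos + n_neg
    if total <= 0:
        raise ValueError("cannot compute impurity of an empty node")
    p_pos = n_pos / total
    p_neg = n_neg / total
    return 1.0 - p_pos * p_pos - p_neg * p_neg


@dataclass(frozen=True)
class TreeParams:
    """Stopping/complexity parameters.

    ``min_rel_decrease`` is the count-weighted impurity decrease of a split
    divided by the root node's count-weighted impurity (a relative
    complexity parameter); defaults mirror the classic CART reference
    implementation: min_split 20, min_leaf 7, relative decrease 0.01.
    """

    max_depth: int | None = None
    min_split: int = 20
    min_leaf: int = 7
    min_rel_decrease: float = 0.01

    def with_depth(self, depth: int | None) -> "TreeParams":
        return TreeParams(depth, self.min_split, self.min_leaf, self.min_rel_decrease)


@dataclass
class TreeNode:
    """One node of the binary tree (leaf iff no split feature/children)."""

    class_counts: tuple[int, int]
    gini: float
    split_feature: str | None = None
    feature_index: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_feature is None

    @property
    def predicted_class(self) -> int:
        """Majority class, ties broken toward the positive (DILI) class."""
        return 1 if self.class_counts[0] >= self.class_counts[1] else 0

    def to_dict(self) -> dict:
        d = {
            "counts": list(self.class_counts),
            "gini": self.gini,
        }
        if not self.is_leaf:
            d["feature"] = self.split_feature
            d["feature_index"] = self.feature_index
            d["threshold"] = self.threshold
            d["children"] = [self.left.to_dict(), self.right.to_dict()]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(tuple(d["counts"]), d["gini"])
        if "feature" in d:
            node.split_feature = d["feature"]
            node.feature_index = d["feature_index"]
            node.threshold = d["threshold"]
            node.left = cls.from_dict(d["children"][0])
            node.right = cls.from_dict(d["children"][1])
        return node


@dataclass
class TreeModel:
    root: TreeNode
    feature_names: list[str]
    params: TreeParams
    importance: dict[str, float] = field(default_factory=dict)

    def depth(self) -> int:
        def _d(node: TreeNode) -> int:
            if node.is_leaf:
                return 0
            return 1 + max(_d(node.left), _d(node.right))

        return _d(self.root)

    def n_leaves(self) -> int:
        def _n(node: TreeNode) -> int:
            if node.is_leaf:
                return 1
            return _n(node.left) + _n(node.right)

        return _n(self.root)

    # -- lossless JSON round-trip ------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "root": self.root.to_dict(),
                "feature_names": self.feature_names,
                "params": {
                    "max_depth": self.params.max_depth,
                    "min_split": self.params.min_split,
                    "min_leaf": self.params.min_leaf,
                    "min_rel_decrease": self.params.min_rel_decrease,
                },
                "importance": self.importance,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TreeModel":
        d = json.loads(text)
        return cls(
            root=TreeNode.from_dict(d["root"]),
            feature_names=list(d["feature_names"]),
            params=TreeParams(**d["params"]),
            importance=dict(d["importance"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "TreeModel":
        return cls.from_json(Path(path).read_text())


def _as_matrix(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns) if feature_names is None else list(feature_names)
        missing = [n for n in names if n not in X.columns]
        if missing:
            raise KeyError(f"missing feature column(s): {', '.join(missing)}")
        values = X[names].to_numpy(dtype=float)
    else:
        values = np.asarray(X, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        names = (
            list(feature_names)
            if feature_names is not None
            else [f"x{i}" for i in range(values.shape[1])]
        )
    if len(names) != values.shape[1]:
        raise ValueError("feature_names length does not match matrix width")
    if len(set(names)) != len(names):
        raise ValueError("feature names must be unique")
    return values, names


def best_split(
    X,
    y,
    candidate_features: Sequence[int] | None = None,
    min_leaf: int = 1,
    feature_names=None,
) -> tuple[int, float, float] | None:
    """Exhaustive search for the best axis-aligned split.

    Candidate thresholds are the midpoints between consecutive distinct
    sorted values of each feature; the returned decrease is the
    count-weighted Gini decrease ``n*G - nL*GL - nR*GR``.  Returns ``None``
    when no split yields a positive decrease or size constraints forbid all
    splits (in particular for pure nodes and constant features).
    """
    values, _ = _as_matrix(X, feature_names)
    yv = np.asarray(y, dtype=int)
    n = yv.shape[0]
    if n < 2:
        return None
    if np.isnan(values).any():
        raise ValueError("NaN among feature values used for splitting")
    n_pos = int(yv.sum())
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    parent = n * gini_impurity((n_pos, n_neg))

    features = (
        range(values.shape[1]) if candidate_features is None else candidate_features
    )
    best: tuple[int, float, float] | None = None  # (fi, threshold, decrease)
    for fi in features:
        col = values[:, fi]
        order = np.argsort(col, kind="stable")
        vs = col[order]
        ys = yv[order]
        boundaries = np.nonzero(vs[1:] != vs[:-1])[0]
        if boundaries.size == 0:
            continue
        n_left = boundaries + 1
        n_right = n - n_left
        ok = (n_left >= min_leaf) & (n_right >= min_leaf)
        if not ok.any():
            continue
        boundaries = boundaries[ok]
        n_left = n_left[ok]
        n_right = n_right[ok]
        pos_left = np.cumsum(ys)[boundaries]
        pos_right = n_pos - pos_left
        gini_left = 1.0 - (pos_left / n_left) ** 2 - ((n_left - pos_left) / n_left) ** 2
        gini_right = (
            1.0 - (pos_right / n_right) ** 2 - ((n_right - pos_right) / n_right) ** 2
        )
        decrease = parent - n_left * gini_left - n_right * gini_right
        j = int(np.argmax(decrease))  # first max -> smallest threshold
        if decrease[j] <= 0:
            continue
        thr = 0.5 * (vs[boundaries[j]] + vs[boundaries[j] + 1])
        if best is None or decrease[j] > best[2]:
            best = (fi, float(thr), float(decrease[j]))
    return best


def grow_tree(X, y, params: TreeParams | None = None, feature_names=None) -> TreeModel:
    """Fit a CART model by greedy recursive partitioning.

    Deterministic given the inputs (sample order does not matter under the
    stable tie rule).  Per-feature importance is the sum of count-weighted
    impurity decreases of that feature's splits, normalized by the number of
    training samples (Mean Decrease in Gini).
    """
    params = params or TreeParams()
    values, names = _as_matrix(X, feature_names)
    yv = np.asarray(y, dtype=int)
    if values.shape[0] == 0:
        raise ValueError("empty training set")
    if values.shape[0] != yv.shape[0]:
        raise ValueError("X and y length mismatch")
    if np.isnan(values).any():
        raise ValueError("NaN among feature values used for splitting")
    if not np.isin(yv, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")

    n_root = values.shape[0]
    counts_root = (int(yv.sum()), int(n_root - yv.sum()))
    root_weighted_impurity = n_root * gini_impurity(counts_root)
    importance = {name: 0.0 for name in names}

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        sub_y = yv[idx]
        n = idx.shape[0]
        counts = (int(sub_y.sum()), int(n - sub_y.sum()))
        node = TreeNode(counts, gini_impurity(counts))
        if (
            counts[0] == 0
            or counts[1] == 0
            or n < params.min_split
            or (params.max_depth is not None and depth >= params.max_depth)
        ):
            return node
        found = best_split(values[idx], sub_y, min_leaf=params.min_leaf)
        if found is None:
            return node
        fi, thr, decrease = found
        if (
            root_weighted_impurity > 0
            and decrease / root_weighted_impurity < params.min_rel_decrease
        ):
            return node
        importance[names[fi]] += decrease / n_root
        node.split_feature = names[fi]
        node.feature_index = fi
        node.threshold = thr
        go_left = values[idx, fi] < thr
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[~go_left], depth + 1)
        return node

    root = build(np.arange(n_root), 0)
    return TreeModel(root=root, feature_names=names, params=params, importance=importance)


def predict(model: TreeModel, X) -> np.ndarray:
    """Route samples through the tree (``< threshold`` left, ``>=`` right)
    and emit each leaf's majority class (ties -> positive)."""
    values, _ = _as_matrix(X, model.feature_names)

    def route(row) -> int:
        node = model.root
        while not node.is_leaf:
            node = node.left if row[node.feature_index] < node.threshold else node.right
        return node.predicted_class

    return np.array([route(row) for row in values], dtype=int)


def select_depth_by_cv(
    X,
    y,
    depth_grid: Sequence[int],
    k: int = 5,
    seed: int = 0,
    params: TreeParams | None = None,
    score: str = "balanced_accuracy",
    feature_names=None,
) -> tuple[int, pd.DataFrame]:
    """Choose ``max_depth`` by stratified k-fold cross-validation.

    For each depth the mean validation score (balanced accuracy by default,
    ``score='accuracy'`` to switch) over k stratified folds is computed; the
    depth with the highest mean wins, ties going to the smallest depth.
    Returns ``(chosen_depth, table)`` with per-depth/per-fold scores.
    """
    from .protocols import stratified_split  # local import to avoid a cycle

    if k < 2:
        raise ValueError("k must be >= 2")
    if not depth_grid:
        raise ValueError("empty depth grid")
    values, names = _as_matrix(X, feature_names)
    yv = np.asarray(y, dtype=int)
    params = params or TreeParams()

    plan = stratified_split(yv, k, seed)
    rows = []
    means: dict[int, float] = {}
    for depth in depth_grid:
        fold_scores = []
        for fold in range(k):
            test_mask = plan.assignments == fold
            if yv[test_mask].min(initial=1) == yv[test_mask].max(initial=0):
                raise ValueError(
                    "a validation fold lacks one of the classes; use fewer folds"
                )
            model = grow_tree(
                values[~test_mask],
                yv[~test_mask],
                params.with_depth(depth),
                feature_names=names,
            )
            pred = predict(model, values[test_mask])
            truth = yv[test_mask]
            tp = int(((pred == 1) & (truth == 1)).sum())
            tn = int(((pred == 0) & (truth == 0)).sum())
            fp = int(((pred == 1) & (truth == 0)).sum())
            fn = int(((pred == 0) & (truth == 1)).sum())
            if score == "accuracy":
                s = (tp + tn) / truth.shape[0]
            elif score == "balanced_accuracy":
                s = 0.5 * (tp / (tp + fn) + tn / (tn + fp))
            else:
                raise ValueError(f"unknown score {score!r}")
            fold_scores.append(s)
            rows.append({"depth": depth, "fold": fold, "score": s})
        means[depth] = float(np.mean(fold_scores))

    best_depth = max(sorted(means), key=lambda d: (means[d], -d))
    table = pd.DataFrame(rows)
    table["mean_score"] = table["depth"].map(means)
    return best_depth, table


def rule_classifier(
    amw_value: float,
    mlogp_value: float | None = None,
    amw_threshold: float = AMW_THRESHOLD,
    mlogp_threshold: float = MLOGP_THRESHOLD,
    strict_two_class: bool = False,
) -> str:
    """The published two-node screening rule.

    ``AMW >= 7.4`` -> positive; ``AMW < 7.4 and MLOGP < -0.454`` -> negative;
    otherwise indeterminate.  In strict two-class mode indeterminate maps to
    negative (equivalent to screening on AMW alone).
    """
    if not np.isfinite(amw_value):
        raise ValueError("AMW must be finite")
    if amw_value >= amw_threshold:
        return "positive"
    if (
        mlogp_value is not None
        and np.isfinite(mlogp_value)
        and mlogp_value < mlogp_threshold
    ):
        return "negative"
    return "negative" if strict_two_class else "indeterminate"
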