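"""Validation machinery: stratified splitting, the nested 3-group/10-repeat
protocol, and final-model construction with inner 5-fold CV.

Seed discipline: one global seed spawns a documented chain of per-repeat and
per-fold sub-seeds via ``numpy.random.SeedSequence``, so any single run can
be re-derived in isolation and identical seeds give bitwise-identical
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cart import TreeModel, TreeParams, grow_tree, predict, select_depth_by_cv
from .metrics import ConfusionMatrix, MetricsReport, confusion, eq_metrics

__all__ = [
    "SplitPlan",
    "ProtocolResult",
    "stratified_split",
    "nested_cv",
    "final_model",
    "load_protocol_config",
    "DEFAULT_DEPTH_GRID",
]

DEFAULT_DEPTH_GRID: tuple[int, ...] = (1, 2, 3, 4, 5)


@dataclass
class SplitPlan:
    """Assignment of samples to k stratified groups."""

    assignments: np.ndarray  # sample -> group index in [0, k)
    k: int
    seed: int

    def group_indices(self, group: int) -> np.ndarray:
        return np.nonzero(self.assignments == group)[0]

    def class_proportions(self, y) -> list[float]:
        yv = np.asarray(y)
        return [
            float(yv[self.assignments == g].mean()) for g in range(self.k)
        ]


def stratified_split(y, k: int, seed: int) -> SplitPlan:
    """Randomly partition samples into k groups preserving the class
    proportion (within-class shuffle, round-robin assignment).

    Each group's positive count is within one sample of ``n_pos / k``.
    Raises if either class has fewer than k members.
    """
    yv = np.asarray(y, dtype=int)
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))
    assignments = np.empty(yv.shape[0], dtype=int)
    for cls in (1, 0):
        idx = np.nonzero(yv == cls)[0]
        if k > 1 and idx.size < k:
            raise ValueError(
                f"class {cls} has only {idx.size} members; cannot make {k} "
                "stratified groups — use fewer folds"
            )
        shuffled = rng.permutation(idx)
        assignments[shuffled] = np.arange(shuffled.size) % k
    return SplitPlan(assignments=assignments, k=k, seed=int(seed))


def _summaries(values: Sequence[float]) -> dict[str, float]:
    arr = np.asarray([v for v in values if v is not None], dtype=float)
    if arr.size == 0:
        return {}
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "min": float(arr.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "max": float(arr.max()),
    }


_METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "balanced_accuracy", "mcc")


@dataclass
class RunRecord:
    repeat: int
    fold: int
    depth: int
    train: MetricsReport
    test: MetricsReport
    n_train: int
    n_test: int


@dataclass
class ProtocolResult:
    runs: list[RunRecord]
    split_plans: list[SplitPlan] = field(default_factory=list)

    def summary(self) -> dict[str, dict[str, dict[str, float]]]:
        """Per-metric dispersion summaries, separately for train and test;
        the reported means are the arithmetic means of the stored per-run
        values and are recomputable from ``runs``."""
        out: dict[str, dict[str, dict[str, float]]] = {"train": {}, "test": {}}
        for side in ("train", "test"):
            for name in _METRIC_NAMES:
                vals = [getattr(getattr(r, side), name) for r in self.runs]
                out[side][name] = _summaries(vals)
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.runs:
            row = {"repeat": r.repeat, "fold": r.fold, "depth": r.depth,
                   "n_train": r.n_train, "n_test": r.n_test}
            for side in ("train", "test"):
                for name in _METRIC_NAMES:
                    row[f"{side}_{name}"] = getattr(getattr(r, side), name)
            rows.append(row)
        return pd.DataFrame(rows)

    def as_dict(self) -> dict:
        return {
            "runs": self.to_frame().to_dict(orient="records"),
            "summary": self.summary(),
        }


def _seed_for(seed: int, *path: int) -> int:
    """Derive a deterministic sub-seed for (repeat, fold, stage...)."""
    return int(
        np.random.SeedSequence([int(seed), *map(int, path)]).generate_state(1)[0]
    )


def nested_cv(
    X,
    y,
    repeats: int = 10,
    outer_k: int = 3,
    inner_k: int = 5,
    depth_grid: Sequence[int] = DEFAULT_DEPTH_GRID,
    seed: int = 0,
    params: TreeParams | None = None,
    score: str = "balanced_accuracy",
    feature_names=None,
    verbose: bool = False,
) -> ProtocolResult:
    """Nested cross-validation: per repeat a fresh stratified outer split;
    per outer fold, tree depth is chosen by inner stratified CV on the
    training pair, the tree is refit at that depth, and metrics are computed
    on both the training pair and the held-out group.  ``verbose`` logs
    progress to stderr at fold granularity."""
    import sys
    yv = np.asarray(y, dtype=int)
    params = params or TreeParams()
    runs: list[RunRecord] = []
    plans: list[SplitPlan] = []

    for rep in range(repeats):
        plan = stratified_split(yv, outer_k, _seed_for(seed, rep, 0))
        plans.append(plan)
        for fold in range(outer_k):
            test_mask = plan.assignments == fold
            X_arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
            names = list(X.columns) if isinstance(X, pd.DataFrame) else feature_names
            X_train, y_train = X_arr[~test_mask], yv[~test_mask]
            X_test, y_test = X_arr[test_mask], yv[test_mask]

            depth, _ = select_depth_by_cv(
                X_train,
                y_train,
                depth_grid,
                k=inner_k,
                seed=_seed_for(seed, rep, fold + 1),
                params=params,
                score=score,
                feature_names=names,
            )
            model = grow_tree(X_train, y_train, params.with_depth(depth), feature_names=names)
            train_metrics = eq_metrics(confusion(y_train, predict(model, X_train)))
            test_metrics = eq_metrics(confusion(y_test, predict(model, X_test)))
            if verbose:
                print(
                    f"nested-cv repeat {rep + 1}/{repeats} fold {fold + 1}/"
                    f"{outer_k}: depth={depth} "
                    f"test_ba={test_metrics.balanced_accuracy}",
                    file=sys.stderr,
                )
            runs.append(
                RunRecord(
                    repeat=rep,
                    fold=fold,
                    depth=depth,
                    train=train_metrics,
                    test=test_metrics,
                    n_train=int((~test_mask).sum()),
                    n_test=int(test_mask.sum()),
                )
            )
    return ProtocolResult(runs=runs, split_plans=plans)


def final_model(
    X,
    y,
    inner_k: int = 5,
    depth_grid: Sequence[int] = DEFAULT_DEPTH_GRID,
    seed: int = 0,
    params: TreeParams | None = None,
    score: str = "balanced_accuracy",
    feature_names=None,
) -> dict:
    """Construct the final model on all data with CV-chosen depth.

    Returns a dict with the fitted :class:`TreeModel`, the chosen depth,
    resubstitution confusion matrix and metrics (evaluated on all data), and
    the per-fold CV metrics at the chosen depth — both explicitly labeled.
    """
    yv = np.asarray(y, dtype=int)
    params = params or TreeParams()
    X_arr = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, dtype=float)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else feature_names

    if yv.min() == yv.max():
        # pure labels: no split possible and no CV constructible
        model = grow_tree(X_arr, yv, params.with_depth(0), feature_names=names)
        cm = confusion(yv, predict(model, X_arr))
        return {
            "model": model,
            "depth": 0,
            "depth_cv_table": None,
            "resubstitution": {"confusion": cm, "metrics": eq_metrics(cm)},
            "cv": None,
        }

    depth, cv_table = select_depth_by_cv(
        X_arr, yv, depth_grid, k=inner_k, seed=_seed_for(seed, 0, 0),
        params=params, score=score, feature_names=names,
    )
    model = grow_tree(X_arr, yv, params.with_depth(depth), feature_names=names)
    cm = confusion(yv, predict(model, X_arr))

    # CV aggregate at the chosen depth, from held-out fold predictions.
    plan = stratified_split(yv, inner_k, _seed_for(seed, 0, 0))
    cv_cms: list[ConfusionMatrix] = []
    for fold in range(inner_k):
        mask = plan.assignments == fold
        fold_model = grow_tree(
            X_arr[~mask], yv[~mask], params.with_depth(depth), feature_names=names
        )
        cv_cms.append(confusion(yv[mask], predict(fold_model, X_arr[mask])))
    pooled = cv_cms[0]
    for c in cv_cms[1:]:
        pooled = pooled + c

    return {
        "model": model,
        "depth": depth,
        "depth_cv_table": cv_table,
        "resubstitution": {"confusion": cm, "metrics": eq_metrics(cm)},
        "cv": {"confusion": pooled, "metrics": eq_metrics(pooled)},
    }


def load_protocol_config(path: str | Path) -> dict:
    """Parse a ``key = value`` protocol configuration file.

    Recognized keys: repeats, outer_k, inner_k, depth_grid (comma-separated
    integers), seed, score.  Unknown keys raise.
    """
    allowed = {"repeats", "outer_k", "inner_k", "depth_grid", "seed", "score"}
    out: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ValueError(f"{path}: line {lineno}: expected 'key = value'")
        key, _, value = stripped.partition("=")
        key, value = key.strip(), value.strip()
        if key not in allowed:
            raise ValueError(f"{path}: line {lineno}: unknown key {key!r}")
        if key == "depth_grid":
            out[key] = tuple(int(v) for v in value.split(",") if v.strip())
        elif key == "score":
            out[key] = value
        else:
            out[key] = int(value)
    return out
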