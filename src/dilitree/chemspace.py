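"""Chemical-space comparison: descriptor filtering and PCA scores.

Mirrors the classic caret/prcomp pipeline: drop near-zero-variance columns,
drop exact linear combinations, then mean-centered (optionally scaled) PCA
with a fixed sign convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterLog",
    "PCAResult",
    "near_zero_variance_filter",
    "linear_combination_filter",
    "pca",
]


@dataclass
class FilterLog:
    """One dropped feature and the rule that dropped it."""

    feature: str
    rule: str

    def as_line(self) -> str:
        return f"{self.feature}\t{self.rule}"


def _named_matrix(X, feature_names=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D feature matrix")
    names = (
        list(feature_names)
        if feature_names is not None
        else [f"x{i}" for i in range(arr.shape[1])]
    )
    return arr, names


def near_zero_variance_filter(
    X,
    freq_ratio_max: float = 19.0,
    unique_pct_min: float = 10.0,
    feature_names=None,
) -> tuple[list[str], list[FilterLog]]:
    """Drop constant columns and columns that are both highly imbalanced
    (most-frequent / second-most-frequent count ratio above
    ``freq_ratio_max``) and low-cardinality (percent distinct below
    ``unique_pct_min``).  Defaults are the 95/5 -> 19 ratio and 10% unique
    cutoffs of the reference implementation.  Idempotent."""
    arr, names = _named_matrix(X, feature_names)
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    kept: list[str] = []
    dropped: list[FilterLog] = []
    for j, name in enumerate(names):
        col = arr[:, j]
        values, counts = np.unique(col, return_counts=True)
        if values.size <= 1:
            dropped.append(FilterLog(name, "zero variance"))
            continue
        top2 = np.sort(counts)[::-1][:2]
        freq_ratio = top2[0] / top2[1]
        unique_pct = 100.0 * values.size / n
        if freq_ratio > freq_ratio_max and unique_pct < unique_pct_min:
            dropped.append(
                FilterLog(
                    name,
                    f"near-zero variance (freq ratio {freq_ratio:.3g}, "
                    f"unique {unique_pct:.3g}%)",
                )
            )
            continue
        kept.append(name)
    return kept, dropped


def linear_combination_filter(
    X, tol: float = 1e-8, feature_names=None
) -> tuple[list[str], list[FilterLog]]:
    """Iteratively drop columns that are exact linear combinations of
    earlier-kept columns (Gram-Schmidt residual test at relative tolerance
    ``tol``); the surviving matrix has full column rank.  Idempotent."""
    arr, names = _named_matrix(X, feature_names)
    kept: list[str] = []
    dropped: list[FilterLog] = []
    basis: list[np.ndarray] = []  # orthonormal
    for j, name in enumerate(names):
        col = arr[:, j].astype(float)
        norm = np.linalg.norm(col)
        residual = col.copy()
        for q in basis:
            residual -= (q @ residual) * q
        # re-orthogonalize once for numerical robustness
        for q in basis:
            residual -= (q @ residual) * q
        res_norm = np.linalg.norm(residual)
        if res_norm <= tol * max(norm, 1.0):
            dropped.append(FilterLog(name, "linear combination of earlier columns"))
            continue
        basis.append(residual / res_norm)
        kept.append(name)
    return kept, dropped


@dataclass
class PCAResult:
    scores: np.ndarray            # n_samples x n_components
    loadings: np.ndarray          # n_features x n_components
    explained_variance: np.ndarray        # full spectrum, length min(n-1?, p)
    explained_fraction: np.ndarray        # full spectrum; sums to 1
    center: np.ndarray
    scale: np.ndarray | None
    feature_names: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def scores_frame(self, index=None) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.scores, columns=cols, index=index)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_components)]
        return pd.DataFrame(self.loadings, columns=cols, index=self.feature_names)


def pca(X, n_components: int | None = None, scale: bool = False, feature_names=None) -> PCAResult:
    """Principal component scores via SVD of the column-centered matrix.

    No variance scaling by default (pass ``scale=True`` to divide by column
    standard deviations).  Deterministic up to sign, fixed by making each
    loading vector's largest-magnitude entry positive.  Variances are the
    usual ``n - 1`` denominators and the explained fractions over the full
    spectrum sum to 1.
    """
    arr, names = _named_matrix(X, feature_names)
    n, p = arr.shape
    max_comp = min(n, p)
    if n_components is None:
        n_components = max_comp
    if not (1 <= n_components <= max_comp):
        raise ValueError(
            f"n_components must be in [1, {max_comp}], got {n_components}"
        )
    center = arr.mean(axis=0)
    centered = arr - center
    scale_vec = None
    if scale:
        scale_vec = centered.std(axis=0, ddof=1)
        if np.any(scale_vec == 0):
            raise ValueError("cannot scale: zero-variance column present")
        centered = centered / scale_vec

    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # sign convention: largest-|entry| of each loading vector is positive
    for i in range(vt.shape[0]):
        pivot = np.argmax(np.abs(vt[i]))
        if vt[i, pivot] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0

    variances = s**2 / max(n - 1, 1)
    total = variances.sum()
    fractions = variances / total if total > 0 else np.zeros_like(variances)
    scores = u[:, :n_components] * s[:n_components]
    return PCAResult(
        scores=scores,
        loadings=vt[:n_components].T,
        explained_variance=variances,
        explained_fraction=fractions,
        center=center,
        scale=scale_vec,
        feature_names=names,
    )
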