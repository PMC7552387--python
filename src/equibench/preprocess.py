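"""Data cleaning, standardization, feature selection and row normalization.

Standardization uses the population (ddof=0) standard deviation, and the
transform fitted on training samples is re-applied unchanged to held-out
samples so that no statistic leaks from test folds. Feature selection offers
the two score functions used for expression matrices in this pipeline:
per-feature one-way ANOVA F between outcome classes (label-aware, computed on
training folds only) and mean absolute deviation about the feature mean
(label-free, dataset-level).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from sklearn.feature_selection import f_classif


@dataclass(frozen=True)
class FeatureSelection:
    """Result of a top-k feature screen.

    ``selected_indices`` are ordered by descending score, ties broken by
    ascending feature position, so the selection is deterministic.
    """

    selected_indices: np.ndarray
    scores: np.ndarray
    method: Literal["anova_f", "mad"]

    def __post_init__(self):
        idx = np.asarray(self.selected_indices)
        if idx.ndim != 1:
            raise ValueError("selected_indices must be one-dimensional")


@dataclass
class Standardizer:
    """Per-feature location/scale transform fitted on training data."""

    means: np.ndarray
    sds: np.ndarray
    zero_variance: np.ndarray = field(default=None)  # boolean flag per feature

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        safe_sd = np.where(self.zero_variance, 1.0, self.sds)
        Z = (X - self.means) / safe_sd
        Z[:, self.zero_variance] = 0.0
        return Z


def filter_samples(X: np.ndarray, max_missing_fraction: float) -> np.ndarray:
    """Boolean row mask keeping samples whose missing fraction is at most
    ``max_missing_fraction``; rows strictly above the cutoff are dropped."""
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    X = np.asarray(X, dtype=float)
    missing_frac = np.mean(np.isnan(X), axis=1)
    mask = missing_frac <= max_missing_fraction
    if not mask.any():
        raise ValueError("sample filter removed every row")
    return mask


def fit_standardizer(X_train: np.ndarray) -> Standardizer:
    X_train = np.asarray(X_train, dtype=float)
    means = X_train.mean(axis=0)
    sds = X_train.std(axis=0, ddof=0)
    zero_var = sds == 0.0
    return Standardizer(means=means, sds=sds, zero_variance=zero_var)


def standardize(X_train: np.ndarray, X_apply: np.ndarray | None = None):
    """Zero-mean / unit-sd columns fitted on ``X_train``; the same transform
    is applied to ``X_apply``. Zero-variance training features map to zeros
    (flagged on the returned Standardizer).

    Returns ``(Z_train, Z_apply, standardizer)``; ``Z_apply`` is None when no
    apply matrix is given.
    """
    st = fit_standardizer(X_train)
    Z_train = st.transform(X_train)
    Z_apply = st.transform(X_apply) if X_apply is not None else None
    return Z_train, Z_apply, st


def _topk(scores: np.ndarray, k: int, method) -> FeatureSelection:
    n = scores.shape[0]
    if not 0 < k <= n:
        raise ValueError(f"k={k} out of range for {n} features")
    # sort by (-score, index): descending score, ties by ascending position
    order = np.lexsort((np.arange(n), -scores))
    return FeatureSelection(selected_indices=order[:k].copy(), scores=scores, method=method)


def select_anova_f(X_train: np.ndarray, y_train: np.ndarray, k: int) -> FeatureSelection:
    """Top-k features by one-way ANOVA F between label classes, computed on
    training samples only."""
    y_train = np.asarray(y_train)
    if np.unique(y_train).size < 2:
        raise ValueError("ANOVA F selection needs both outcome classes in y_train")
    F, _ = f_classif(np.asarray(X_train, dtype=float), y_train)
    F = np.nan_to_num(F, nan=0.0)
    return _topk(F, k, "anova_f")


def select_mad(X: np.ndarray, k: int) -> FeatureSelection:
    """Top-k features by mean absolute deviation about the feature mean.

    Label-free, so it may use all samples of a dataset.
    """
    X = np.asarray(X, dtype=float)
    mad = np.mean(np.abs(X - X.mean(axis=0)), axis=0)
    return _topk(mad, k, "mad")


def l2_normalize_rows(X: np.ndarray) -> np.ndarray:
    """Scale every sample (row) to unit Euclidean norm, sum_j x_ij^2 = 1."""
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    bad = np.flatnonzero(norms == 0.0)
    if bad.size:
        raise ValueError(f"cannot L2-normalize all-zero sample row(s) {bad.tolist()}")
    return X / norms[:, None]
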