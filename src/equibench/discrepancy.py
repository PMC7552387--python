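"""Marginal and conditional distribution discrepancy between two groups.

Marginal (P(X)) discrepancy is quantified by the fraction of features called
differentially expressed by a permutation t-test between the groups.
Conditional (P(Y|X)) discrepancy is quantified by fitting one multivariate
logistic regression per group and correlating the two coefficient vectors:
a low Pearson r means a feature's association with the outcome differs
between groups even if the feature distributions match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression


@dataclass
class DiscrepancyReport:
    de_fraction: float
    de_pvalues: np.ndarray
    beta_group1: np.ndarray
    beta_group2: np.ndarray
    pearson_r: float

    def __post_init__(self):
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if len(self.beta_group1) != len(self.beta_group2):
            raise ValueError("coefficient vectors must have equal length")


def _welch_t(X: np.ndarray, mask1: np.ndarray, pooled: bool = False) -> np.ndarray:
    """Two-sample t statistic per feature (column); Welch by default."""
    A, B = X[mask1], X[~mask1]
    na, nb = A.shape[0], B.shape[0]
    ma, mb = A.mean(axis=0), B.mean(axis=0)
    va, vb = A.var(axis=0, ddof=1), B.var(axis=0, ddof=1)
    if pooled:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        se = np.sqrt(va / na + vb / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / se
    return np.nan_to_num(t, nan=0.0, posinf=0.0, neginf=0.0)


def permutation_ttest(
    X: np.ndarray,
    group: np.ndarray,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    pooled: bool = False,
):
    """Permutation-based two-sample t-test per feature.

    One permutation matrix of group labels is shared across all features, so
    identical features receive identical p-values. The smoothed p-value is
    ``(1 + #{|t*| >= |t|}) / (1 + B)``.

    Returns ``(pvalues, de_mask)`` with ``de_mask = pvalues < alpha``.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    X = np.asarray(X, dtype=float)
    group = np.asarray(group)
    groups = np.unique(group)
    if groups.size != 2:
        raise ValueError("permutation t-test requires exactly two groups")
    mask1 = group == groups[0]
    if mask1.sum() < 2 or (~mask1).sum() < 2:
        raise ValueError("each group needs at least two samples")
    rng = np.random.default_rng() if rng is None else rng

    t_obs = np.abs(_welch_t(X, mask1, pooled=pooled))
    exceed = np.zeros(X.shape[1], dtype=int)
    for _ in range(n_permutations):
        perm_mask = np.zeros(X.shape[0], dtype=bool)
        perm_mask[rng.permutation(X.shape[0])[: mask1.sum()]] = True
        exceed += np.abs(_welch_t(X, perm_mask, pooled=pooled)) >= t_obs
    pvalues = (1.0 + exceed) / (1.0 + n_permutations)
    return pvalues, pvalues < alpha


def group_logistic(X: np.ndarray, y: np.ndarray, group: np.ndarray):
    """One multivariate logistic regression per group on all features.

    Fits use a small L2 (ridge) penalty for identifiability when features
    outnumber samples. Returns the two coefficient vectors (intercept
    excluded) in group-id order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    group = np.asarray(group)
    coefs = []
    for k in np.unique(group):
        mask = group == k
        yk = y[mask]
        if np.unique(yk).size < 2:
            raise ValueError(f"group {k} has a single outcome class; logistic fit undefined")
        # default L2 penalty with large C == the small ridge (~1e-4) we want
        model = LogisticRegression(C=1e4, solver="lbfgs", max_iter=2000)
        model.fit(X[mask], yk)
        coefs.append(model.coef_.ravel().copy())
    if len(coefs) != 2:
        raise ValueError("expected exactly two groups")
    return coefs[0], coefs[1]


def coefficient_correlation(beta1: np.ndarray, beta2: np.ndarray) -> float:
    """Pearson correlation between two coefficient vectors."""
    beta1 = np.asarray(beta1, dtype=float)
    beta2 = np.asarray(beta2, dtype=float)
    if beta1.shape != beta2.shape or beta1.ndim != 1 or beta1.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 entries")
    if np.std(beta1) == 0 or np.std(beta2) == 0:
        raise ValueError("Pearson correlation undefined for a constant vector")
    return float(stats.pearsonr(beta1, beta2).statistic)


def discrepancy_report(
    X: np.ndarray,
    y: np.ndarray,
    group: np.ndarray,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> DiscrepancyReport:
    """Full two-group discrepancy summary (DE fraction + coefficient r)."""
    pvalues, de_mask = permutation_ttest(X, group, n_permutations, alpha, rng=rng)
    b1, b2 = group_logistic(X, y, group)
    return DiscrepancyReport(
        de_fraction=float(de_mask.mean()),
        de_pvalues=pvalues,
        beta_group1=b1,
        beta_group2=b2,
        pearson_r=coefficient_correlation(b1, b2),
    )
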