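"""Synthetic two-group labeled expression cohorts.

The generator produces a cohort of two ancestry groups with three controllable
properties:

* **data inequality** — unequal group sizes ``n1`` (majority) vs ``n2``
  (minority);
* **marginal discrepancy** — ``n_de`` differentially expressed features whose
  group-2 mean is shifted by a fold change on the count scale, so the groups
  differ in P(X);
* **conditional discrepancy** — per-group effect vectors ``beta1, beta2`` with
  entries in {-1, +1}; labels are thresholded logistic scores
  ``z = sigmoid(sum_j beta_j^k x_ij)``, so the groups differ in P(Y|X)
  wherever the two vectors disagree.

Features are negative-binomial counts with log-normal baseline means,
log2(count+1)-transformed and standardized; labels are balanced within each
group by thresholding z at a per-group quantile (default the median).
``estimate_params_from_cohort`` inverts the construction: group sizes are read
off directly, ``n_de`` from a permutation t-test between groups, and the four
beta sign-combination counts from per-group multivariate logistic fits
dichotomized at the median coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import standardize

# Parameters of the four simulated study conditions: group sizes, count of
# differentially expressed features, and the four beta sign-combination counts
# (n_mm, n_mp, n_pm, n_pp) over 200 features. Datasets 1-2 have data
# inequality (2184 vs 320); datasets 1 and 3 have distribution discrepancy
# (20 DE features and 74 discordant beta positions).
STUDY_CONDITIONS = {
    1: dict(n1=2184, n2=320, n_de=20, beta_counts=(64, 37, 37, 62)),
    2: dict(n1=2184, n2=320, n_de=0, beta_counts=(100, 0, 0, 100)),
    3: dict(n1=260, n2=260, n_de=20, beta_counts=(64, 37, 37, 62)),
    4: dict(n1=260, n2=260, n_de=0, beta_counts=(100, 0, 0, 100)),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """All generator parameters for a two-group synthetic cohort.

    ``beta_counts`` gives the number of features with effect-sign combination
    (beta1, beta2) equal to (-1,-1), (-1,+1), (+1,-1), (+1,+1) in that order;
    the four counts must sum to ``n_features``. ``class_quantile`` is the
    quantile of the per-group logistic score used as the labeling threshold
    c^k (0.5 gives balanced classes).
    """

    n1: int
    n2: int
    n_features: int = 200
    n_de: int = 20
    beta_counts: tuple[int, int, int, int] = (64, 37, 37, 62)
    de_fold_change: float = 2.0
    dispersion: float = 0.1
    class_quantile: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes n1, n2 must be >= 1")
        if not 0 <= self.n_de <= self.n_features:
            raise ValueError(f"n_de={self.n_de} must be in [0, n_features={self.n_features}]")
        if len(self.beta_counts) != 4 or any(c < 0 for c in self.beta_counts):
            raise ValueError("beta_counts must be four non-negative counts")
        if sum(self.beta_counts) != self.n_features:
            raise ValueError(
                f"beta_counts sum to {sum(self.beta_counts)}, expected n_features={self.n_features}"
            )
        if self.de_fold_change <= 0:
            raise ValueError("de_fold_change must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 < self.class_quantile < 1:
            raise ValueError("class_quantile must lie strictly between 0 and 1")


def study_config(dataset: int, seed: int = 0, **overrides) -> SyntheticConfig:
    """SyntheticConfig for one of the four predefined study conditions."""
    params = dict(STUDY_CONDITIONS[dataset])
    params.update(overrides)
    return SyntheticConfig(seed=seed, **params)


@dataclass(frozen=True)
class BetaPair:
    """Per-feature effect signs for the two groups, entries in {-1, +1}."""

    beta1: np.ndarray
    beta2: np.ndarray

    def __post_init__(self):
        b1 = np.asarray(self.beta1)
        b2 = np.asarray(self.beta2)
        if b1.shape != b2.shape or b1.ndim != 1:
            raise ValueError("beta1 and beta2 must be 1-d vectors of equal length")
        for b in (b1, b2):
            if not np.isin(b, (-1, 1)).all():
                raise ValueError("beta entries must be -1 or +1")

    def combination_counts(self) -> tuple[int, int, int, int]:
        """Counts of (beta1, beta2) = (-1,-1), (-1,+1), (+1,-1), (+1,+1)."""
        b1, b2 = np.asarray(self.beta1), np.asarray(self.beta2)
        return (
            int(np.sum((b1 == -1) & (b2 == -1))),
            int(np.sum((b1 == -1) & (b2 == 1))),
            int(np.sum((b1 == 1) & (b2 == -1))),
            int(np.sum((b1 == 1) & (b2 == 1))),
        )


@dataclass
class Cohort:
    """Standardized feature matrix with binary outcome and group membership.

    Labels are in {-1, +1}; group ids in {1, 2}. ``truth`` optionally carries
    generator ground truth (DE feature indices, BetaPair, thresholds, config).
    """

    X: np.ndarray
    y: np.ndarray
    group: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]
    truth: dict | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.group = np.asarray(self.group, dtype=int)
        n, p = self.X.shape
        if not (len(self.y) == len(self.group) == n):
            raise ValueError("X rows, y and group must have equal length")
        if len(self.feature_ids) != p or len(self.sample_ids) != n:
            raise ValueError("identifier lists do not match matrix dimensions")
        if not np.isin(self.y, (-1, 1)).all():
            raise ValueError("labels must be -1 or +1")
        if not np.isin(self.group, (1, 2)).all():
            raise ValueError("group ids must be 1 or 2")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


# log-normal baseline for per-feature mean counts (natural-log scale)
_LOG_MEAN = 5.0
_LOG_SD = 1.0


def _nb_counts(mean: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Negative-binomial counts via gamma-Poisson mixing; Poisson at phi=0."""
    if dispersion == 0.0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def simulate_features(config: SyntheticConfig, rng: np.random.Generator):
    """Simulate the (n1+n2) x n_features expression matrix on the log scale.

    Exactly ``n_de`` randomly chosen features have their group-2 mean count
    multiplied (or divided, direction random per feature) by
    ``de_fold_change``; all other features are identically distributed across
    groups. Returns ``(X_log, group, de_indices)`` where X_log is
    log2(count+1)-transformed but not yet standardized.
    """
    n = config.n1 + config.n2
    p = config.n_features
    group = np.concatenate([np.ones(config.n1, int), np.full(config.n2, 2, int)])

    base_mean = np.exp(rng.normal(_LOG_MEAN, _LOG_SD, size=p))
    de_indices = np.sort(rng.choice(p, size=config.n_de, replace=False))
    up = rng.random(config.n_de) < 0.5
    factor = np.where(up, config.de_fold_change, 1.0 / config.de_fold_change)

    mean2 = base_mean.copy()
    mean2[de_indices] *= factor

    counts = np.empty((n, p))
    counts[group == 1] = _nb_counts(
        np.broadcast_to(base_mean, (config.n1, p)), config.dispersion, rng
    )
    counts[group == 2] = _nb_counts(
        np.broadcast_to(mean2, (config.n2, p)), config.dispersion, rng
    )
    return np.log2(counts + 1.0), group, de_indices


def assign_betas(config: SyntheticConfig, rng: np.random.Generator) -> BetaPair:
    """Assign the four (beta1, beta2) sign combinations to feature positions
    by a uniform random permutation, honoring the configured counts."""
    n_mm, n_mp, n_pm, n_pp = config.beta_counts
    b1 = np.concatenate(
        [np.full(n_mm, -1), np.full(n_mp, -1), np.full(n_pm, 1), np.full(n_pp, 1)]
    )
    b2 = np.concatenate(
        [np.full(n_mm, -1), np.full(n_mp, 1), np.full(n_pm, -1), np.full(n_pp, 1)]
    )
    perm = rng.permutation(config.n_features)
    return BetaPair(beta1=b1[perm], beta2=b2[perm])


def logistic_score(x_row: np.ndarray, beta: np.ndarray) -> float | np.ndarray:
    """z = sigmoid(sum_j beta_j x_j). Accepts a single row or a matrix."""
    x = np.asarray(x_row, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if x.shape[-1] != beta.shape[0]:
        raise ValueError(f"length mismatch: x has {x.shape[-1]} features, beta {beta.shape[0]}")
    return 1.0 / (1.0 + np.exp(-(x @ beta)))


def generate_labels(X: np.ndarray, group: np.ndarray, betas: BetaPair, class_quantile: float):
    """Threshold per-group logistic scores at the group's class_quantile.

    Returns ``(y, (c1, c2))`` with y in {-1, +1}: sample i in group k gets +1
    iff z_i^k > c^k where c^k is the class_quantile quantile of group k's
    scores.
    """
    X = np.asarray(X, dtype=float)
    group = np.asarray(group)
    y = np.empty(X.shape[0], dtype=int)
    thresholds = []
    for k, beta in ((1, betas.beta1), (2, betas.beta2)):
        mask = group == k
        if not mask.any():
            raise ValueError(f"group {k} has no samples")
        z = logistic_score(X[mask], beta)
        c = float(np.quantile(z, class_quantile))
        y[mask] = np.where(z > c, 1, -1)
        thresholds.append(c)
    return y, tuple(thresholds)


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """End-to-end cohort generation: counts -> log -> standardize -> betas ->
    labels. Ground truth (DE indices, betas, thresholds, config) is attached
    as ``cohort.truth``."""
    rng = np.random.default_rng(config.seed)
    X_log, group, de_indices = simulate_features(config, rng)
    X, _, _ = standardize(X_log)
    betas = assign_betas(config, rng)
    y, thresholds = generate_labels(X, group, betas, config.class_quantile)
    n, p = X.shape
    return Cohort(
        X=X,
        y=y,
        group=group,
        feature_ids=[f"feat_{j:04d}" for j in range(p)],
        sample_ids=[f"sample_{i:05d}" for i in range(n)],
        truth={
            "de_indices": de_indices,
            "betas": betas,
            "thresholds": thresholds,
            "config": config,
        },
    )


def _median_dichotomize(coef: np.ndarray) -> np.ndarray:
    """+1 where the coefficient is strictly above the vector median, else -1."""
    med = np.median(coef)
    return np.where(coef > med, 1, -1)


def estimate_params_from_cohort(
    cohort: Cohort, n_permutations: int = 1000, alpha: float = 0.05
) -> SyntheticConfig:
    """Estimate generator parameters from a (real or simulated) cohort.

    Group sizes are counted directly; ``n_de`` is the number of features with
    permutation t-test p < alpha between the two groups; the beta
    sign-combination counts come from per-group multivariate logistic fits,
    each coefficient vector dichotomized at its median.
    """
    from .discrepancy import group_logistic, permutation_ttest

    rng = np.random.default_rng(cohort.truth["config"].seed if cohort.truth else 0)
    n1 = int(np.sum(cohort.group == 1))
    n2 = int(np.sum(cohort.group == 2))
    pvals, de_mask = permutation_ttest(
        cohort.X, cohort.group, n_permutations=n_permutations, alpha=alpha, rng=rng
    )
    beta_g1, beta_g2 = group_logistic(cohort.X, cohort.y, cohort.group)
    pair = BetaPair(beta1=_median_dichotomize(beta_g1), beta2=_median_dichotomize(beta_g2))
    return SyntheticConfig(
        n1=n1,
        n2=n2,
        n_features=cohort.n_features,
        n_de=int(de_mask.sum()),
        beta_counts=pair.combination_counts(),
    )
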