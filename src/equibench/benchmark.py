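"""Six-experiment benchmarking suite and AUROC disparity-gap statistics.

The suite compares three multi-group learning schemes on one two-group
cohort:

* **Mixture** — one model trained on pooled data with threefold CV
  stratified jointly by outcome and group; AUROC read on the whole test fold
  (Mixture0) and on its group-1 (Mixture1) and group-2 (Mixture2) subsets.
* **Independent** — a separate model per group, threefold CV stratified by
  outcome within the group (Independent1, Independent2).
* **Transfer** — all group-1 samples as the source domain; the group-2
  folds (as in Independent2) provide the target train/test split; the score
  is the best of three transfer methods on the target test fold.

Each run uses fresh random partitions; AUROC is averaged over the three
folds to give one value per (experiment, run). The disparity gap statistics
summarize medians over runs:

    AUROC_bar_majority = (A_Mixture1 + A_Independent1) / 2
    AUROC_bar_minority = (A_Mixture2 + A_Independent2) / 2
    G      = AUROC_bar_majority - AUROC_bar_minority
    G_tilde = AUROC_bar_majority - A_Transfer
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .neural import NetSpec, TrainConfig, predict_proba, train
from .synth_cohort import Cohort

logger = logging.getLogger(__name__)

EXPERIMENTS = (
    "Mixture0",
    "Mixture1",
    "Mixture2",
    "Independent1",
    "Independent2",
    "Transfer",
)


@dataclass
class FoldPlan:
    """Per-sample fold assignment for threefold stratified CV."""

    fold_id: np.ndarray
    strata: str  # "outcome_x_group" or "outcome"
    n_folds: int = 3

    def train_test(self, fold: int):
        test = self.fold_id == fold
        return ~test, test


def stratified_threefold(
    y: np.ndarray,
    group: np.ndarray | None = None,
    mode: str = "mixture",
    rng: np.random.Generator | None = None,
    n_folds: int = 3,
) -> FoldPlan:
    """Random stratified fold assignment.

    In ``mixture`` mode samples are stratified jointly on (outcome, group);
    in ``independent`` mode on outcome only (the caller passes one group's
    labels). Within each stratum shuffled samples are dealt round-robin from
    a random starting fold, so stratum fold counts differ by at most one.
    Strata smaller than the fold count are assigned the same way but cannot
    cover every fold; this is logged as a warning.
    """
    rng = np.random.default_rng() if rng is None else rng
    y = np.asarray(y)
    if mode == "mixture":
        if group is None:
            raise ValueError("mixture mode requires a group vector")
        keys = [f"{yi}|{gi}" for yi, gi in zip(y, np.asarray(group))]
        strata_name = "outcome_x_group"
    elif mode == "independent":
        keys = [str(yi) for yi in y]
        strata_name = "outcome"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keys = np.asarray(keys)
    fold_id = np.empty(len(y), dtype=int)
    for key in np.unique(keys):
        idx = np.flatnonzero(keys == key)
        if len(idx) < n_folds:
            logger.warning(
                "stratum %s has %d sample(s), fewer than %d folds", key, len(idx), n_folds
            )
        perm = rng.permutation(idx)
        start = int(rng.integers(n_folds))
        fold_id[perm] = (start + np.arange(len(idx))) % n_folds
    return FoldPlan(fold_id=fold_id, strata=strata_name, n_folds=n_folds)


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve via the rank (Mann-Whitney) formula.

    Equals the fraction of (positive, negative) pairs where the positive is
    scored higher, with ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray(labels) > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC requires both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclass
class SuiteResult:
    """Per-run AUROC for each experiment, plus the seeds that produced them."""

    table: pd.DataFrame  # columns: experiment, run, auroc
    run_seeds: list[int] = field(default_factory=list)

    def __post_init__(self):
        vals = self.table["auroc"].to_numpy()
        finite = vals[np.isfinite(vals)]
        if finite.size and ((finite < 0) | (finite > 1)).any():
            raise ValueError("AUROC values must lie in [0, 1]")

    def medians(self) -> dict[str, float]:
        med = self.table.groupby("experiment")["auroc"].median()
        return {k: float(v) for k, v in med.items()}

    def experiments(self) -> list[str]:
        return sorted(self.table["experiment"].unique())


@dataclass
class GapReport:
    """Median AUROCs of the six experiments and the disparity gaps."""

    medians: dict[str, float]
    auroc_bar_majority: float
    auroc_bar_minority: float
    G: float
    G_tilde: float
    mixture_gap: float
    independent_gap: float
    gap_threshold: float = 0.05

    @property
    def mixture_gap_call(self) -> str:
        return "yes" if self.mixture_gap > self.gap_threshold else "no"

    @property
    def independent_gap_call(self) -> str:
        return "yes" if self.independent_gap > self.gap_threshold else "no"

    def as_dict(self) -> dict:
        return {
            "medians": self.medians,
            "auroc_bar_majority": self.auroc_bar_majority,
            "auroc_bar_minority": self.auroc_bar_minority,
            "G": self.G,
            "G_tilde": self.G_tilde,
            "mixture_gap": self.mixture_gap,
            "independent_gap": self.independent_gap,
            "gap_threshold": self.gap_threshold,
            "mixture_gap_call": self.mixture_gap_call,
            "independent_gap_call": self.independent_gap_call,
        }


def _safe_auroc(scores, labels, what):
    try:
        return auroc(scores, labels)
    except ValueError as exc:
        logger.warning("skipping AUROC for %s: %s", what, exc)
        return np.nan


def _fold_mean(values):
    values = [v for v in values if np.isfinite(v)]
    return float(np.mean(values)) if values else np.nan


def minority_batch_size(n1: int, n2: int) -> int:
    """Batch size for the minority-group independent model.

    Small minority groups train with batch 4 (too few cases for batch 20
    to give enough updates); under equal group sizes both groups use 20.
    """
    return 4 if n2 * 2 <= n1 else 20


def run_suite(
    cohort: Cohort,
    n_runs: int = 20,
    seed: int = 0,
    schemes: tuple[str, ...] = ("mixture", "independent", "transfer"),
    net_spec: NetSpec | None = None,
    train_cfg: TrainConfig | None = None,
    batch_minority: int | None = None,
    transfer_kwargs: dict | None = None,
) -> SuiteResult:
    """Run the experiment suite for ``n_runs`` random CV partitions.

    ``train_cfg`` provides the shared SGD hyperparameters (its batch_size is
    used for pooled and majority models; the minority independent model uses
    ``batch_minority``, by default 4 under data inequality and 20 otherwise).
    One master ``seed`` deterministically spawns every per-run, per-fold and
    per-model seed.
    """
    from .transfer import DomainPair, LabeledData, transfer_best
    from .neural import SDASpec
    from .transfer import CCSAConfig, default_finetune_config, default_pretrain_config

    net_spec = net_spec or NetSpec(input_nodes=cohort.n_features)
    train_cfg = train_cfg or TrainConfig()
    X, y, group = cohort.X, cohort.y, cohort.group
    n1 = int(np.sum(group == 1))
    n2 = int(np.sum(group == 2))
    if batch_minority is None:
        batch_minority = minority_batch_size(n1, n2)
    for k in (1, 2):
        if np.unique(y[group == k]).size < 2:
            raise ValueError(f"group {k} lacks one of the outcome classes")

    master = np.random.default_rng(seed)
    rows = []
    run_seeds = []
    for run in range(n_runs):
        run_seed = int(master.integers(2**31))
        run_seeds.append(run_seed)
        rng = np.random.default_rng(run_seed)

        if "mixture" in schemes:
            plan = stratified_threefold(y, group, mode="mixture", rng=rng)
            m0, m1, m2 = [], [], []
            for f in range(plan.n_folds):
                tr, te = plan.train_test(f)
                cfg = _with_seed(train_cfg, int(rng.integers(2**31)))
                model = train(net_spec, cfg, X[tr], y[tr])
                scores = predict_proba(model, X[te])
                y_te, g_te = y[te], group[te]
                m0.append(_safe_auroc(scores, y_te, f"Mixture0 run {run} fold {f}"))
                m1.append(
                    _safe_auroc(
                        scores[g_te == 1], y_te[g_te == 1], f"Mixture1 run {run} fold {f}"
                    )
                )
                m2.append(
                    _safe_auroc(
                        scores[g_te == 2], y_te[g_te == 2], f"Mixture2 run {run} fold {f}"
                    )
                )
            rows.append(("Mixture0", run, _fold_mean(m0)))
            rows.append(("Mixture1", run, _fold_mean(m1)))
            rows.append(("Mixture2", run, _fold_mean(m2)))

        group2_plan = None
        if "independent" in schemes or "transfer" in schemes:
            group2_plan = stratified_threefold(
                y[group == 2], mode="independent", rng=rng
            )

        if "independent" in schemes:
            for k, name, batch in (
                (1, "Independent1", train_cfg.batch_size),
                (2, "Independent2", batch_minority),
            ):
                gmask = group == k
                plan = (
                    group2_plan
                    if k == 2
                    else stratified_threefold(y[gmask], mode="independent", rng=rng)
                )
                Xg, yg = X[gmask], y[gmask]
                scores_by_fold = []
                for f in range(plan.n_folds):
                    tr, te = plan.train_test(f)
                    cfg = _with_seed(
                        train_cfg, int(rng.integers(2**31)), batch_size=batch
                    )
                    model = train(net_spec, cfg, Xg[tr], yg[tr])
                    scores_by_fold.append(
                        _safe_auroc(
                            predict_proba(model, Xg[te]),
                            yg[te],
                            f"{name} run {run} fold {f}",
                        )
                    )
                rows.append((name, run, _fold_mean(scores_by_fold)))

        if "transfer" in schemes:
            tkw = dict(transfer_kwargs or {})
            g2 = group == 2
            Xs, ys = X[group == 1], y[group == 1]
            X2, y2 = X[g2], y[g2]
            t_scores = []
            for f in range(group2_plan.n_folds):
                tr, te = group2_plan.train_test(f)
                fold_seed = int(rng.integers(2**30))
                pair = DomainPair(
                    source=LabeledData(Xs, ys),
                    target_train=LabeledData(X2[tr], y2[tr]),
                    target_test=LabeledData(X2[te], y2[te]),
                )
                kwargs = dict(
                    net_spec=net_spec,
                    pretrain_cfg=default_pretrain_config(seed=fold_seed),
                    finetune_cfg=default_finetune_config(seed=fold_seed + 1),
                    sda_spec=SDASpec(input_nodes=cohort.n_features, seed=fold_seed + 2),
                    ccsa_cfg=CCSAConfig(seed=fold_seed + 3),
                )
                kwargs.update(tkw)
                try:
                    _, score, _ = transfer_best(pair, **kwargs)
                except Exception as exc:  # noqa: BLE001
                    logger.warning("transfer failed run %d fold %d: %s", run, f, exc)
                    score = np.nan
                t_scores.append(score)
            rows.append(("Transfer", run, _fold_mean(t_scores)))

    table = pd.DataFrame(rows, columns=["experiment", "run", "auroc"])
    return SuiteResult(table=table, run_seeds=run_seeds)


def _with_seed(cfg: TrainConfig, seed: int, **overrides) -> TrainConfig:
    from dataclasses import replace

    return replace(cfg, seed=seed, **overrides)


def scheme_gaps(result: SuiteResult) -> dict[str, float]:
    """Per-scheme majority-minority gaps of median AUROCs.

    Needs the mixture and independent experiments; the transfer experiment is
    not required.
    """
    med = result.medians()
    return {
        "mixture_gap": med["Mixture1"] - med["Mixture2"],
        "independent_gap": med["Independent1"] - med["Independent2"],
    }


def gap_report(
    result: SuiteResult | dict[str, float], gap_threshold: float = 0.05
) -> GapReport:
    """Disparity-gap summary over all six experiments.

    Accepts a SuiteResult or a ready-made mapping of experiment names to
    median AUROCs.
    """
    med = result.medians() if isinstance(result, SuiteResult) else dict(result)
    missing = [e for e in EXPERIMENTS if e not in med]
    if missing:
        raise ValueError(f"missing experiment(s) in suite result: {missing}")
    bar_major = (med["Mixture1"] + med["Independent1"]) / 2.0
    bar_minor = (med["Mixture2"] + med["Independent2"]) / 2.0
    return GapReport(
        medians=med,
        auroc_bar_majority=bar_major,
        auroc_bar_minority=bar_minor,
        G=bar_major - bar_minor,
        G_tilde=bar_major - med["Transfer"],
        mixture_gap=med["Mixture1"] - med["Mixture2"],
        independent_gap=med["Independent1"] - med["Independent2"],
        gap_threshold=gap_threshold,
    )
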