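"""Transfer learning from a data-rich source group to a small target group.

Three methods are provided, mirroring common practice for small-sample
domain transfer on tabular omics data:

1. **Backprop fine-tuning** — pretrain the pyramid classifier on the source
   group, then continue training all weights on the target training samples
   at a reduced learning rate (0.002) and smaller batches (10).
2. **SDA fine-tuning** — pretrain a stacked denoising autoencoder on
   unlabeled source + target-train features, keep the encoder
   (input -> 128 -> 64), append dropout layers and a logistic output, and
   fine-tune on the labeled target training samples.
3. **CCSA domain adaptation** — contrastive classification semantic
   alignment: a one-hidden-layer embedding g (100 ReLU units, dropout 0.5
   before the logistic head h) trained with

       L_CCSA = (1 - gamma) * L_C(h o g) + gamma * (L_SA + L_S)

   where L_SA averages half squared Euclidean distance over same-label
   cross-domain embedding pairs, and L_S averages the half squared hinge
   max(0, m - d)^2 over different-label pairs. Inputs must be row
   L2-normalized so pairwise embedding distances are comparable.

``transfer_best`` runs all three and reports the best target-test AUROC
(ties broken by the fixed order finetune, sda, ccsa).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .benchmark import auroc
from .neural import (
    NetSpec,
    NetState,
    SDASpec,
    TrainConfig,
    _nesterov_step,
    _sigmoid,
    _epoch_batches,
    _CLIP,
    glorot_init,
    predict_proba,
    relu,
    sda_pretrain,
    train,
)

logger = logging.getLogger(__name__)


@dataclass
class LabeledData:
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y lengths differ")


@dataclass
class DomainPair:
    """Source-domain data plus a train/test partition of the target domain."""

    source: LabeledData
    target_train: LabeledData
    target_test: LabeledData

    def __post_init__(self):
        ps = {d.X.shape[1] for d in (self.source, self.target_train, self.target_test)}
        if len(ps) != 1:
            raise ValueError("source and target must share one feature space")

    @property
    def n_features(self) -> int:
        return self.source.X.shape[1]


@dataclass(frozen=True)
class CCSAConfig:
    gamma: float = 0.25
    margin_m: float = 0.3
    hidden_nodes: int = 100
    dropout_p: float = 0.5
    lr: float = 0.01
    momentum: float = 0.9
    batch_size: int = 20
    max_iter: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.gamma <= 1:
            raise ValueError("gamma must be in [0, 1]")
        if self.margin_m <= 0:
            raise ValueError("margin_m must be positive")


def default_pretrain_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(lr=0.01, batch_size=20, max_iter=100, seed=seed)


def default_finetune_config(seed: int = 0, max_iter: int = 100) -> TrainConfig:
    return TrainConfig(lr=0.002, batch_size=10, max_iter=max_iter, seed=seed)


def finetune_transfer(
    pair: DomainPair,
    net_spec: NetSpec | None = None,
    pretrain_cfg: TrainConfig | None = None,
    finetune_cfg: TrainConfig | None = None,
) -> NetState:
    """Pretrain on the source group, fine-tune all weights on target_train."""
    net_spec = net_spec or NetSpec(input_nodes=pair.n_features)
    pretrain_cfg = pretrain_cfg or default_pretrain_config()
    finetune_cfg = finetune_cfg or default_finetune_config(seed=pretrain_cfg.seed + 1)
    source_model = train(net_spec, pretrain_cfg, pair.source.X, pair.source.y)
    if finetune_cfg.max_iter == 0:
        return source_model
    return train(
        net_spec,
        finetune_cfg,
        pair.target_train.X,
        pair.target_train.y,
        init_params=source_model.params,
    )


def sda_transfer(
    pair: DomainPair,
    sda_spec: SDASpec | None = None,
    finetune_cfg: TrainConfig | None = None,
) -> NetState:
    """Autoencoder pretraining on unlabeled features, then supervised
    fine-tuning of the encoder + logistic head on target_train.

    Pretraining uses source and target *training* features only, never the
    target test fold.
    """
    sda_spec = sda_spec or SDASpec(input_nodes=pair.n_features)
    finetune_cfg = finetune_cfg or default_finetune_config(seed=sda_spec.seed + 1)
    X_unlabeled = np.vstack([pair.source.X, pair.target_train.X])
    encoder, _ = sda_pretrain(sda_spec, X_unlabeled)
    net_spec = NetSpec(
        input_nodes=pair.n_features,
        hidden=(sda_spec.code_nodes, sda_spec.bottleneck_nodes),
    )
    rng = np.random.default_rng(finetune_cfg.seed)
    out_layer = glorot_init([sda_spec.bottleneck_nodes, 1], rng)[0]
    init_params = [(W.copy(), b.copy()) for W, b in encoder] + [out_layer]
    return train(
        net_spec,
        finetune_cfg,
        pair.target_train.X,
        pair.target_train.y,
        init_params=init_params,
    )


def ccsa_pair_losses(
    embeddings_s: np.ndarray,
    embeddings_t: np.ndarray,
    labels_s: np.ndarray,
    labels_t: np.ndarray,
    margin_m: float,
):
    """Semantic-alignment and separation losses over all cross-domain pairs.

    L_SA = mean over same-label (source, target) pairs of d^2 / 2;
    L_S  = mean over different-label pairs of max(0, m - d)^2 / 2,
    with d the Euclidean embedding distance. A kind of pair that does not
    occur contributes 0 (logged).
    """
    Zs = np.asarray(embeddings_s, dtype=float)
    Zt = np.asarray(embeddings_t, dtype=float)
    ys = np.asarray(labels_s) > 0
    yt = np.asarray(labels_t) > 0
    d2 = np.maximum(
        np.sum(Zs**2, axis=1)[:, None]
        + np.sum(Zt**2, axis=1)[None, :]
        - 2.0 * Zs @ Zt.T,
        0.0,
    )
    d = np.sqrt(d2)
    same = ys[:, None] == yt[None, :]
    if same.any():
        l_sa = float(np.mean(0.5 * d2[same]))
    else:
        logger.info("no same-label cross-domain pairs; L_SA set to 0")
        l_sa = 0.0
    diff = ~same
    if diff.any():
        hinge = np.maximum(0.0, margin_m - d[diff])
        l_s = float(np.mean(0.5 * hinge**2))
    else:
        logger.info("no different-label cross-domain pairs; L_S set to 0")
        l_s = 0.0
    return l_sa, l_s


def _check_row_normalized(X: np.ndarray, name: str):
    norms = np.linalg.norm(X, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError(
            f"{name} rows must be L2-normalized before CCSA (max |norm-1| = "
            f"{np.max(np.abs(norms - 1.0)):.3g})"
        )


def _ccsa_forward(params, Xs, Xt, masks):
    """Embeddings and classifier outputs for a source and a target batch."""
    (We, be), (Wh, bh) = params
    hs, ht = Xs @ We + be, Xt @ We + be
    Zs, Zt = relu(hs), relu(ht)
    Zs_c = Zs * masks[0] if masks is not None else Zs
    Zt_c = Zt * masks[1] if masks is not None else Zt
    ps = _sigmoid((Zs_c @ Wh + bh)[:, 0])
    pt = _sigmoid((Zt_c @ Wh + bh)[:, 0])
    return hs, ht, Zs, Zt, Zs_c, Zt_c, ps, pt


def ccsa_loss_and_grads(params, Xs, ys01, Xt, yt01, cfg: CCSAConfig, masks=None):
    """Full CCSA batch loss and analytic gradients.

    L_C is the mean binary cross-entropy over the concatenated source and
    target batch; the alignment terms use the dropout-free embeddings.
    """
    hs, ht, Zs, Zt, Zs_c, Zt_c, ps, pt = _ccsa_forward(params, Xs, Xt, masks)
    (We, be), (Wh, bh) = params
    m_total = len(ys01) + len(yt01)

    pc = np.concatenate([ps, pt])
    yc01 = np.concatenate([ys01, yt01])
    pcl = np.clip(pc, _CLIP, 1 - _CLIP)
    l_c = float(-np.mean(yc01 * np.log(pcl) + (1 - yc01) * np.log(1 - pcl)))

    l_sa, l_s = ccsa_pair_losses(Zs, Zt, 2 * ys01 - 1, 2 * yt01 - 1, cfg.margin_m)
    total = (1 - cfg.gamma) * l_c + cfg.gamma * (l_sa + l_s)

    # --- classification gradients ---
    w_c = (1 - cfg.gamma) / m_total
    delta_s = w_c * (ps - ys01)[:, None]
    delta_t = w_c * (pt - yt01)[:, None]
    gWh = Zs_c.T @ delta_s + Zt_c.T @ delta_t
    gbh = delta_s.sum(axis=0) + delta_t.sum(axis=0)
    dZs = delta_s @ Wh.T
    dZt = delta_t @ Wh.T
    if masks is not None:
        dZs = dZs * masks[0]
        dZt = dZt * masks[1]

    # --- alignment gradients on the dropout-free embeddings ---
    ys_pos = ys01 > 0.5
    yt_pos = yt01 > 0.5
    same = ys_pos[:, None] == yt_pos[None, :]
    diffmat = Zs[:, None, :] - Zt[None, :, :]  # (ns, nt, k)
    n_sa = int(same.sum())
    if n_sa:
        w_sa = cfg.gamma / n_sa
        coeff = np.where(same, w_sa, 0.0)
        dZs = dZs + np.einsum("st,stk->sk", coeff, diffmat)
        dZt = dZt - np.einsum("st,stk->tk", coeff, diffmat)
    n_s = int((~same).sum())
    if n_s:
        d = np.sqrt(np.maximum(np.sum(diffmat**2, axis=2), 1e-12))
        hinge = np.maximum(0.0, cfg.margin_m - d)
        coeff = np.where(~same, -(cfg.gamma / n_s) * hinge / d, 0.0)
        dZs = dZs + np.einsum("st,stk->sk", coeff, diffmat)
        dZt = dZt - np.einsum("st,stk->tk", coeff, diffmat)

    ds = dZs * (hs > 0)
    dt = dZt * (ht > 0)
    gWe = Xs.T @ ds + Xt.T @ dt
    gbe = ds.sum(axis=0) + dt.sum(axis=0)
    return total, [(gWe, gbe), (gWh, gbh)], (l_c, l_sa, l_s)


def ccsa_train(pair: DomainPair, cfg: CCSAConfig | None = None) -> NetState:
    """Jointly train the embedding and classifier by Nesterov SGD on L_CCSA.

    Per epoch the source set is traversed in shuffled batches while target
    batches cycle through an independently shuffled target ordering; every
    batch contributes all its source x target pairs to the alignment terms.
    """
    cfg = cfg or CCSAConfig()
    for part, name in (
        (pair.source, "source"),
        (pair.target_train, "target_train"),
    ):
        _check_row_normalized(part.X, name)
    rng = np.random.default_rng(cfg.seed)
    p = pair.n_features
    params = glorot_init([p, cfg.hidden_nodes, 1], rng)
    velocity = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
    Xs_all, ys01 = pair.source.X, (pair.source.y > 0).astype(float)
    Xt_all, yt01 = pair.target_train.X, (pair.target_train.y > 0).astype(float)
    ns, nt = len(ys01), len(yt01)
    keep = 1.0 - cfg.dropout_p
    log = []
    for epoch in range(cfg.max_iter):
        t_order = rng.permutation(nt)
        t_pos = 0
        epoch_loss, n_batches = 0.0, 0
        for s_idx in _epoch_batches(ns, cfg.batch_size, rng):
            t_idx = np.array(
                [t_order[(t_pos + j) % nt] for j in range(cfg.batch_size)]
            )
            t_pos = (t_pos + cfg.batch_size) % nt
            Xs, ysb = Xs_all[s_idx], ys01[s_idx]
            Xt, ytb = Xt_all[t_idx], yt01[t_idx]
            if cfg.dropout_p > 0:
                masks = (
                    (rng.random((len(s_idx), cfg.hidden_nodes)) >= cfg.dropout_p) / keep,
                    (rng.random((len(t_idx), cfg.hidden_nodes)) >= cfg.dropout_p) / keep,
                )
            else:
                masks = None
            _, grads, _ = ccsa_loss_and_grads(params, Xs, ysb, Xt, ytb, cfg, masks)
            _nesterov_step(params, velocity, grads, cfg.lr, cfg.momentum)
            n_batches += 1
        val, _, _ = ccsa_loss_and_grads(params, Xs_all, ys01, Xt_all, yt01, cfg)
        if not np.isfinite(val):
            raise ValueError(f"CCSA loss became non-finite at epoch {epoch}")
        log.append(float(val))
    spec = NetSpec(input_nodes=p, hidden=(cfg.hidden_nodes,))
    return NetState(spec=spec, params=params, training_log=log)


_METHOD_ORDER = ("finetune", "sda", "ccsa")


def transfer_best(
    pair: DomainPair,
    net_spec: NetSpec | None = None,
    pretrain_cfg: TrainConfig | None = None,
    finetune_cfg: TrainConfig | None = None,
    sda_spec: SDASpec | None = None,
    ccsa_cfg: CCSAConfig | None = None,
):
    """Run all three transfer methods, return (method, AUROC, model) with the
    best target-test AUROC; ties and failures resolve by fixed method order.

    CCSA receives row-L2-normalized copies of the inputs (its distance-based
    loss requires them); the evaluation label set is shared.
    """
    from .preprocess import l2_normalize_rows

    results = {}
    try:
        model = finetune_transfer(pair, net_spec, pretrain_cfg, finetune_cfg)
        score = auroc(predict_proba(model, pair.target_test.X), pair.target_test.y)
        results["finetune"] = (score, model)
    except Exception as exc:  # noqa: BLE001 - a failed method is skipped, not fatal
        logger.warning("finetune transfer failed: %s", exc)
    try:
        model = sda_transfer(pair, sda_spec, finetune_cfg)
        score = auroc(predict_proba(model, pair.target_test.X), pair.target_test.y)
        results["sda"] = (score, model)
    except Exception as exc:  # noqa: BLE001
        logger.warning("sda transfer failed: %s", exc)
    try:
        norm_pair = DomainPair(
            source=LabeledData(l2_normalize_rows(pair.source.X), pair.source.y),
            target_train=LabeledData(
                l2_normalize_rows(pair.target_train.X), pair.target_train.y
            ),
            target_test=LabeledData(
                l2_normalize_rows(pair.target_test.X), pair.target_test.y
            ),
        )
        model = ccsa_train(norm_pair, ccsa_cfg)
        score = auroc(
            predict_proba(model, norm_pair.target_test.X), norm_pair.target_test.y
        )
        results["ccsa"] = (score, model)
    except Exception as exc:  # noqa: BLE001
        logger.warning("ccsa transfer failed: %s", exc)
    if not results:
        raise RuntimeError("all transfer methods failed")
    best_method = None
    best_score = -np.inf
    for method in _METHOD_ORDER:
        if method in results and results[method][0] > best_score:
            best_method, best_score = method, results[method][0]
    return best_method, best_score, results[best_method][1]
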