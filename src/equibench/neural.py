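"""Feed-forward classifier and stacked denoising autoencoder, in NumPy.

The classifier is a small pyramid network: input, fully connected 128-node
layer + dropout, fully connected 64-node layer + dropout, and a single
logistic output unit. ReLU activations on the hidden layers. Training is
mini-batch stochastic gradient descent with Nesterov momentum, minimizing a
cross-entropy loss plus L1 and L2 weight penalties

    l(W) = CE(y, yhat) + lambda1 * sum|W| + lambda2 * ||W||^2

(the squared-norm weight-decay convention; ``squared_l2=False`` switches to
the unsquared global norm). Penalties apply to connection weights only, not
biases. Forward and backward passes are written out explicitly so the
analytic gradients can be validated against finite differences.

Everything is deterministic under a fixed seed: weight initialization
(Glorot uniform), batch shuffling and dropout masks all draw from one seeded
generator. Dropout is implemented as inverted dropout (activations scaled by
1/(1-p) during training), so inference is a plain deterministic forward pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_CLIP = 1e-7  # keep yhat away from {0,1} in the cross-entropy


class DivergenceError(RuntimeError):
    """Raised when training produces a non-finite loss."""


@dataclass(frozen=True)
class NetSpec:
    """Architecture of the pyramid classifier.

    ``hidden`` lists the fully connected hidden layer sizes, each followed by
    dropout during training; the output is a single logistic unit. An empty
    ``hidden`` tuple gives a plain logistic-regression network.
    """

    input_nodes: int
    hidden: tuple[int, ...] = (128, 64)

    def layer_sizes(self) -> list[int]:
        return [self.input_nodes, *self.hidden, 1]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 0.01
    lr_decay: float = 0.0
    batch_size: int = 20
    max_iter: int = 100
    momentum: float = 0.9
    dropout_p: float = 0.5
    lambda1: float = 0.001
    lambda2: float = 0.001
    seed: int = 0
    squared_l2: bool = True
    mean_loss: bool = True  # mean cross-entropy per batch; False sums instead

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalty weights must be non-negative")


@dataclass
class NetState:
    """Trained network: layer weights/biases plus the per-epoch loss log."""

    spec: NetSpec
    params: list[tuple[np.ndarray, np.ndarray]]
    training_log: list[float] = field(default_factory=list)

    def copy(self) -> "NetState":
        return NetState(
            spec=self.spec,
            params=[(W.copy(), b.copy()) for W, b in self.params],
            training_log=list(self.training_log),
        )


@dataclass(frozen=True)
class SDASpec:
    """Five-layer denoising autoencoder: input -> 128 -> 64 -> 128 -> input."""

    input_nodes: int
    code_nodes: int = 128
    bottleneck_nodes: int = 64
    corruption_level: float = 0.3
    lr: float = 0.01
    batch_size: int = 32
    max_iter: int = 500
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.corruption_level < 1:
            raise ValueError("corruption_level must be in [0, 1)")

    def layer_sizes(self) -> list[int]:
        return [
            self.input_nodes,
            self.code_nodes,
            self.bottleneck_nodes,
            self.code_nodes,
            self.input_nodes,
        ]


def relu(x):
    """Elementwise max(0, x)."""
    return np.maximum(0, x)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def glorot_init(sizes: list[int], rng: np.random.Generator):
    """Uniform Glorot-initialized (W, b) pairs for consecutive layer sizes."""
    params = []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        W = rng.uniform(-limit, limit, size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        params.append((W, b))
    return params


def _penalty(params, lambda1, lambda2, squared_l2):
    """L1 + L2 penalty over connection weights (biases excluded)."""
    l1 = sum(np.abs(W).sum() for W, _ in params)
    sq = sum((W**2).sum() for W, _ in params)
    l2 = sq if squared_l2 else np.sqrt(sq)
    return lambda1 * l1 + lambda2 * l2


def _penalty_grads(params, lambda1, lambda2, squared_l2):
    if not squared_l2:
        norm = np.sqrt(sum((W**2).sum() for W, _ in params))
    grads = []
    for W, _ in params:
        g = lambda1 * np.sign(W)
        if squared_l2:
            g = g + 2.0 * lambda2 * W
        elif norm > 0:
            g = g + lambda2 * W / norm
        grads.append(g)
    return grads


def forward(params, X, dropout_masks=None):
    """Forward pass; returns (yhat, cache) for backprop.

    ``dropout_masks`` is a list of pre-scaled masks (entries 0 or 1/(1-p)),
    one per hidden layer, or None for a deterministic pass.
    """
    a = np.asarray(X, dtype=float)
    acts = [a]  # post-activation (and post-dropout) input to each layer
    pre = []  # pre-activations of hidden layers
    n_hidden = len(params) - 1
    for i in range(n_hidden):
        W, b = params[i]
        h = a @ W + b
        pre.append(h)
        a = relu(h)
        if dropout_masks is not None:
            a = a * dropout_masks[i]
        acts.append(a)
    W, b = params[-1]
    out = a @ W + b
    yhat = _sigmoid(out[:, 0])
    return yhat, (acts, pre)


def loss_and_grads(
    params,
    X,
    y01,
    lambda1=0.0,
    lambda2=0.0,
    squared_l2=True,
    mean_loss=True,
    dropout_masks=None,
    value=True,
):
    """Regularized cross-entropy and its analytic gradients.

    Returns ``(loss, grads)`` with grads a list of (dW, db) matching params.
    ``value=False`` skips computing the loss value (gradients only, used in
    the inner training loop) and returns None in its place.
    """
    X = np.asarray(X)
    y01 = np.asarray(y01)
    m = X.shape[0]
    yhat, (acts, pre) = forward(params, X, dropout_masks)
    # mean_loss divides the whole batch objective (cross-entropy and
    # penalties alike) by the batch size, so the data/penalty ratio matches
    # the summed formulation and only the learning-rate scale changes
    scale = 1.0 / m if mean_loss else 1.0
    if value:
        if not np.isfinite(yhat).all():
            raise DivergenceError("non-finite network output")
        yc = np.clip(yhat, _CLIP, 1 - _CLIP)
        ce = -np.sum(y01 * np.log(yc) + (1 - y01) * np.log(1 - yc))
        total = scale * (ce + _penalty(params, lambda1, lambda2, squared_l2))
    else:
        total = None

    pgrads = (
        _penalty_grads(params, scale * lambda1, scale * lambda2, squared_l2)
        if (lambda1 != 0 or lambda2 != 0)
        else None
    )
    grads = [None] * len(params)
    delta = scale * (yhat - y01)[:, None]  # d loss / d output pre-activation
    for i in range(len(params) - 1, -1, -1):
        W, _ = params[i]
        a_prev = acts[i]
        gW = a_prev.T @ delta
        if pgrads is not None:
            gW = gW + pgrads[i]
        gb = delta.sum(axis=0)
        grads[i] = (gW, gb)
        if i > 0:
            delta = delta @ W.T
            if dropout_masks is not None:
                delta = delta * dropout_masks[i - 1]
            delta = delta * (pre[i - 1] > 0)
    return total, grads


def loss(net: NetState, batch_X, batch_y, lambda1=0.0, lambda2=0.0, **kw):
    """Regularized cross-entropy of a network state on a batch.

    ``batch_y`` may be in {0,1} or {-1,+1}; the latter is mapped to {0,1}.
    """
    y01 = (np.asarray(batch_y) > 0).astype(float)
    val, _ = loss_and_grads(net.params, batch_X, y01, lambda1, lambda2, **kw)
    return float(val)


def _nesterov_step(params, velocity, grads, lr, momentum):
    """One Nesterov momentum update, in the reformulated (lookahead-free)
    form used by common SGD implementations:

        v <- mu * v - lr * g(w);   w <- w + mu * v - lr * g(w)

    which tracks the lookahead parameters implicitly. Updates in place.
    """
    for (W, b), vel, (gW, gb) in zip(params, velocity, grads):
        vW, vb = vel
        # equivalent grouping with one less pass: w += mu^2 v - (1+mu) lr g
        W += (momentum * momentum) * vW
        W -= ((1.0 + momentum) * lr) * gW
        vW *= momentum
        vW -= lr * gW
        b += (momentum * momentum) * vb
        b -= ((1.0 + momentum) * lr) * gb
        vb *= momentum
        vb -= lr * gb


try:  # fused single-pass kernel for the inner training loop
    from numba import njit

    @njit(cache=False, fastmath=False)
    def _fused_update_2d(W, v, g, lr, mu, lam1, lam2):
        """Penalty gradient + Nesterov update in one pass over the weights.

        Adds lam1 * sign(w) + 2 * lam2 * w (the squared-L2 convention) to the
        data gradient, then applies the same reformulated Nesterov update as
        :func:`_nesterov_step`.
        """
        rows, cols = W.shape
        for i in range(rows):
            for j in range(cols):
                w = W[i, j]
                s = 1.0 if w > 0 else (-1.0 if w < 0 else 0.0)
                gt = g[i, j] + lam1 * s + 2.0 * lam2 * w
                vn = mu * v[i, j] - lr * gt
                v[i, j] = vn
                W[i, j] = w + mu * vn - lr * gt

    @njit(cache=False, fastmath=False)
    def _fused_update_1d(b, v, g, lr, mu):
        for i in range(b.shape[0]):
            vn = mu * v[i] - lr * g[i]
            v[i] = vn
            b[i] = b[i] + mu * vn - lr * g[i]

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False


def _epoch_batches(n, batch_size, rng):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def train(
    net_spec: NetSpec,
    cfg: TrainConfig,
    X: np.ndarray,
    y: np.ndarray,
    init_params=None,
) -> NetState:
    """Mini-batch Nesterov SGD on the regularized cross-entropy.

    The learning rate decays as lr / (1 + lr_decay * epoch). ``init_params``
    continues training from an existing parameter set (used for transfer
    fine-tuning). The per-epoch training log records the full-data loss with
    dropout disabled. Training arithmetic runs in single precision (SGD with
    dropout is insensitive to it and it roughly halves the runtime); the
    returned parameters are float32 arrays.
    """
    X = np.ascontiguousarray(X, dtype=np.float32)
    y01 = (np.asarray(y) > 0).astype(np.float32)
    n = X.shape[0]
    rng = np.random.default_rng(cfg.seed)
    if init_params is None:
        params = glorot_init(net_spec.layer_sizes(), rng)
    else:
        params = init_params
    params = [
        (W.astype(np.float32), b.astype(np.float32)) for W, b in params
    ]
    velocity = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
    n_hidden = len(net_spec.hidden)
    keep = np.float32(1.0 - cfg.dropout_p)
    # the fused kernel implements the squared-L2 weight-decay convention only
    fused = _HAVE_NUMBA and cfg.squared_l2
    log = []
    for epoch in range(cfg.max_iter):
        lr_t = cfg.lr / (1.0 + cfg.lr_decay * epoch)
        for idx in _epoch_batches(n, cfg.batch_size, rng):
            Xb, yb = X[idx], y01[idx]
            if cfg.dropout_p > 0 and n_hidden:
                masks = [
                    (rng.random((len(idx), h)) >= cfg.dropout_p).astype(np.float32)
                    / keep
                    for h in net_spec.hidden
                ]
            else:
                masks = None
            if fused:
                # penalty gradients are folded into the fused update kernel
                _, grads = loss_and_grads(
                    params, Xb, yb, 0.0, 0.0,
                    cfg.squared_l2, cfg.mean_loss, masks, value=False,
                )
                pscale = 1.0 / len(idx) if cfg.mean_loss else 1.0
                for (W, b), (vW, vb), (gW, gb) in zip(params, velocity, grads):
                    _fused_update_2d(
                        W, vW, gW, lr_t, cfg.momentum,
                        pscale * cfg.lambda1, pscale * cfg.lambda2,
                    )
                    _fused_update_1d(b, vb, gb, lr_t, cfg.momentum)
            else:
                _, grads = loss_and_grads(
                    params, Xb, yb, cfg.lambda1, cfg.lambda2,
                    cfg.squared_l2, cfg.mean_loss, masks, value=False,
                )
                _nesterov_step(params, velocity, grads, lr_t, cfg.momentum)
        full, _ = loss_and_grads(
            params, X, y01, cfg.lambda1, cfg.lambda2, cfg.squared_l2, cfg.mean_loss
        )
        if not np.isfinite(full):
            raise DivergenceError(f"training loss became non-finite at epoch {epoch}")
        log.append(float(full))
    return NetState(spec=net_spec, params=params, training_log=log)


def predict_proba(net: NetState, X: np.ndarray) -> np.ndarray:
    """Deterministic (dropout-free) class-probability predictions."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != net.spec.input_nodes:
        raise ValueError(
            f"feature count {X.shape[1]} does not match input_nodes {net.spec.input_nodes}"
        )
    yhat, _ = forward(net.params, X)
    return np.clip(yhat, _CLIP, 1 - _CLIP)


def _mse_loss_and_grads(params, X_in, X_target):
    """Squared-error reconstruction loss and gradients for the autoencoder.

    Hidden layers use ReLU; the output layer is linear (it reconstructs
    standardized, hence signed, data).
    """
    a = X_in
    acts = [a]
    pre = []
    for i in range(len(params) - 1):
        W, b = params[i]
        h = a @ W + b
        pre.append(h)
        a = relu(h)
        acts.append(a)
    W, b = params[-1]
    out = a @ W + b
    m = X_in.shape[0]
    diff = out - X_target
    total = float(np.mean(diff**2))
    grads = [None] * len(params)
    delta = 2.0 * diff / diff.size
    for i in range(len(params) - 1, -1, -1):
        W, _ = params[i]
        grads[i] = (acts[i].T @ delta, delta.sum(axis=0))
        if i > 0:
            delta = (delta @ W.T) * (pre[i - 1] > 0)
    return total, grads


def sda_pretrain(spec: SDASpec, X_unlabeled: np.ndarray):
    """Train the 5-layer denoising autoencoder; return encoder params + log.

    Each presentation masks a fraction ``corruption_level`` of input entries
    to zero; the reconstruction target is the uncorrupted input. Returns
    ``(encoder_params, reconstruction_log)`` where encoder_params are the
    input->code and code->bottleneck layers.
    """
    X = np.asarray(X_unlabeled, dtype=float)
    rng = np.random.default_rng(spec.seed)
    params = glorot_init(spec.layer_sizes(), rng)
    n = X.shape[0]
    log = []
    for epoch in range(spec.max_iter):
        epoch_loss = 0.0
        n_batches = 0
        for idx in _epoch_batches(n, spec.batch_size, rng):
            Xb = X[idx]
            if spec.corruption_level > 0:
                keep_mask = rng.random(Xb.shape) >= spec.corruption_level
                X_in = Xb * keep_mask
            else:
                X_in = Xb
            val, grads = _mse_loss_and_grads(params, X_in, Xb)
            params = [
                (W - spec.lr * gW, b - spec.lr * gb)
                for (W, b), (gW, gb) in zip(params, grads)
            ]
            epoch_loss += val
            n_batches += 1
        mean_loss = epoch_loss / n_batches
        if not np.isfinite(mean_loss):
            raise DivergenceError(f"autoencoder loss became non-finite at epoch {epoch}")
        log.append(mean_loss)
    return params[:2], log
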