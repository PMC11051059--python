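"""NumPy implementation of the CNN: forward, backprop, and Adam training.

Convolutions run as BLAS matmuls: the binary-image entry layer through a
single im2col GEMM, deeper layers as k*k shifted batched matmuls. All
large per-batch arrays come from a scratch-buffer pool so repeated
training steps reuse memory instead of re-faulting fresh pages — on a
single CPU the allocator, not the FLOPs, is otherwise the bottleneck.
The training loop follows the published recipe (mini-batch Adam on
categorical cross-entropy with the legacy per-update learning-rate decay)
and checkpoints the weights of the epoch with the best validation AUC.
"""

from __future__ import annotations

import numpy as np

from .architecture import CnnSpec, ModelBundle, TrainConfig, validate_weights


class TrainingError(ValueError):
    """Degenerate training inputs (empty partitions, single-class labels)."""


def _as_input(images: np.ndarray, spec: CnnSpec) -> np.ndarray:
    x = np.asarray(images, dtype=np.float32)
    if x.ndim == 3:
        x = x[..., None]
    if x.shape[1:] != (spec.input_height, spec.input_width, 1):
        raise TrainingError(
            f"images shaped {x.shape[1:]} do not match spec input "
            f"{(spec.input_height, spec.input_width, 1)}"
        )
    return x


class _Buffers:
    """Named scratch arrays reused across training steps."""

    def __init__(self) -> None:
        self._pool: dict[str, np.ndarray] = {}

    def get(self, name: str, shape: tuple[int, ...], fill: float | None = None) -> np.ndarray:
        a = self._pool.get(name)
        if a is None or a.shape != shape:
            a = np.empty(shape, dtype=np.float32)
            self._pool[name] = a
        if fill is not None:
            a.fill(fill)
        return a


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray, buf: _Buffers, tag: str):
    """Same-padded convolution. Entry layer (few input channels): one
    im2col GEMM. Deeper layers: shifted batched matmuls."""
    n, h, w, cin = x.shape
    k = W.shape[0]
    p = k // 2
    cout = W.shape[-1]
    xp = buf.get(f"{tag}:xp", (n, h + 2 * p, w + 2 * p, cin), fill=0.0)
    xp[:, p : p + h, p : p + w, :] = x
    out = buf.get(f"{tag}:out", (n, h, w, cout))
    if cin * k * k <= 64:
        rows = buf.get(f"{tag}:rows", (cin * k * k, n * h * w))
        r = 0
        for i in range(k):
            for j in range(k):
                for c in range(cin):
                    np.copyto(rows[r].reshape(n, h, w), xp[:, i : i + h, j : j + w, c])
                    r += 1
        kmat = W.reshape(k * k * cin, cout)  # (i, j, c) row order, matching rows
        np.matmul(rows.T, kmat, out=out.reshape(n * h * w, cout))
        out += b
        return out, ("im2col", rows, x.shape)
    tmp = buf.get(f"{tag}:tmp", (n, h, w, cout))
    np.copyto(out, b)
    for i in range(k):
        for j in range(k):
            np.matmul(xp[:, i : i + h, j : j + w, :], W[i, j], out=tmp)
            out += tmp
    return out, ("shift", xp, x.shape)


def _conv_backward(
    dout: np.ndarray, cache, W: np.ndarray, buf: _Buffers, tag: str, need_dx: bool = True
):
    mode, stored, x_shape = cache
    n, h, w, cin = x_shape
    k = W.shape[0]
    p = k // 2
    cout = dout.shape[-1]
    db = dout.sum(axis=(0, 1, 2))
    dflat = dout.reshape(-1, cout)
    if mode == "im2col":
        rows = stored
        dW = (rows @ dflat).reshape(k, k, cin, cout)
        dx = None
        if need_dx:
            dcol = (dflat @ W.reshape(k * k * cin, cout).T).reshape(n, h, w, k, k, cin)
            dxp = buf.get(f"{tag}:dxp", (n, h + 2 * p, w + 2 * p, cin), fill=0.0)
            for i in range(k):
                for j in range(k):
                    dxp[:, i : i + h, j : j + w, :] += dcol[:, :, :, i, j, :]
            dx = dxp[:, p : p + h, p : p + w, :]
        return dx, dW, db
    xp = stored
    dW = np.empty_like(W)
    xs = buf.get(f"{tag}:xs", (n, h, w, cin))
    dxp = buf.get(f"{tag}:dxp", xp.shape, fill=0.0) if need_dx else None
    tmp = buf.get(f"{tag}:dtmp", (n, h, w, cin)) if need_dx else None
    for i in range(k):
        for j in range(k):
            np.copyto(xs, xp[:, i : i + h, j : j + w, :])
            dW[i, j] = xs.reshape(-1, cin).T @ dflat
            if need_dx:
                np.matmul(dout, W[i, j].T, out=tmp)
                dxp[:, i : i + h, j : j + w, :] += tmp
    dx = dxp[:, p : p + h, p : p + w, :] if need_dx else None
    return dx, dW, db


def _pool_forward(x: np.ndarray, buf: _Buffers, tag: str):
    """2x2 max-pool, stride 2, as maximum chains over the four phase
    slices; the backward pass routes gradients by comparison (ties prefer
    top-left, then top-right, then bottom-left)."""
    s00 = x[:, 0::2, 0::2, :]
    s01 = x[:, 0::2, 1::2, :]
    s10 = x[:, 1::2, 0::2, :]
    s11 = x[:, 1::2, 1::2, :]
    m0 = np.maximum(s00, s01, out=buf.get(f"{tag}:m0", s00.shape))
    m1 = np.maximum(s10, s11, out=buf.get(f"{tag}:m1", s00.shape))
    out = np.maximum(m0, m1, out=buf.get(f"{tag}:out", s00.shape))
    return out, (x, m0, m1, x.shape)


def _pool_backward(dout: np.ndarray, cache, buf: _Buffers, tag: str):
    x, m0, m1, x_shape = cache
    s00 = x[:, 0::2, 0::2, :]
    s01 = x[:, 0::2, 1::2, :]
    s10 = x[:, 1::2, 0::2, :]
    s11 = x[:, 1::2, 1::2, :]
    zero = np.float32(0.0)
    d0 = np.where(m0 >= m1, dout, zero)
    d1 = dout - d0
    dx = buf.get(f"{tag}:dx", x_shape)
    dx[:, 0::2, 0::2, :] = np.where(s00 >= s01, d0, zero)
    dx[:, 0::2, 1::2, :] = np.where(s00 >= s01, zero, d0)
    dx[:, 1::2, 0::2, :] = np.where(s10 >= s11, d1, zero)
    dx[:, 1::2, 1::2, :] = np.where(s10 >= s11, zero, d1)
    return dx


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with half credit for ties (internal checkpoint
    metric; the evaluation module owns the reported DeLong AUC)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        return float("nan")
    from scipy.stats import rankdata

    ranks = rankdata(np.concatenate([pos, neg]))
    return (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)


class NumpyCnn:
    """Stateful view over a :class:`ModelBundle` with forward/backward."""

    def __init__(self, bundle: ModelBundle):
        bundle.spec.validate()
        validate_weights(bundle.spec, bundle.weights)
        self.bundle = bundle
        self.spec = bundle.spec
        self.weights = bundle.weights
        self._buf = _Buffers()

    # -- forward ---------------------------------------------------------
    def forward(
        self,
        x: np.ndarray,
        train: bool = False,
        dropout_rng: np.random.Generator | None = None,
    ):
        spec, w = self.spec, self.weights
        caches: list = []
        a = x
        for i in range(1, spec.n_blocks + 1):
            z, conv_cache = _conv_forward(
                a, w[f"conv{i}_W"], w[f"conv{i}_b"], self._buf, f"conv{i}"
            )
            np.maximum(z, 0, out=z)
            a, pool_cache = _pool_forward(z, self._buf, f"pool{i}")
            caches.append((conv_cache, z, pool_cache))
        n = a.shape[0]
        flat = a.reshape(n, -1)
        z1 = flat @ w["dense1_W"] + w["dense1_b"]
        a1 = np.maximum(z1, 0)
        z2 = a1 @ w["dense2_W"] + w["dense2_b"]
        a2 = np.maximum(z2, 0)
        if train and spec.dropout_rate > 0:
            keep = 1.0 - spec.dropout_rate
            mask = (dropout_rng.random(a2.shape) < keep).astype(a2.dtype) / keep
        else:
            mask = np.ones_like(a2)
        a2d = a2 * mask
        logits = a2d @ w["out_W"] + w["out_b"]
        probs = _softmax(logits)
        head_cache = (flat, z1, a1, z2, a2, mask, a2d, a.shape)
        return probs, (caches, head_cache)

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = _as_input(images, self.spec)
        out = []
        for s in range(0, x.shape[0], batch_size):
            probs, _ = self.forward(x[s : s + batch_size], train=False)
            out.append(probs.copy())
        return np.concatenate(out, axis=0)

    # -- backward --------------------------------------------------------
    def backward(self, probs: np.ndarray, y_onehot: np.ndarray, cache):
        caches, (flat, z1, a1, z2, a2, mask, a2d, feat_shape) = cache
        w = self.weights
        n = probs.shape[0]
        grads: dict[str, np.ndarray] = {}
        dlogits = (probs - y_onehot).astype(np.float32) / n
        grads["out_W"] = a2d.T @ dlogits
        grads["out_b"] = dlogits.sum(axis=0)
        da2 = (dlogits @ w["out_W"].T) * mask
        dz2 = da2 * (z2 > 0)
        grads["dense2_W"] = a1.T @ dz2
        grads["dense2_b"] = dz2.sum(axis=0)
        da1 = dz2 @ w["dense2_W"].T
        dz1 = da1 * (z1 > 0)
        grads["dense1_W"] = flat.T @ dz1
        grads["dense1_b"] = dz1.sum(axis=0)
        da = (dz1 @ w["dense1_W"].T).reshape(feat_shape)
        for i in range(self.spec.n_blocks, 0, -1):
            conv_cache, z_relu, pool_cache = caches[i - 1]
            dz = _pool_backward(da, pool_cache, self._buf, f"pool{i}")
            dz *= z_relu > 0
            da, dW, db = _conv_backward(
                dz, conv_cache, w[f"conv{i}_W"], self._buf, f"conv{i}", need_dx=i > 1
            )
            grads[f"conv{i}_W"] = dW
            grads[f"conv{i}_b"] = db
        return grads


def train_model(
    bundle: ModelBundle,
    train_images: np.ndarray,
    train_labels: np.ndarray,
    val_images: np.ndarray,
    val_labels: np.ndarray,
    cfg: TrainConfig | None = None,
) -> tuple[ModelBundle, list[dict]]:
    """Mini-batch Adam training; returns the best-checkpoint bundle and a
    per-epoch history (train loss, validation loss and AUC)."""
    cfg = cfg or TrainConfig()
    cfg.validate()
    net = NumpyCnn(bundle)
    x = _as_input(train_images, bundle.spec)
    y = np.asarray(train_labels, dtype=int)
    if x.shape[0] == 0 or len(val_images) == 0:
        raise TrainingError("training and validation partitions must be non-empty")
    xv = _as_input(val_images, bundle.spec)
    yv = np.asarray(val_labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")
    y_onehot = np.eye(2, dtype=np.float32)[y]

    rng = np.random.default_rng(cfg.seed)
    m = {k: np.zeros_like(v) for k, v in net.weights.items()}
    v = {k: np.zeros_like(w) for k, w in net.weights.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-7
    step = 0
    history: list[dict] = []
    best = {"auc": -np.inf, "epoch": 0, "weights": bundle.copy_weights()}

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(x.shape[0])
        losses = []
        for s in range(0, x.shape[0], cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            probs, cache = net.forward(x[idx], train=True, dropout_rng=rng)
            loss = -np.mean(
                np.log(np.clip(probs[np.arange(idx.size), y[idx]], 1e-12, None))
            )
            losses.append(float(loss))
            grads = net.backward(probs, y_onehot[idx], cache)
            step += 1
            lr_t = cfg.learning_rate / (1.0 + cfg.lr_decay * step)
            for k, g in grads.items():
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1**step)
                vhat = v[k] / (1 - beta2**step)
                net.weights[k] -= (lr_t * mhat / (np.sqrt(vhat) + eps)).astype(np.float32)

        val_probs = net.predict_proba(xv, cfg.batch_size)
        val_loss = -np.mean(
            np.log(np.clip(val_probs[np.arange(yv.size), yv], 1e-12, None))
        )
        val_auc = _rank_auc(val_probs[:, 1], yv)
        history.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": float(val_loss),
                "val_auc": float(val_auc),
            }
        )
        if np.isfinite(val_auc) and val_auc > best["auc"]:
            best = {"auc": float(val_auc), "epoch": epoch, "weights": bundle.copy_weights()}

    if cfg.epochs > 0 and np.isfinite(best["auc"]):
        bundle.weights.update(best["weights"])
    bundle.metadata.update(
        {
            "trained_epochs": cfg.epochs,
            "best_epoch": int(best["epoch"]),
            "best_val_auc": float(best["auc"]) if np.isfinite(best["auc"]) else None,
        }
    )
    return bundle, history
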