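"""Self-contained NumPy engine for small 2D encoder–decoder segmentation nets.

Implements exactly what the per-plane segmenter needs and nothing more:
3x3 same-padded convolutions, ReLU, 2x2 max pooling, nearest-neighbor 2x
upsampling, channel-concatenation skip connections, a 1x1 convolution head,
sigmoid outputs, soft-Dice (and BCE+Dice) losses with analytic gradients, and
an Adam optimizer.  Arrays are channels-last (N, H, W, C) — convolutions
reduce to nine shifted (pixels × channels) @ (channels × channels) BLAS
matmuls, which is the fastest pure-NumPy formulation at these sizes — and
float32 unless the parameters are cast otherwise (gradient-check tests run
the whole engine in float64).

The architecture is a depth-configurable U-Net: ``depth`` encoder levels of
(conv-ReLU, maxpool), a bottleneck conv, and mirrored (upsample, concat skip,
conv-ReLU) decoder levels, followed by a 1x1 conv producing one logit map.
Spatial dims must be divisible by 2**depth.
"""

from __future__ import annotations

import numpy as np

__all__ = ["UNet2D", "Adam", "dice_loss_and_grad", "bce_dice_loss_and_grad", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _conv3x3_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    """x (N,H,W,C), W (3,3,C,Cout), b (Cout,) → y (N,H,W,Cout), cached pad."""
    N, H, Wd, C = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    y = np.zeros((N, H, Wd, W.shape[3]), dtype=x.dtype)
    for u in range(3):
        for v in range(3):
            y += xp[:, u : u + H, v : v + Wd, :] @ W[u, v]
    y += b
    return y, xp


def _conv3x3_backward(dy: np.ndarray, xp: np.ndarray, W: np.ndarray):
    """Gradients of a 3x3 same conv. Returns (dx, dW, db)."""
    N, H, Wd, _ = dy.shape
    dW = np.empty_like(W)
    dxp = np.zeros_like(xp)
    for u in range(3):
        for v in range(3):
            xs = xp[:, u : u + H, v : v + Wd, :]
            dW[u, v] = np.tensordot(xs, dy, axes=([0, 1, 2], [0, 1, 2]))
            dxp[:, u : u + H, v : v + Wd, :] += dy @ W[u, v].T
    db = dy.sum(axis=(0, 1, 2))
    return dxp[:, 1:-1, 1:-1, :], dW, db


def _maxpool2(x: np.ndarray):
    N, H, W, C = x.shape
    win = x.reshape(N, H // 2, 2, W // 2, 2, C).transpose(0, 1, 3, 5, 2, 4)
    win = np.ascontiguousarray(win).reshape(N, H // 2, W // 2, C, 4)
    arg = win.argmax(axis=-1)
    y = np.take_along_axis(win, arg[..., None], axis=-1)[..., 0]
    return y, arg


def _maxpool2_backward(dy: np.ndarray, arg: np.ndarray, x_shape):
    # route each gradient to the single argmax position (first on ties)
    N, H, W, C = x_shape
    dwin = np.zeros(dy.shape + (4,), dtype=dy.dtype)
    np.put_along_axis(dwin, arg[..., None], dy[..., None], axis=-1)
    dwin = dwin.reshape(N, H // 2, W // 2, C, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    return np.ascontiguousarray(dwin).reshape(N, H, W, C)


def _upsample2(x: np.ndarray) -> np.ndarray:
    return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)


def _upsample2_backward(dy: np.ndarray) -> np.ndarray:
    N, H, W, C = dy.shape
    return dy.reshape(N, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


def dice_loss_and_grad(logits: np.ndarray, targets: np.ndarray, eps: float = 1.0):
    """Batch-global soft Dice loss and its gradient w.r.t. the logits."""
    p = sigmoid(logits)
    g = targets
    num = 2.0 * float((p * g).sum()) + eps
    den = float(p.sum()) + float(g.sum()) + eps
    loss = 1.0 - num / den
    dp = -(2.0 * g * den - num) / (den * den)
    dz = dp * p * (1.0 - p)
    return loss, dz.astype(logits.dtype)


def bce_dice_loss_and_grad(logits: np.ndarray, targets: np.ndarray, eps: float = 1.0):
    """Equal-weight sum of mean binary cross-entropy and soft Dice."""
    p = sigmoid(logits)
    g = targets
    bce = float(np.mean(
        np.maximum(logits, 0) - logits * g + np.log1p(np.exp(-np.abs(logits)))
    ))
    dz_bce = (p - g) / p.size
    d_loss, dz_dice = dice_loss_and_grad(logits, targets, eps)
    return bce + d_loss, (dz_bce + dz_dice).astype(logits.dtype)


class UNet2D:
    """Depth-configurable U-Net with one conv per level.

    ``base`` channels at the top level double at each of the ``depth``
    encoder levels; He-normal initialization from ``seed``.  Inputs and
    outputs are channels-last: forward takes (N, H, W, in_ch) and returns
    (N, H, W, 1) logits.
    """

    def __init__(self, in_ch: int = 1, base: int = 8, depth: int = 2, seed: int = 0):
        self.in_ch = in_ch
        self.base = base
        self.depth = depth
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}

        def _conv(name: str, cin: int, cout: int, k: int = 3) -> None:
            std = np.sqrt(2.0 / (cin * k * k))
            self.params[f"{name}.W"] = rng.normal(
                0, std, (k, k, cin, cout)
            ).astype(np.float32)
            self.params[f"{name}.b"] = np.zeros(cout, dtype=np.float32)

        cin = in_ch
        self.enc_ch = []
        for i in range(depth):
            cout = base * 2**i
            _conv(f"enc{i}", cin, cout)
            self.enc_ch.append(cout)
            cin = cout
        _conv("bott", cin, base * 2**depth)
        cin = base * 2**depth
        for i in reversed(range(depth)):
            _conv(f"dec{i}", cin + self.enc_ch[i], self.enc_ch[i])
            cin = self.enc_ch[i]
        _conv("head", cin, 1, k=1)
        self._cache: dict = {}

    @property
    def dtype(self):
        return self.params["head.b"].dtype

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch (N, H, W, in_ch); H, W divisible by 2**depth."""
        if x.shape[1] % 2**self.depth or x.shape[2] % 2**self.depth:
            raise ValueError(
                f"spatial dims {x.shape[1:3]} must be divisible by {2 ** self.depth}"
            )
        cache: dict = {}
        h = np.asarray(x, dtype=self.dtype)
        skips = []
        for i in range(self.depth):
            name = f"enc{i}"
            y, xp = _conv3x3_forward(h, self.params[f"{name}.W"], self.params[f"{name}.b"])
            h = np.maximum(y, 0)
            if train:
                cache[f"{name}.xp"] = xp
                cache[f"{name}.relu"] = h > 0
            skips.append(h)
            h, arg = _maxpool2(h)
            if train:
                cache[f"{name}.pool"] = (arg, skips[-1].shape)
        y, xp = _conv3x3_forward(h, self.params["bott.W"], self.params["bott.b"])
        h = np.maximum(y, 0)
        if train:
            cache["bott.xp"] = xp
            cache["bott.relu"] = h > 0
        for i in reversed(range(self.depth)):
            name = f"dec{i}"
            h = _upsample2(h)
            h = np.concatenate([h, skips[i]], axis=-1)
            y, xp = _conv3x3_forward(h, self.params[f"{name}.W"], self.params[f"{name}.b"])
            h = np.maximum(y, 0)
            if train:
                cache[f"{name}.xp"] = xp
                cache[f"{name}.relu"] = h > 0
        if train:
            cache["head.in"] = h
        logits = h @ self.params["head.W"][0, 0] + self.params["head.b"]
        if train:
            self._cache = cache
        return logits

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        """Parameter gradients given dLoss/dlogits (after forward(train=True))."""
        cache = self._cache
        grads: dict[str, np.ndarray] = {}
        hin = cache["head.in"]
        grads["head.b"] = dlogits.sum(axis=(0, 1, 2))
        gW = np.tensordot(hin, dlogits, axes=([0, 1, 2], [0, 1, 2]))
        grads["head.W"] = gW[None, None]
        dh = dlogits @ self.params["head.W"][0, 0].T

        dskips: dict[int, np.ndarray] = {}
        for i in range(self.depth):
            name = f"dec{i}"
            dh = dh * cache[f"{name}.relu"]
            dx, dW_, db = _conv3x3_backward(
                dh, cache[f"{name}.xp"], self.params[f"{name}.W"]
            )
            grads[f"{name}.W"] = dW_
            grads[f"{name}.b"] = db
            c_up = dx.shape[-1] - self.enc_ch[i]
            dskips[i] = dx[..., c_up:]
            dh = _upsample2_backward(np.ascontiguousarray(dx[..., :c_up]))

        dh = dh * cache["bott.relu"]
        dh, grads["bott.W"], grads["bott.b"] = _conv3x3_backward(
            dh, cache["bott.xp"], self.params["bott.W"]
        )

        for i in reversed(range(self.depth)):
            name = f"enc{i}"
            arg, pre_shape = cache[f"{name}.pool"]
            dpool = _maxpool2_backward(dh, arg, pre_shape)
            dpool = (dpool + dskips[i]) * cache[f"{name}.relu"]
            dh, grads[f"{name}.W"], grads[f"{name}.b"] = _conv3x3_backward(
                dpool, cache[f"{name}.xp"], self.params[f"{name}.W"]
            )
        self._cache = {}
        return grads

    def predict_proba(self, x: np.ndarray, batch_size: int = 16) -> np.ndarray:
        """Sigmoid probabilities for (N, H, W, in_ch) input, returned as (N, H, W)."""
        outs = []
        for i in range(0, x.shape[0], batch_size):
            logits = self.forward(x[i : i + batch_size], train=False)
            outs.append(sigmoid(logits)[..., 0])
        return np.concatenate(outs, axis=0)

    def copy(self) -> "UNet2D":
        clone = UNet2D(self.in_ch, self.base, self.depth, seed=0)
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.array(state[k], dtype=self.params[k].dtype)


class Adam:
    """Standard Adam optimizer over a parameter dict (updates in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        lr_t = self.lr * np.sqrt(1 - b2**self.t) / (1 - b1**self.t)
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            p -= lr_t * self.m[k] / (np.sqrt(self.v[k]) + self.eps)
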