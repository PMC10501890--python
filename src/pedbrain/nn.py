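"""Minimal encoder-decoder segmentation networks in pure numpy.

Both cascade models are small U-Nets: repeated 3x3(x3) convolutions with
ReLU, factor-2 max-pooling on the way down, nearest-neighbour upsampling
plus skip concatenation on the way up, and a 1x1 output convolution.  They
are trained with the soft Dice loss

    L = 1 - mean_c (2 * sum(p_c * t_c) + s) / (sum(p_c) + sum(t_c) + s)

(softmax over channels for multi-class heads, sigmoid for the single
channel head), optimised with Adam.  Convolutions are im2col + GEMM;
gradients are written out by hand and checked against finite differences
in the test suite.  Arrays are ``(N, C, *spatial)`` float32; everything is
deterministic given the initialisation / shuffling seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


# --------------------------------------------------------------- layers


def _im2col(xp: np.ndarray, k: int, nd: int):
    """Columns of all kxk(xk) patches of a padded ``(N, C, *sp)`` array."""
    win = sliding_window_view(xp, (k,) * nd, axis=tuple(range(2, 2 + nd)))
    sp = win.shape[2:2 + nd]
    win = np.moveaxis(win, 1, 1 + nd)  # (N, *sp, C, *k)
    n = xp.shape[0]
    cols = np.ascontiguousarray(win).reshape(n * int(np.prod(sp)), -1)
    return cols, sp


class Conv:
    """Same-padding convolution with odd kernel size."""

    def __init__(self, cin: int, cout: int, ndim: int, rng, kernel: int = 3):
        self.cin, self.cout, self.nd, self.k = cin, cout, ndim, kernel
        fan_in = cin * kernel ** ndim
        self.w = rng.normal(scale=np.sqrt(2.0 / fan_in),
                            size=(cout, cin) + (kernel,) * ndim).astype(DTYPE)
        self.b = np.zeros(cout, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]

    def _pad(self, a):
        p = self.k // 2
        if p == 0:
            return a
        pad = [(0, 0), (0, 0)] + [(p, p)] * self.nd
        return np.pad(a, pad)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        cols, sp = _im2col(self._pad(x), self.k, self.nd)
        y = cols @ self.w.reshape(self.cout, -1).T + self.b
        y = y.reshape((x.shape[0],) + sp + (self.cout,))
        return np.ascontiguousarray(np.moveaxis(y, -1, 1))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        n = x.shape[0]
        dy_flat = np.moveaxis(dy, 1, -1).reshape(-1, self.cout)
        cols, _ = _im2col(self._pad(x), self.k, self.nd)
        self.dw += (dy_flat.T @ cols).reshape(self.w.shape)
        self.db += dy_flat.sum(axis=0)
        # dx = dy convolved with the flipped, transposed kernel
        wt = np.flip(self.w, axis=tuple(range(2, 2 + self.nd)))
        wt = np.swapaxes(wt, 0, 1).reshape(self.cin, -1)  # (cin, cout*k^d)
        cols_dy, sp = _im2col(self._pad(dy), self.k, self.nd)
        dx = (cols_dy @ wt.T).reshape((n,) + sp + (self.cin,))
        return np.ascontiguousarray(np.moveaxis(dx, -1, 1))


class ReLU:
    params = ()

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


def _to_blocks(x, nd):
    """Reshape ``(N, C, *sp)`` to ``(N, C, *sp/2, 2**nd)`` factor-2 blocks."""
    shape = [x.shape[0], x.shape[1]]
    for s in x.shape[2:]:
        shape += [s // 2, 2]
    xr = x.reshape(shape)
    block_axes = [3 + 2 * i for i in range(nd)]
    xr = np.moveaxis(xr, block_axes, range(-nd, 0))
    return xr.reshape(xr.shape[:2 + nd] + (-1,)), xr.shape

def _from_blocks(blocks, xr_shape, nd, out_shape):
    xr = blocks.reshape(xr_shape)
    block_axes = [3 + 2 * i for i in range(nd)]
    xr = np.moveaxis(xr, range(-nd, 0), block_axes)
    return xr.reshape(out_shape)


class MaxPool:
    """Factor-2 max pooling over every spatial dimension."""
    params = ()

    def __init__(self, ndim):
        self.nd = ndim

    def forward(self, x):
        self._in_shape = x.shape
        blocks, self._xr_shape = _to_blocks(x, self.nd)
        self._arg = blocks.argmax(axis=-1)
        return np.take_along_axis(blocks, self._arg[..., None], -1)[..., 0]

    def backward(self, dy):
        blocks = np.zeros(self._xr_shape, dtype=dy.dtype).reshape(
            self._xr_shape[:2 + self.nd] + (-1,))
        np.put_along_axis(blocks, self._arg[..., None], dy[..., None], -1)
        return _from_blocks(blocks, self._xr_shape, self.nd, self._in_shape)


class Upsample:
    """Factor-2 nearest-neighbour upsampling."""
    params = ()

    def __init__(self, ndim):
        self.nd = ndim

    def forward(self, x):
        for ax in range(2, 2 + self.nd):
            x = np.repeat(x, 2, axis=ax)
        return x

    def backward(self, dy):
        blocks, xr_shape = _to_blocks(dy, self.nd)
        return blocks.sum(axis=-1)


# --------------------------------------------------------------- the U-Net


class UNet:
    """Encoder-decoder with skip connections; ``ndim`` 2 or 3."""

    def __init__(self, ndim: int, in_channels: int, out_channels: int,
                 base_channels: int = 8, depth: int = 2,
                 convs_per_block: int = 1, seed: int = 0):
        if ndim not in (2, 3):
            raise ValueError("ndim must be 2 or 3")
        if depth < 1:
            raise ValueError("depth must be >= 1")
        self.config = dict(ndim=ndim, in_channels=in_channels,
                           out_channels=out_channels,
                           base_channels=base_channels, depth=depth,
                           convs_per_block=convs_per_block, seed=seed)
        rng = np.random.default_rng(seed)
        ch = [base_channels * 2 ** i for i in range(depth + 1)]
        self.nd, self.depth = ndim, depth

        def block(cin, cout):
            layers = []
            for i in range(convs_per_block):
                layers += [Conv(cin if i == 0 else cout, cout, ndim, rng), ReLU()]
            return layers

        self.enc = [block(in_channels if d == 0 else ch[d - 1], ch[d])
                    for d in range(depth)]
        self.pools = [MaxPool(ndim) for _ in range(depth)]
        self.bottleneck = block(ch[depth - 1], ch[depth])
        self.ups = [Upsample(ndim) for _ in range(depth)]
        self.dec = [block(ch[d] + ch[d + 1], ch[d]) for d in range(depth)]
        self.out_conv = Conv(ch[0], out_channels, ndim, rng, kernel=1)

    # -- plumbing

    def _all_layers(self):
        for blk in self.enc + [self.bottleneck] + self.dec:
            yield from blk
        yield self.out_conv

    @property
    def params(self):
        out = []
        for layer in self._all_layers():
            out.extend(layer.params)
        return out

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0

    def check_input(self, x):
        for s in x.shape[2:]:
            if s % (2 ** self.depth):
                raise ValueError(f"spatial dims {x.shape[2:]} not divisible "
                                 f"by 2**depth={2 ** self.depth}")

    # -- forward / backward

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.check_input(x)
        h = np.ascontiguousarray(x, dtype=DTYPE)
        skips = []
        for d in range(self.depth):
            for layer in self.enc[d]:
                h = layer.forward(h)
            skips.append(h)
            h = self.pools[d].forward(h)
        for layer in self.bottleneck:
            h = layer.forward(h)
        self._skip_channels = [s.shape[1] for s in skips]
        for d in reversed(range(self.depth)):
            h = self.ups[d].forward(h)
            h = np.concatenate([skips[d], h], axis=1)
            for layer in self.dec[d]:
                h = layer.forward(h)
        return self.out_conv.forward(h)

    def backward(self, dlogits: np.ndarray) -> None:
        h = self.out_conv.backward(dlogits)
        dskips = [None] * self.depth
        for d in range(self.depth):
            for layer in reversed(self.dec[d]):
                h = layer.backward(h)
            c = self._skip_channels[d]
            dskips[d], h = h[:, :c], h[:, c:]
            h = self.ups[d].backward(h)
        for layer in reversed(self.bottleneck):
            h = layer.backward(h)
        for d in reversed(range(self.depth)):
            h = self.pools[d].backward(h)
            h = h + dskips[d]
            for layer in reversed(self.enc[d]):
                h = layer.backward(h)

    # -- state

    def state_arrays(self):
        return {f"p{i}": w for i, (w, _) in enumerate(self.params)}

    def load_state_arrays(self, arrays):
        for i, (w, _) in enumerate(self.params):
            w[...] = arrays[f"p{i}"]

    def copy_state(self):
        return [w.copy() for w, _ in self.params]

    def restore_state(self, state):
        for (w, _), saved in zip(self.params, state):
            w[...] = saved


def save_checkpoint(net: UNet, path) -> None:
    np.savez(path, __config__=np.frombuffer(
        json.dumps(net.config).encode(), dtype=np.uint8), **net.state_arrays())


def load_checkpoint(path) -> UNet:
    with np.load(path) as data:
        cfg = json.loads(bytes(data["__config__"]).decode())
        net = UNet(**cfg)
        net.load_state_arrays(data)
    return net


# --------------------------------------------------------------- losses


def dice_loss(prediction: np.ndarray, target: np.ndarray,
              smooth: float = 1e-6) -> float:
    """Soft Dice loss of per-voxel class probabilities vs a one-hot target.

    Channel axis is 1 (or 0 for unbatched single arrays without channels
    use shape ``(C, ...)``); the loss is one minus the channel-mean soft
    Dice coefficient and lies in ``[0, 1]``.
    """
    prediction = np.asarray(prediction, dtype=float)
    target = np.asarray(target, dtype=float)
    if prediction.shape != target.shape:
        raise ValueError(f"shape mismatch {prediction.shape} vs {target.shape}")
    if prediction.min() < 0 or prediction.max() > 1:
        raise ValueError("prediction values must lie in [0, 1]")
    # flatten everything except the leading channel axis
    p = prediction.reshape(prediction.shape[0], -1)
    t = target.reshape(target.shape[0], -1)
    num = 2.0 * (p * t).sum(axis=1) + smooth
    den = p.sum(axis=1) + t.sum(axis=1) + smooth
    return float(1.0 - np.mean(num / den))


def _softmax(z, axis=1):
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_dice(logits, target, smooth=1.0, mask=None):
    """Loss and d(loss)/d(logits) for a softmax Dice head.

    ``mask`` (broadcastable ``(N, 1, *sp)``) restricts the loss to a region
    (e.g. brain voxels for the lobe head, the whole-tumor mask for the
    cascade's second stage).
    """
    p = _softmax(logits.astype(np.float64))
    pm = p * mask if mask is not None else p
    tm = target * mask if mask is not None else target
    c = p.shape[1]
    axes = (0,) + tuple(range(2, p.ndim))
    inter = (pm * tm).sum(axis=axes)
    num = 2.0 * inter + smooth
    den = pm.sum(axis=axes) + tm.sum(axis=axes) + smooth
    loss = float(1.0 - np.mean(num / den))
    shape = [1, c] + [1] * (p.ndim - 2)
    dnum = (2.0 * tm * den.reshape(shape) - num.reshape(shape))
    dpm = -(dnum / (den ** 2).reshape(shape)) / c
    dp = dpm * mask if mask is not None else dpm
    dz = p * (dp - (dp * p).sum(axis=1, keepdims=True))
    return loss, dz.astype(DTYPE)


def sigmoid_dice(logits, target, smooth=1.0):
    """Loss and gradient for a single-channel sigmoid Dice head.

    The Dice term is computed per sample and averaged over the batch, so
    each (tumor-bearing) slice keeps its own normalisation; a global batch
    Dice lets the many near-empty slices drown the foreground gradient and
    the optimiser collapse into the empty-prediction attractor.
    """
    from scipy.special import expit
    p = expit(logits.astype(np.float64))
    n = p.shape[0]
    axes = tuple(range(1, p.ndim))
    inter = (p * target).sum(axis=axes)
    num = 2.0 * inter + smooth
    den = p.sum(axis=axes) + target.sum(axis=axes) + smooth
    loss = float(np.mean(1.0 - num / den))
    shape = (n,) + (1,) * (p.ndim - 1)
    dp = -(2.0 * target * den.reshape(shape) - num.reshape(shape)) \
        / (den ** 2).reshape(shape) / n
    dz = dp * p * (1.0 - p)
    return loss, dz.astype(DTYPE)


# --------------------------------------------------------------- optimiser


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(w) for w, _ in params]
        self.v = [np.zeros_like(w) for w, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (w, g) in enumerate(self.params):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            w -= (self.lr * (self.m[i] / b1t)
                  / (np.sqrt(self.v[i] / b2t) + self.eps)).astype(w.dtype)


# --------------------------------------------------------------- training


@dataclass
class TrainingCurve:
    """Per-epoch training and validation Dice-loss records."""
    records: list = field(default_factory=list)

    def append(self, epoch, train_loss, val_loss):
        self.records.append({"epoch": epoch, "train_loss": train_loss,
                             "val_loss": val_loss})

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.records)

    @property
    def epochs(self):
        return [r["epoch"] for r in self.records]


def train_network(net: UNet, loss_fn: Callable, train_items, val_items,
                  max_epochs: int, patience: Optional[int], lr: float,
                  seed: int, augment_fn: Callable = None) -> TrainingCurve:
    """Generic seeded training loop with early stopping on validation loss.

    ``train_items`` / ``val_items`` are lists of ``(x, target, mask)``
    batches; ``loss_fn(logits, target, mask)`` returns ``(loss, dlogits)``.
    The network is left at the best-validation-loss state.  ``patience=0``
    stops at the first epoch without improvement; ``patience=None`` never
    stops early.
    """
    if not train_items or not val_items:
        raise ValueError("need at least one training and one validation item")
    rng = np.random.default_rng(seed)
    opt = Adam(net.params, lr=lr)
    curve = TrainingCurve()
    best_val, best_state, since_best = np.inf, None, 0
    for epoch in range(1, max_epochs + 1):
        order = rng.permutation(len(train_items))
        train_losses = []
        for idx in order:
            x, t, m = train_items[idx]
            if augment_fn is not None:
                x, t, m = augment_fn(x, t, m, rng)
            net.zero_grad()
            logits = net.forward(x)
            loss, dz = loss_fn(logits, t, m)
            net.backward(dz)
            opt.step()
            train_losses.append(loss)
        val_losses = [loss_fn(net.forward(x), t, m)[0] for x, t, m in val_items]
        val_loss = float(np.mean(val_losses))
        curve.append(epoch, float(np.mean(train_losses)), val_loss)
        if val_loss < best_val - 1e-6:
            best_val, best_state, since_best = val_loss, net.copy_state(), 0
        else:
            since_best += 1
            if patience is not None and since_best > patience:
                break
    if best_state is not None:
        net.restore_state(best_state)
    return curve


def flip_scale_augment(x, t, m, rng):
    """Random left-right flip plus +/-10% intensity scaling."""
    if rng.random() < 0.5:
        x, t = np.flip(x, axis=2), np.flip(t, axis=2)
        m = np.flip(m, axis=2) if m is not None else None
    x = x * (1.0 + rng.uniform(-0.1, 0.1))
    return np.ascontiguousarray(x), np.ascontiguousarray(t), \
        (np.ascontiguousarray(m) if m is not None else None)
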