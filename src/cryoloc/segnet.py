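"""Dual U-net segmentation of marker and shaft, implemented in numpy.

Two encoder-decoder networks of the same architecture: U-net^marker maps a
grayscale frame to a soft marker mask; U-net^shaft takes the frame plus a
marker mask as a second input channel and predicts the shaft centerline
mask. The encoder downsamples with 2x2 maxpooling, the decoder upsamples
with 2x2 strided transposed convolutions and skip concatenations, dropout
regularizes the bottleneck, and an additive residual connection feeds the
input image into the output stage. Training uses per-pixel binary
cross-entropy (optionally class-weighted, or soft-Dice) with the Adam
optimizer.

The whole network — im2col convolutions, pooling, transposed convolutions,
backpropagation and Adam — is written on numpy in float32, which keeps
training deterministic under a seed and dependency-free; desk-scale image
sizes (64-128 px) train in minutes on one CPU.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "UNetConfig",
    "TrainConfig",
    "UNet",
    "build_unet",
    "train",
    "predict_marker",
    "predict_shaft",
    "save_model",
    "load_model",
    "DEFAULT_EPOCHS",
    "DEFAULT_MARKER_BATCH",
    "DEFAULT_SHAFT_BATCH",
]

#: Training defaults mirroring the clinical setup.
DEFAULT_EPOCHS = 50
DEFAULT_MARKER_BATCH = 8
DEFAULT_SHAFT_BATCH = 4


@dataclass(frozen=True)
class UNetConfig:
    """Architecture parameters.

    ``input_channels`` is 1 for the marker net and 2 for the shaft net
    (image + marker mask). ``image_size_px`` must be divisible by
    ``2**depth``.
    """

    input_channels: int = 1
    depth: int = 4
    base_filters: int = 16
    dropout_rate: float = 0.5
    residual_output: bool = True
    image_size_px: int = 512

    def __post_init__(self):
        if self.input_channels not in (1, 2):
            raise ValueError(f"input_channels must be 1 or 2, got {self.input_channels}")
        if self.image_size_px % (2**self.depth) != 0:
            raise ValueError(
                f"image size {self.image_size_px} not divisible by 2^depth = {2**self.depth}"
            )
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization parameters (adaptive moment estimation)."""

    epochs: int = DEFAULT_EPOCHS
    batch_size: int = DEFAULT_MARKER_BATCH
    learning_rate: float = 1e-3
    loss: str = "bce"  # "bce" or "dice"
    pos_weight: float = 1.0  # foreground class weight for BCE
    rng_seed: int = 0
    validation_fraction: float = 0.15
    augment_flips: bool = False

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.loss not in ("bce", "dice"):
            raise ValueError(f"unknown loss {self.loss!r}")


# ---------------------------------------------------------------------------
# Layers (NHWC, float32)
# ---------------------------------------------------------------------------

def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, 9*C) patches for 3x3 same-padding convolution."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = sliding_window_view(xp, (3, 3), axis=(1, 2))  # (N, H, W, C, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * w, 9 * c)


def _conv3_raw(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """3x3 same-padding convolution with kernel (3, 3, Cin, Cout)."""
    n, h, wd, cin = x.shape
    cout = w.shape[3]
    y = _im2col3(x) @ w.reshape(9 * cin, cout)
    return y.reshape(n, h, wd, cout)


class _Conv3x3:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (9 * cin))
        self.W = rng.normal(0.0, scale, (3, 3, cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, cache: bool) -> np.ndarray:
        cin, cout = self.W.shape[2], self.W.shape[3]
        n, h, w, _ = x.shape
        cols = _im2col3(x)
        if cache:
            self._cols = cols
        y = cols @ self.W.reshape(9 * cin, cout) + self.b
        return y.reshape(n, h, w, cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cin, cout = self.W.shape[2], self.W.shape[3]
        dyf = dy.reshape(-1, cout)
        self.dW = (self._cols.T @ dyf).reshape(3, 3, cin, cout)
        self.db = dyf.sum(axis=0)
        self._cols = None
        w_rot = self.W[::-1, ::-1].transpose(0, 1, 3, 2)  # (3, 3, Cout, Cin)
        return _conv3_raw(dy, np.ascontiguousarray(w_rot))

    def params(self):
        return [("W", self), ("b", self)]


class _Conv1x1:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / cin), (cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, cache):
        n, h, w, cin = x.shape
        if cache:
            self._x = x
        return (x.reshape(-1, cin) @ self.W + self.b).reshape(n, h, w, -1)

    def backward(self, dy):
        n, h, w, cout = dy.shape
        cin = self.W.shape[0]
        dyf = dy.reshape(-1, cout)
        self.dW = self._x.reshape(-1, cin).T @ dyf
        self.db = dyf.sum(axis=0)
        self._x = None
        return (dyf @ self.W.T).reshape(n, h, w, cin)


class _ConvT2x2:
    """2x2 stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / cin), (cin, 2, 2, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, cache):
        n, h, w, cin = x.shape
        cout = self.W.shape[3]
        if cache:
            self._x = x
        y = x.reshape(-1, cin) @ self.W.reshape(cin, 4 * cout)
        y = y.reshape(n, h, w, 2, 2, cout).transpose(0, 1, 3, 2, 4, 5)
        return np.ascontiguousarray(y).reshape(n, 2 * h, 2 * w, cout) + self.b

    def backward(self, dy):
        n, h2, w2, cout = dy.shape
        h, w = h2 // 2, w2 // 2
        cin = self.W.shape[0]
        blocks = dy.reshape(n, h, 2, w, 2, cout).transpose(0, 1, 3, 2, 4, 5)
        blocks = np.ascontiguousarray(blocks).reshape(-1, 4 * cout)
        self.dW = (self._x.reshape(-1, cin).T @ blocks).reshape(cin, 2, 2, cout)
        self.db = dy.reshape(-1, cout).sum(axis=0)
        self._x = None
        dx = blocks @ self.W.reshape(cin, 4 * cout).T
        return dx.reshape(n, h, w, cin)


def _relu_forward(x):
    return np.maximum(x, 0.0)


def _maxpool2_forward(x):
    n, h, w, c = x.shape
    xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    xr = np.ascontiguousarray(xr).reshape(n, h // 2, w // 2, 4, c)
    idx = np.argmax(xr, axis=3)
    y = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
    return y, idx


def _maxpool2_backward(dy, idx, in_shape):
    n, h, w, c = in_shape
    dxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=dy.dtype)
    np.put_along_axis(dxr, idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
    dxr = dxr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
    return np.ascontiguousarray(dxr).reshape(n, h, w, c)


# ---------------------------------------------------------------------------
# U-net model
# ---------------------------------------------------------------------------

class UNet:
    """Encoder-decoder network; see module docstring for topology."""

    def __init__(self, config: UNetConfig, rng_seed: int = 0):
        self.config = config
        rng = np.random.default_rng([rng_seed & 0x7FFFFFFF, 0x0E7])
        f = config.base_filters
        self.enc: list[tuple[_Conv3x3, _Conv3x3]] = []
        cin = config.input_channels
        for level in range(config.depth):
            cout = f * (2**level)
            self.enc.append((_Conv3x3(cin, cout, rng), _Conv3x3(cout, cout, rng)))
            cin = cout
        cbot = f * (2**config.depth)
        self.bot = (_Conv3x3(cin, cbot, rng), _Conv3x3(cbot, cbot, rng))
        self.up: list[_ConvT2x2] = []
        self.dec: list[tuple[_Conv3x3, _Conv3x3]] = []
        cin = cbot
        for level in reversed(range(config.depth)):
            cout = f * (2**level)
            self.up.append(_ConvT2x2(cin, cout, rng))
            self.dec.append((_Conv3x3(2 * cout, cout, rng), _Conv3x3(cout, cout, rng)))
            cin = cout
        head_in = cin + (1 if config.residual_output else 0)
        self.head = _Conv1x1(head_in, 1, rng)

    # -- parameter plumbing -------------------------------------------------
    def _layers(self):
        for c1, c2 in self.enc:
            yield c1
            yield c2
        yield self.bot[0]
        yield self.bot[1]
        for u, (c1, c2) in zip(self.up, self.dec):
            yield u
            yield c1
            yield c2
        yield self.head

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend([layer.W, layer.b])
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for layer in self._layers():
            out.extend([layer.dW, layer.db])
        return out

    def set_parameters(self, values: Sequence[np.ndarray]) -> None:
        it = iter(values)
        for layer in self._layers():
            layer.W = np.asarray(next(it), dtype=np.float32).reshape(layer.W.shape)
            layer.b = np.asarray(next(it), dtype=np.float32).reshape(layer.b.shape)

    @property
    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False,
                dropout_rng: np.random.Generator | None = None) -> np.ndarray:
        """Compute logits for input (N, H, W, C) in [0, 1]."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[3] != self.config.input_channels:
            raise ValueError(
                f"expected (N, H, W, {self.config.input_channels}) input, got {x.shape}"
            )
        if x.shape[1] % (2**self.config.depth) or x.shape[2] % (2**self.config.depth):
            raise ValueError(
                f"input size {x.shape[1:3]} not divisible by 2^depth"
            )
        cache = train
        self._cache = {"x0": x}
        skips, relus, pools = [], [], []
        h = x
        for li, (c1, c2) in enumerate(self.enc):
            a = _relu_forward(c1.forward(h, cache))
            b = _relu_forward(c2.forward(a, cache))
            skips.append(b)
            relus.append((a, b))
            h, idx = _maxpool2_forward(b)
            pools.append((idx, b.shape))
        a = _relu_forward(self.bot[0].forward(h, cache))
        b = _relu_forward(self.bot[1].forward(a, cache))
        relus.append((a, b))
        if train and self.config.dropout_rate > 0:
            if dropout_rng is None:
                dropout_rng = np.random.default_rng(0)
            keep = 1.0 - self.config.dropout_rate
            mask = (dropout_rng.random(b.shape) < keep).astype(np.float32) / keep
            self._cache["dropout_mask"] = mask
            h = b * mask
        else:
            h = b
        dec_relus = []
        for li, (u, (c1, c2)) in enumerate(zip(self.up, self.dec)):
            upped = u.forward(h, cache)
            skip = skips[-(li + 1)]
            cat = np.concatenate([upped, skip], axis=3)
            if cache:
                self._cache[f"cat_split_{li}"] = upped.shape[3]
            a = _relu_forward(c1.forward(cat, cache))
            b2 = _relu_forward(c2.forward(a, cache))
            dec_relus.append((a, b2))
            h = b2
        if self.config.residual_output:
            h = np.concatenate([h, x[:, :, :, :1]], axis=3)
        logits = self.head.forward(h, cache)[:, :, :, 0]
        if cache:
            self._cache.update(relus=relus, pools=pools, dec_relus=dec_relus)
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        c = self._cache
        d = self.head.backward(dlogits[:, :, :, None].astype(np.float32))
        if self.config.residual_output:
            d = d[:, :, :, :-1]
        for li in reversed(range(len(self.dec))):
            a, b2 = c["dec_relus"][li]
            u, (c1, c2) = self.up[li], self.dec[li]
            d = c2.backward(d * (b2 > 0))
            d = c1.backward(d * (a > 0))
            split = c[f"cat_split_{li}"]
            d_up, d_skip = d[:, :, :, :split], d[:, :, :, split:]
            d = u.backward(np.ascontiguousarray(d_up))
            c.setdefault("skip_grads", {})[len(self.dec) - 1 - li] = d_skip
        a, b = c["relus"][-1]
        if "dropout_mask" in c:
            d = d * c["dropout_mask"]
        d = self.bot[1].backward(d * (b > 0))
        d = self.bot[0].backward(d * (a > 0))
        for li in reversed(range(len(self.enc))):
            idx, shape = c["pools"][li]
            d = _maxpool2_backward(d, idx, shape)
            d = d + c["skip_grads"][li]
            a, b = c["relus"][li]
            c1, c2 = self.enc[li]
            d = c2.backward(d * (b > 0))
            d = c1.backward(d * (a > 0))
        self._cache = {}


def build_unet(config: UNetConfig, rng_seed: int = 0) -> UNet:
    """Construct a U-net for the given configuration."""
    return UNet(config, rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# Loss and optimizer
# ---------------------------------------------------------------------------

def _bce_with_logits(logits, targets, pos_weight=1.0):
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    softplus = np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0)
    # elementwise: w_pos * y * softplus(-z) + (1 - y) * softplus(z)
    loss_el = pos_weight * y * (softplus - z) + (1.0 - y) * softplus
    n = z.size
    loss = float(loss_el.sum() / n)
    sig = 1.0 / (1.0 + np.exp(-z))
    grad = ((1.0 - y) * sig - pos_weight * y * (1.0 - sig)) / n
    return loss, grad.astype(np.float32)


def _dice_loss(logits, targets, eps=1.0):
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    p = 1.0 / (1.0 + np.exp(-z))
    axes = (1, 2)
    inter = (p * y).sum(axis=axes)
    denom = p.sum(axis=axes) + y.sum(axis=axes)
    dice = (2.0 * inter + eps) / (denom + eps)
    loss = float((1.0 - dice).mean())
    ddice_dp = (2.0 * y * (denom + eps)[:, None, None]
                - (2.0 * inter + eps)[:, None, None]) / (denom + eps)[:, None, None] ** 2
    grad = -(ddice_dp / z.shape[0]) * p * (1.0 - p)
    return loss, grad.astype(np.float32)


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------

def train(
    model: UNet,
    images: np.ndarray,
    targets: np.ndarray,
    train_config: TrainConfig,
    val_images: np.ndarray | None = None,
    val_targets: np.ndarray | None = None,
) -> dict:
    """Train a U-net; returns ``{"train_loss": [...], "val_loss": [...]}``.

    ``images`` is (N, H, W, C) in [0, 1]; ``targets`` is (N, H, W) binary.
    When no explicit validation set is given, ``validation_fraction`` of the
    samples is split off deterministically. The best-validation-loss
    weights are restored into the model at the end.
    """
    images = np.asarray(images, dtype=np.float32)
    targets = np.asarray(targets, dtype=np.float32)
    if images.ndim != 4 or targets.shape != images.shape[:3]:
        raise ValueError(
            f"shape mismatch: images {images.shape} vs targets {targets.shape}"
        )
    if images.max() > 1.0 + 1e-6 or images.min() < -1e-6:
        raise ValueError("images must be normalized to [0, 1]")
    rng = np.random.default_rng([train_config.rng_seed & 0x7FFFFFFF, 0x7124])

    if val_images is None:
        n = len(images)
        n_val = max(int(round(train_config.validation_fraction * n)), 1)
        if n - n_val < 1:
            raise ValueError("need at least one training and one validation sample")
        order = rng.permutation(n)
        val_idx, tr_idx = order[:n_val], order[n_val:]
        val_images, val_targets = images[val_idx], targets[val_idx]
        images, targets = images[tr_idx], targets[tr_idx]
    else:
        val_images = np.asarray(val_images, dtype=np.float32)
        val_targets = np.asarray(val_targets, dtype=np.float32)

    loss_fn = _bce_with_logits if train_config.loss == "bce" else _dice_loss
    kw = {"pos_weight": train_config.pos_weight} if train_config.loss == "bce" else {}
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_params = [p.copy() for p in model.parameters()]
    opt = _Adam(model.parameters(), lr=train_config.learning_rate)

    n = len(images)
    bs = min(train_config.batch_size, n)
    for epoch in range(train_config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, bs):
            idx = order[start: start + bs]
            xb, yb = images[idx], targets[idx]
            if train_config.augment_flips:
                if rng.random() < 0.5:
                    xb, yb = xb[:, :, ::-1], yb[:, :, ::-1]
                if rng.random() < 0.5:
                    xb, yb = xb[:, ::-1], yb[:, ::-1]
            logits = model.forward(np.ascontiguousarray(xb), train=True, dropout_rng=rng)
            loss, grad = loss_fn(logits, np.ascontiguousarray(yb), **kw)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {epoch}, batch start {start}; "
                    f"logit range [{logits.min():.3g}, {logits.max():.3g}]"
                )
            model.backward(grad)
            opt.step(model.parameters(), model.gradients())
            epoch_loss += loss * len(idx)
        history["train_loss"].append(epoch_loss / n)

        val_loss = 0.0
        for start in range(0, len(val_images), bs):
            xb = val_images[start: start + bs]
            yb = val_targets[start: start + bs]
            logits = model.forward(xb, train=False)
            val_loss += loss_fn(logits, yb, **kw)[0] * len(xb)
        val_loss /= len(val_images)
        history["val_loss"].append(val_loss)
        if val_loss < best_val:
            best_val = val_loss
            best_params = [p.copy() for p in model.parameters()]
    model.set_parameters(best_params)
    return history


def _predict(model: UNet, x: np.ndarray) -> np.ndarray:
    logits = model.forward(x[None, ...], train=False)[0]
    return (1.0 / (1.0 + np.exp(-logits.astype(np.float64)))).astype(np.float32)


def predict_marker(model: UNet, image: np.ndarray) -> np.ndarray:
    """Predict the soft marker mask for one grayscale frame (uint8 or [0,1])."""
    if model.config.input_channels != 1:
        raise ValueError("marker model must have 1 input channel")
    x = np.asarray(image, dtype=np.float32)
    if x.max() > 1.0:
        x = x / 255.0
    return _predict(model, x[:, :, None])


def predict_shaft(model: UNet, image: np.ndarray, marker_mask: np.ndarray) -> np.ndarray:
    """Predict the soft shaft mask from a frame plus a marker mask.

    The marker mask may be the soft prediction of the marker net or an
    annotated binary mask; both are normalized to [0, 1].
    """
    if model.config.input_channels != 2:
        raise ValueError("shaft model must have 2 input channels")
    x = np.asarray(image, dtype=np.float32)
    if x.max() > 1.0:
        x = x / 255.0
    m = np.asarray(marker_mask, dtype=np.float32)
    if m.max() > 1.0:
        m = m / 255.0
    if m.shape != x.shape:
        raise ValueError(f"image {x.shape} and marker mask {m.shape} shapes differ")
    return _predict(model, np.stack([x, m], axis=2))


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_model(model: UNet, path: str | Path) -> None:
    """Save weights as .npz with a JSON sidecar holding the configuration."""
    path = Path(path)
    arrays = {f"p{i:03d}": p for i, p in enumerate(model.parameters())}
    np.savez(path, **arrays)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(model.config), indent=2))


def load_model(path: str | Path) -> UNet:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    config = UNetConfig(**json.loads(sidecar.read_text()))
    model = UNet(config)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz_path) as data:
        model.set_parameters([data[k] for k in sorted(data.files)])
    return model
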