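"""Trainable slice-wise encoder–decoder segmentation.

A compact convolutional encoder–decoder, implemented directly on NumPy,
that learns a per-pixel foreground probability from annotated 2D tiles and
is applied slice-by-slice to full 3D stacks.  The reference configuration
mirrors slice-wise semantic segmentation of light-sheet stacks: four
encoding and four decoding levels, single input intensity channel rescaled
to [0, 1], single output label map, a 0.75/0.20/0.05 train/validation/test
split, 350 training epochs, five augmentation operations (skew, rotation,
flip, zoom, random distortion) each applied independently with probability
0.30, 512x512 training tiles and a factor-2 downsampling at inference.

Training minimizes a soft-dice loss (the dice coefficient is also the
reported validation metric) with Adam.  All randomness — split membership,
shuffling, augmentation — derives from the spec seed, so training twice with
the same seed reproduces the same split and the same weights.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .segmentation import dice_coefficient
from .volio import ChannelVolume

AUGMENTATION_OPS = ("skew", "rotation", "flip", "zoom", "distortion")


@dataclass
class SegModelSpec:
    """Architecture and training schedule of the slice segmenter."""

    levels: int = 4                      # encoding (= decoding) levels
    base_channels: int = 8
    epochs: int = 350
    split: tuple[float, float, float] = (0.75, 0.20, 0.05)
    augment_prob: float = 0.30           # per op, independently
    tile_size: int = 512
    downsample_factor: int = 2           # inference-time slice downsampling
    learning_rate: float = 0.01
    batch_size: int = 4
    seed: int = 0

    def validate(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("train/validation/test fractions must sum to 1")
        if not 0.0 <= self.augment_prob <= 1.0:
            raise ValueError("augment_prob must lie in [0, 1]")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.tile_size % (2 ** self.levels) != 0:
            raise ValueError(
                f"tile_size {self.tile_size} must be divisible by 2^levels "
                f"({2 ** self.levels})"
            )


# ---------------------------------------------------------------------------
# NumPy layers (im2col convolutions)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N,C,H,W), odd k -> (N, C*k*k, H*W) with same-size zero padding."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # windows: (N, C, H, W, k, k)
    return windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * k * k, h * w)


def _col2im(cols: np.ndarray, x_shape, k: int) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add back to the padded image)."""
    n, c, h, w = x_shape
    p = k // 2
    xp = np.zeros((n, c, h + 2 * p, w + 2 * p))
    cols = cols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + h, j:j + w] += cols[:, :, i, j]
    return xp[:, :, p:p + h, p:p + w]


class _Conv:
    def __init__(self, c_in, c_out, k, rng):
        scale = np.sqrt(2.0 / (c_in * k * k))      # He initialization
        self.W = rng.normal(0.0, scale, size=(c_out, c_in * k * k))
        self.b = np.zeros(c_out)
        self.k = k

    def forward(self, x):
        self._x_shape = x.shape
        self._cols = _im2col(x, self.k)
        n, _, hw = self._cols.shape
        out = np.einsum("oc,ncp->nop", self.W, self._cols) + self.b[None, :, None]
        h, w = x.shape[2], x.shape[3]
        return out.reshape(n, -1, h, w)

    def backward(self, grad):
        n, c_out, h, w = grad.shape
        g = grad.reshape(n, c_out, h * w)
        self.dW = np.einsum("nop,ncp->oc", g, self._cols) / n
        self.db = g.sum(axis=(0, 2)) / n
        dcols = np.einsum("oc,nop->ncp", self.W, g)
        return _col2im(dcols, self._x_shape, self.k)

    @property
    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _ReLU:
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, grad):
        return grad * self._m


class _MaxPool2:
    def forward(self, x):
        n, c, h, w = x.shape
        self._in_shape = x.shape
        xv = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xv.max(axis=(3, 5))
        mask = xv == out[:, :, :, None, :, None]
        # break ties toward the first max so the adjoint stays well-defined
        maskr = mask.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        cum = np.cumsum(maskr, axis=-1)
        self._first = (cum == 1) & maskr
        return out

    def backward(self, grad):
        n, c, h, w = self._in_shape
        g = np.zeros((n, c, h // 2, w // 2, 4))
        g[self._first] = grad.reshape(n, c, h // 2, w // 2, 1).repeat(4, axis=-1)[self._first]
        g = g.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return g.reshape(n, c, h, w)


class _UpNearest2:
    def forward(self, x):
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, grad):
        n, c, h, w = grad.shape
        return grad.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class SliceSegmenter:
    """The trained model handle: an encoder–decoder with skip connections
    over single-channel tiles."""

    def __init__(self, spec: SegModelSpec, rng: np.random.Generator | None = None):
        spec.validate()
        self.spec = spec
        self.validation_dice: float | None = None
        rng = rng or np.random.default_rng(spec.seed)
        channels = [min(spec.base_channels * 2 ** l, 32) for l in range(spec.levels)]
        self.enc_convs, self.enc_relus, self.pools = [], [], []
        c_in = 1
        for c in channels:
            self.enc_convs.append(_Conv(c_in, c, 3, rng))
            self.enc_relus.append(_ReLU())
            self.pools.append(_MaxPool2())
            c_in = c
        self.dec_convs, self.dec_relus, self.ups = [], [], []
        for c in reversed(channels):
            self.ups.append(_UpNearest2())
            # decoder conv sees upsampled features concatenated with the
            # same-resolution encoder features (skip connection)
            self.dec_convs.append(_Conv(c_in + c, c, 3, rng))
            self.dec_relus.append(_ReLU())
            c_in = c
        self._head = _Conv(c_in, 1, 1, rng)

    # -- forward/backward ---------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (N, H, W) in [0,1] -> foreground probability (N, H, W)."""
        h = x[:, None, :, :].astype(np.float64)
        skips = []
        for conv, relu, pool in zip(self.enc_convs, self.enc_relus, self.pools):
            h = relu.forward(conv.forward(h))
            skips.append(h)
            h = pool.forward(h)
        self._skip_channels = []
        for up, conv, relu, skip in zip(self.ups, self.dec_convs, self.dec_relus,
                                        reversed(skips)):
            h = up.forward(h)
            self._skip_channels.append(h.shape[1])
            h = relu.forward(conv.forward(np.concatenate([h, skip], axis=1)))
        logits = self._head.forward(h)
        self._p = 1.0 / (1.0 + np.exp(-np.clip(logits, -30.0, 30.0)))
        return self._p[:, 0]

    def backward(self, dprob: np.ndarray) -> None:
        grad = dprob[:, None] * self._p * (1.0 - self._p)
        grad = self._head.backward(grad)
        skip_grads = []
        for up, conv, relu, c_up in zip(reversed(self.ups), reversed(self.dec_convs),
                                        reversed(self.dec_relus),
                                        reversed(self._skip_channels)):
            g = conv.backward(relu.backward(grad))
            skip_grads.append(g[:, c_up:])
            grad = up.backward(g[:, :c_up])
        # skip_grads[i] is the gradient flowing into skips[i]; the encoder
        # pass below walks levels deepest-first
        for conv, relu, pool, sg in zip(reversed(self.enc_convs),
                                        reversed(self.enc_relus),
                                        reversed(self.pools),
                                        reversed(skip_grads)):
            grad = pool.backward(grad) + sg
            grad = conv.backward(relu.backward(grad))

    def trainable(self):
        for layer in self.enc_convs + self.dec_convs + [self._head]:
            yield layer

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path).with_suffix(".npz")
        arrays = {}
        for i, conv in enumerate(self.trainable()):
            arrays[f"W{i}"] = conv.W
            arrays[f"b{i}"] = conv.b
        np.savez(path, **arrays)
        sidecar = {
            "spec": self.spec.__dict__ | {"split": list(self.spec.split)},
            "seed": self.spec.seed,
            "validation_dice": self.validation_dice,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "SliceSegmenter":
        path = Path(path).with_suffix(".npz")
        sidecar = json.loads(path.with_suffix(".json").read_text())
        spec_d = dict(sidecar["spec"])
        spec_d["split"] = tuple(spec_d["split"])
        spec = SegModelSpec(**spec_d)
        model = cls(spec)
        data = np.load(path)
        for i, conv in enumerate(model.trainable()):
            conv.W = data[f"W{i}"]
            conv.b = data[f"b{i}"]
        model.validation_dice = sidecar["validation_dice"]
        return model


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _augment_pair(img, mask, prob, rng):
    """Apply each of the five ops independently with the given probability.

    Order is fixed (skew, rotation, flip, zoom, distortion).  The image is
    interpolated linearly, the mask with nearest neighbor to stay binary.
    """
    def _affine(im, matrix, offset, order):
        return ndimage.affine_transform(im, matrix, offset=offset, order=order,
                                        mode="constant", cval=0.0)

    h, w = img.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    if rng.random() < prob:   # skew (shear)
        s = rng.uniform(-0.2, 0.2)
        m = np.array([[1.0, s], [0.0, 1.0]])
        off = center - m @ center
        img, mask = _affine(img, m, off, 1), _affine(mask, m, off, 0)
    if rng.random() < prob:   # rotation
        a = np.deg2rad(rng.uniform(-30, 30))
        m = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        off = center - m @ center
        img, mask = _affine(img, m, off, 1), _affine(mask, m, off, 0)
    if rng.random() < prob:   # flip
        axis = int(rng.integers(2))
        img, mask = np.flip(img, axis=axis).copy(), np.flip(mask, axis=axis).copy()
    if rng.random() < prob:   # zoom
        z = rng.uniform(0.8, 1.2)
        m = np.eye(2) / z
        off = center - (m @ center)
        img, mask = _affine(img, m, off, 1), _affine(mask, m, off, 0)
    if rng.random() < prob:   # random (elastic) distortion
        disp = [ndimage.gaussian_filter(rng.normal(0, 1, size=img.shape), 4) * 6
                for _ in range(2)]
        zz, yy = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        coords = np.array([zz + disp[0], yy + disp[1]])
        img = ndimage.map_coordinates(img, coords, order=1, mode="constant")
        mask = ndimage.map_coordinates(mask, coords, order=0, mode="constant")
    return img, mask


# ---------------------------------------------------------------------------
# Training and inference
# ---------------------------------------------------------------------------

def split_tiles(n: int, split: tuple[float, float, float], seed: int):
    """Seeded deterministic train/validation/test membership by tile index."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(split[0] * n))
    n_val = int(round(split[1] * n))
    return perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:]


def _soft_dice_loss(p: np.ndarray, g: np.ndarray, eps=1.0):
    """Soft dice loss and its gradient wrt the probabilities (batch-global)."""
    inter = (p * g).sum()
    denom = p.sum() + g.sum()
    dice = (2 * inter + eps) / (denom + eps)
    # d(1-dice)/dp = -(2g(denom+eps) - (2 inter+eps)) / (denom+eps)^2
    dp = -(2 * g * (denom + eps) - (2 * inter + eps)) / (denom + eps) ** 2
    return 1.0 - dice, dp


def _dice_bce_loss(p: np.ndarray, g: np.ndarray, bce_weight=0.5):
    """Soft dice plus a pixel-wise cross-entropy term.

    The cross-entropy component keeps gradients informative when the model
    starts far from the target (where the dice term alone is nearly flat);
    the dice component drives the overlap the validation metric measures.
    """
    dice_loss, dp_dice = _soft_dice_loss(p, g)
    pc = np.clip(p, 1e-7, 1 - 1e-7)
    bce = -(g * np.log(pc) + (1 - g) * np.log(1 - pc)).mean()
    dp_bce = (pc - g) / (pc * (1 - pc)) / p.size
    return dice_loss + bce_weight * bce, dp_dice + bce_weight * dp_bce


class _Adam:
    def __init__(self, convs, lr):
        self.convs = list(convs)
        self.lr = lr
        self.t = 0
        self.state = [{n: (np.zeros_like(getattr(c, n)), np.zeros_like(getattr(c, n)))
                       for n in ("W", "b")} for c in self.convs]

    def step(self):
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for c, st in zip(self.convs, self.state):
            for name, gname in (("W", "dW"), ("b", "db")):
                g = getattr(c, gname)
                m, v = st[name]
                m[:] = b1 * m + (1 - b1) * g
                v[:] = b2 * v + (1 - b2) * g * g
                mh = m / (1 - b1 ** self.t)
                vh = v / (1 - b2 ** self.t)
                getattr(c, name)[...] -= self.lr * mh / (np.sqrt(vh) + eps)


def train_slice_segmenter(tiles, masks, spec: SegModelSpec):
    """Train the slice segmenter on annotated 2D tiles.

    ``tiles`` are single-channel intensity tiles (rescaled internally to
    [0, 1] per tile); ``masks`` are binary label tiles of the same shapes.
    Returns ``(model, validation_dice)``.
    """
    spec.validate()
    tiles = [np.asarray(t, dtype=np.float64) for t in tiles]
    masks = [np.asarray(m) for m in masks]
    if len(tiles) < 2:
        raise ValueError("need at least 2 annotated tiles")
    if len(tiles) != len(masks):
        raise ValueError("tiles and masks must have equal length")
    for i, (t, m) in enumerate(zip(tiles, masks)):
        if t.shape != m.shape:
            raise ValueError(f"tile {i}: shape mismatch {t.shape} vs {m.shape}")
        if not np.all(np.isin(np.unique(m), (0, 1))):
            raise ValueError(f"mask {i} is not binary (values {np.unique(m)[:5]})")
        if any(s % (2 ** spec.levels) for s in t.shape):
            raise ValueError(
                f"tile {i}: shape {t.shape} not divisible by 2^levels "
                f"({2 ** spec.levels})"
            )

    def _norm(t):
        lo, hi = t.min(), t.max()
        return (t - lo) / (hi - lo) if hi > lo else np.zeros_like(t)

    tiles = [_norm(t) for t in tiles]
    masks = [m.astype(np.float64) for m in masks]

    train_idx, val_idx, _ = split_tiles(len(tiles), spec.split, spec.seed)
    if len(val_idx) == 0:
        raise ValueError("no validation tile after the split; add tiles or change fractions")
    if len(train_idx) == 0:
        raise ValueError("no training tile after the split")

    rng = np.random.default_rng(spec.seed + 1)
    model = SliceSegmenter(spec, rng=np.random.default_rng(spec.seed + 2))
    opt = _Adam(model.trainable(), spec.learning_rate)

    for epoch in range(spec.epochs):
        order = rng.permutation(train_idx)
        for start in range(0, len(order), spec.batch_size):
            batch = order[start:start + spec.batch_size]
            xs, gs = [], []
            for i in batch:
                x, g = tiles[i], masks[i]
                if spec.augment_prob > 0:
                    x, g = _augment_pair(x, g, spec.augment_prob, rng)
                xs.append(x)
                gs.append(g)
            x = np.stack(xs)
            g = np.stack(gs)
            p = model.forward(x)
            _, dp = _dice_bce_loss(p, g)
            model.backward(dp)
            opt.step()

    # hard-mask dice on the held-out validation tiles
    dices = []
    for i in val_idx:
        p = model.forward(tiles[i][None])[0]
        dices.append(dice_coefficient(p > 0.5, masks[i] > 0.5))
    val_dice = float(np.mean(dices))
    model.validation_dice = val_dice
    return model, val_dice


def predict_slice_segmenter(model: SliceSegmenter, channel: ChannelVolume) -> np.ndarray:
    """Apply the trained segmenter slice-by-slice to a 3D channel.

    Each z-slice is rescaled to [0, 1], downsampled by the spec factor
    (local mean), padded to a size the encoder can pool, classified, cropped,
    and upsampled back to the native slice size with nearest neighbor so the
    output stays binary.  Slices are processed independently.
    """
    f = model.spec.downsample_factor
    depth = 2 ** model.spec.levels
    h, w = channel.shape[1], channel.shape[2]
    if f > 1 and (h % f or w % f):
        raise ValueError(
            f"slice shape {(h, w)} is not divisible by the downsampling "
            f"factor {f}"
        )
    if h // f < depth or w // f < depth:
        raise ValueError(f"slice too small for {model.spec.levels} pooling levels")
    out = np.zeros(channel.shape, dtype=np.uint8)
    for z in range(channel.shape[0]):
        s = channel.data[z].astype(np.float64)
        lo, hi = s.min(), s.max()
        if hi == lo:
            continue    # constant slice carries no signal: empty prediction
        s = (s - lo) / (hi - lo)
        if f > 1:
            s = s.reshape(h // f, f, w // f, f).mean(axis=(1, 3))
        hd, wd = s.shape
        ph = (-hd) % depth
        pw = (-wd) % depth
        sp = np.pad(s, ((0, ph), (0, pw)), mode="reflect") if (ph or pw) else s
        p = model.forward(sp[None])[0][:hd, :wd]
        m = (p > 0.5).astype(np.uint8)
        if f > 1:
            m = m.repeat(f, axis=0).repeat(f, axis=1)
        out[z] = m[:h, :w]
    return out
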