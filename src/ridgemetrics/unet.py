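"""U-net semantic segmentation of microridges, in pure NumPy.

A convolutional encoder–decoder with ReLU activations, 2x max-pool
downsampling, nearest-neighbor upsampling and skip connections, trained with
weighted pixel-wise cross-entropy (softmax) by stochastic gradient descent
with momentum.  Convolutions run as im2col matrix products and gradients are
derived analytically, so the whole trainer is deterministic under a fixed
seed and has no framework dependency.  The intended regime is the reduced
synthetic one (depth 2, 64x64 inputs, a few hundred pairs); the full-scale
recipe (depth 6, 256x256, mini-batch 6, 800 epochs) is expressible through
:class:`NetConfig` but takes GPU-scale resources.

Training pairs come from the conventional ridge-labeling algorithm; images
are median-normalized and class imbalance is countered both by the
normalization and by median-frequency class weights in the loss.

After prediction the physical pixel pitch of the resized mask is restored
from the original extracted-cell dimensions:
Dx = x_o * psz / N, Dy = y_o * psz / N for an N x N network input.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .grid import PixelGrid, as_grid

__all__ = ["NetConfig", "SegMetrics", "RescaledMask", "normalize_and_weight",
           "augment", "build_unet", "train_unet", "mean_iou",
           "predict_and_rescale", "rescaled_pixel_size", "UNet"]


# ---------------------------------------------------------------------------
# configuration and metric containers
# ---------------------------------------------------------------------------

@dataclass
class NetConfig:
    """Hyperparameters of the encoder–decoder and its training run."""

    input_size: int = 256
    depth: int = 6
    learning_rate: float = 1e-4
    mini_batch_size: int = 6
    max_epochs: int = 800
    train_fraction: float = 0.93
    seed: int = 0
    base_channels: int = 8
    momentum: float = 0.9

    def __post_init__(self):
        if self.mini_batch_size < 1 or self.max_epochs < 1:
            raise ValueError("mini_batch_size and max_epochs must be >= 1")
        if self.input_size % (2 ** self.depth) != 0:
            raise ValueError(
                f"input_size {self.input_size} must be divisible by 2^depth={2**self.depth}")


@dataclass
class SegMetrics:
    """IoU and accuracy summary; mean_iou averages the class IoUs present."""

    mean_iou: float
    per_class_iou: dict
    pixel_accuracy: float
    per_image_accuracy: list = field(default_factory=list)


@dataclass
class RescaledMask:
    """Network mask NB, masked grayscale NM = IM .* NB and restored pitch."""

    NB: np.ndarray
    NM: np.ndarray
    dx_new: float
    dy_new: float
    x_o: int
    y_o: int
    psz: float


# ---------------------------------------------------------------------------
# dataset preparation
# ---------------------------------------------------------------------------

def normalize_and_weight(pairs: list):
    """Median-normalize images and compute median-frequency class weights.

    Each image is divided by the median of its nonzero pixels (zero-median
    images are skipped with a warning).  Class weights are
    w_c = median class frequency / class frequency, so the rarer foreground
    class is up-weighted; balanced classes get weight 1 each.

    Returns ``(normalized_pairs, class_weights)`` with weights indexed
    [background, foreground].
    """
    out = []
    freq = np.zeros(2)
    for img, lab in pairs:
        img = np.asarray(img, dtype=float)
        lab = np.asarray(lab)
        nz = img[img > 0]
        med = np.median(nz) if nz.size else 0.0
        if med == 0:
            warnings.warn("skipping image with zero median intensity")
            continue
        out.append((img / med, lab.astype(np.int64)))
        freq += np.bincount((lab > 0).astype(int).ravel(), minlength=2)
    if not out:
        raise ValueError("no usable training pairs")
    freq = freq / freq.sum()
    with np.errstate(divide="ignore"):
        weights = np.where(freq > 0, np.median(freq) / freq, 0.0)
    return out, weights


def augment(pairs: list, seed: int, multiplier: int = 2,
            max_shift: int = 5) -> list:
    """Augment (image, label) pairs by rotations, translations, reflections.

    The identical transform is applied to image and label (labels stay
    binary: all transforms are pixel permutations).  Returns the original
    pairs followed by ``(multiplier - 1)`` transformed copies of each.
    """
    rng = np.random.default_rng(seed)
    out = list(pairs)
    for _ in range(max(0, multiplier - 1)):
        for img, lab in pairs:
            k = int(rng.integers(0, 4))
            flip = bool(rng.integers(0, 2))
            sh = rng.integers(-max_shift, max_shift + 1, size=2)
            ti, tl = np.rot90(img, k), np.rot90(lab, k)
            if flip:
                ti, tl = np.fliplr(ti), np.fliplr(tl)
            ti = np.roll(ti, sh, axis=(0, 1))
            tl = np.roll(tl, sh, axis=(0, 1))
            out.append((ti.copy(), tl.copy()))
    return out


# ---------------------------------------------------------------------------
# layers (float32, NHWC)
# ---------------------------------------------------------------------------

def _conv_forward(x, W, b):
    """Same-padding stride-1 convolution; returns (out, cols) for backprop."""
    kh, kw, cin, cout = W.shape
    ph, pw = kh // 2, kw // 2
    if ph or pw:
        xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    else:
        xp = x
    win = sliding_window_view(xp, (kh, kw), axis=(1, 2))      # B,H,W,C,kh,kw
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3))
    B, H, Wd = x.shape[:3]
    cols = cols.reshape(B * H * Wd, kh * kw * cin)
    out = cols @ W.reshape(-1, cout) + b
    return out.reshape(B, H, Wd, cout), cols


def _conv_backward(dout, cols, x_shape, W):
    kh, kw, cin, cout = W.shape
    B, H, Wd = dout.shape[:3]
    dmat = dout.reshape(-1, cout)
    dW = (cols.T @ dmat).reshape(W.shape)
    db = dmat.sum(axis=0)
    # dx = same-conv of dout with spatially flipped, channel-transposed kernel
    W_rot = W[::-1, ::-1].transpose(0, 1, 3, 2).copy()
    dx, _ = _conv_forward(dout, W_rot, np.zeros(cin, dtype=W.dtype))
    return dx, dW, db


def _maxpool(x):
    B, H, W, C = x.shape
    r = x.reshape(B, H // 2, 2, W // 2, 2, C)
    out = r.max(axis=(2, 4))
    mask = (r == out[:, :, None, :, None, :])
    return out, mask


def _maxpool_backward(dout, mask):
    B, Hh, Wh, C = dout.shape
    spread = mask * dout[:, :, None, :, None, :]
    return spread.reshape(B, Hh * 2, Wh * 2, C)


def _upsample(x):
    return x.repeat(2, axis=1).repeat(2, axis=2)


def _upsample_backward(dout):
    B, H, W, C = dout.shape
    return dout.reshape(B, H // 2, 2, W // 2, 2, C).sum(axis=(2, 4))


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class UNet:
    """Encoder–decoder with skip connections; two output classes."""

    def __init__(self, cfg: NetConfig, in_channels: int = 1):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.params = {}
        b, d = cfg.base_channels, cfg.depth
        widths = [b * 2 ** i for i in range(d + 1)]
        c_prev = in_channels
        for i in range(d):                      # encoder double-convs
            self._add_conv(rng, f"enc{i}a", 3, c_prev, widths[i])
            self._add_conv(rng, f"enc{i}b", 3, widths[i], widths[i])
            c_prev = widths[i]
        self._add_conv(rng, "bota", 3, c_prev, widths[d])
        self._add_conv(rng, "botb", 3, widths[d], widths[d])
        c_prev = widths[d]
        for i in reversed(range(d)):            # decoder double-convs
            self._add_conv(rng, f"dec{i}a", 3, c_prev + widths[i], widths[i])
            self._add_conv(rng, f"dec{i}b", 3, widths[i], widths[i])
            c_prev = widths[i]
        self._add_conv(rng, "out", 1, c_prev, 2)
        self.velocity = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _add_conv(self, rng, name, k, cin, cout):
        std = np.sqrt(2.0 / (k * k * cin))
        self.params[f"{name}_W"] = rng.normal(0, std, (k, k, cin, cout)).astype(np.float32)
        self.params[f"{name}_b"] = np.zeros(cout, dtype=np.float32)

    # -- forward / backward ------------------------------------------------

    def _block(self, x, name, cache):
        for suffix in ("a", "b"):
            W, bb = self.params[f"{name}{suffix}_W"], self.params[f"{name}{suffix}_b"]
            out, cols = _conv_forward(x, W, bb)
            relu_mask = out > 0
            x_next = out * relu_mask
            cache.append((f"{name}{suffix}", cols, x.shape, relu_mask))
            x = x_next
        return x

    def _block_backward(self, dx, cache, grads):
        for _ in range(2):
            name, cols, x_shape, relu_mask = cache.pop()
            dx = dx * relu_mask
            dx, dW, db = _conv_backward(dx, cols, x_shape, self.params[f"{name}_W"])
            grads[f"{name}_W"] = grads.get(f"{name}_W", 0) + dW
            grads[f"{name}_b"] = grads.get(f"{name}_b", 0) + db
        return dx

    def forward(self, x):
        """Logits of shape (B, H, W, 2) for input (B, H, W) or (B, H, W, 1)."""
        return _forward_full(self, x)[0]


def _forward_full(net: UNet, x):
    """Forward pass keeping every intermediate needed for the backward pass."""
    if x.ndim == 3:
        x = x[..., None]
    x = x.astype(np.float32)
    d = net.cfg.depth
    enc_caches, skips, pools = [], [], []
    for i in range(d):
        cache = []
        x = net._block(x, f"enc{i}", cache)
        enc_caches.append(cache)
        skips.append(x)
        x, mask = _maxpool(x)
        pools.append(mask)
    bot_cache = []
    x = net._block(x, "bot", bot_cache)
    dec_caches, concat_splits = [], []
    for i in reversed(range(d)):
        x = _upsample(x)
        skip = skips[i]
        concat_splits.append(skip.shape[-1])
        x = np.concatenate([skip, x], axis=-1)
        cache = []
        x = net._block(x, f"dec{i}", cache)
        dec_caches.append(cache)
    logits, out_cols = _conv_forward(x, net.params["out_W"], net.params["out_b"])
    ctx = (enc_caches, pools, bot_cache, dec_caches, concat_splits,
           out_cols, x.shape)
    return logits, ctx


def _backward_full(net: UNet, dlogits, ctx):
    enc_caches, pools, bot_cache, dec_caches, concat_splits, out_cols, pre_out = ctx
    grads = {}
    dx, dW, db = _conv_backward(dlogits, out_cols, pre_out, net.params["out_W"])
    grads["out_W"], grads["out_b"] = dW, db
    d = net.cfg.depth
    skip_grads = [None] * d
    # dec_caches are stored in forward order (levels d-1 .. 0); unwind from
    # the outermost (level 0, nearest the output) back to the innermost
    for idx in range(d - 1, -1, -1):
        level = d - 1 - idx
        dx = net._block_backward(dx, dec_caches[idx], grads)
        sc = concat_splits[idx]
        skip_grads[level] = dx[..., :sc]
        dx = _upsample_backward(dx[..., sc:])
    dx = net._block_backward(dx, bot_cache, grads)
    for i in reversed(range(d)):                      # encoder, deepest first
        dx = _maxpool_backward(dx, pools[i])
        dx = dx + skip_grads[i]
        dx = net._block_backward(dx, enc_caches[i], grads)
    return grads


def _weighted_ce(logits, labels, weights):
    """Weighted pixel-wise softmax cross-entropy; returns (loss, dlogits)."""
    m = logits.max(axis=-1, keepdims=True)
    e = np.exp(logits - m)
    p = e / e.sum(axis=-1, keepdims=True)
    onehot = np.eye(2, dtype=np.float32)[labels]
    w = weights[labels].astype(np.float32)
    eps = 1e-12
    loss = float(-(w * np.log(p[..., 1] * onehot[..., 1]
                              + p[..., 0] * onehot[..., 0] + eps)).sum() / w.sum())
    dlogits = w[..., None] * (p - onehot) / w.sum()
    return loss, dlogits.astype(np.float32)


def build_unet(cfg: NetConfig, in_channels: int = 1) -> UNet:
    """Construct an untrained network for the given configuration."""
    return UNet(cfg, in_channels)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclass
class TrainedUNet:
    """A trained network with its loss history and held-out metrics."""

    net: UNet
    cfg: NetConfig
    loss_history: list
    test_metrics: SegMetrics | None
    class_weights: np.ndarray

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Argmax class mask for (B, H, W) or a single (H, W) image."""
        single = images.ndim == 2
        x = images[None] if single else images
        logits = _forward_full(self.net, np.asarray(x, dtype=np.float32))[0]
        pred = logits.argmax(axis=-1).astype(np.uint8)
        return pred[0] if single else pred


def _resize_pair(img, lab, size):
    if img.shape != (size, size):
        img = resize(img, (size, size), order=1, preserve_range=True,
                     anti_aliasing=True)
        lab = resize(lab.astype(float), (size, size), order=0,
                     preserve_range=True, anti_aliasing=False)
    return np.asarray(img, dtype=np.float32), (np.asarray(lab) > 0.5).astype(np.int64)


def train_unet(pairs: list, cfg: NetConfig, *, augment_multiplier: int = 1) -> TrainedUNet:
    """Train the U-net on (image, label) pairs.

    Pairs are median-normalized, resized to ``cfg.input_size``, split into
    train/test by ``cfg.train_fraction`` (seeded shuffle), optionally
    augmented, and optimized with SGD + momentum on weighted pixel-wise
    cross-entropy.  Deterministic under a fixed ``cfg.seed``.
    """
    normed, weights = normalize_and_weight(pairs)
    data = [_resize_pair(img, lab, cfg.input_size) for img, lab in normed]
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(data))
    n_train = max(1, int(round(cfg.train_fraction * len(data))))
    train = [data[i] for i in order[:n_train]]
    test = [data[i] for i in order[n_train:]]
    if augment_multiplier > 1:
        train = augment(train, seed=cfg.seed + 1, multiplier=augment_multiplier)

    net = UNet(cfg)
    X = np.stack([p[0] for p in train]).astype(np.float32)
    Y = np.stack([p[1] for p in train])
    history = []
    for epoch in range(cfg.max_epochs):
        idx = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), cfg.mini_batch_size):
            sel = idx[start:start + cfg.mini_batch_size]
            logits, ctx = _forward_full(net, X[sel])
            loss, dlogits = _weighted_ce(logits, Y[sel], weights)
            grads = _backward_full(net, dlogits, ctx)
            for k, g in grads.items():
                v = net.velocity[k]
                v *= cfg.momentum
                v -= cfg.learning_rate * g.astype(np.float32)
                net.params[k] += v
            losses.append(loss)
        history.append(float(np.mean(losses)))

    model = TrainedUNet(net, cfg, history, None, weights)
    if test:
        preds = model.predict(np.stack([p[0] for p in test]))
        metrics = [mean_iou(pr, la) for pr, la in zip(preds, [p[1] for p in test])]
        per_img_acc = [m.pixel_accuracy for m in metrics]
        ious = [m.mean_iou for m in metrics if np.isfinite(m.mean_iou)]
        per_class = {}
        for c in (0, 1):
            vals = [m.per_class_iou[c] for m in metrics if c in m.per_class_iou]
            if vals:
                per_class[c] = float(np.mean(vals))
        model.test_metrics = SegMetrics(
            mean_iou=float(np.mean(ious)) if ious else float("nan"),
            per_class_iou=per_class,
            pixel_accuracy=float(np.mean(per_img_acc)),
            per_image_accuracy=per_img_acc)
    return model


# ---------------------------------------------------------------------------
# metrics and rescaling
# ---------------------------------------------------------------------------

def mean_iou(pred: np.ndarray, label: np.ndarray) -> SegMetrics:
    """Per-class intersection-over-union and their mean (Jaccard similarity).

    Classes absent from both prediction and label (undefined IoU: empty
    union) are excluded from the mean.  Also reports pixel accuracy.
    """
    pred = np.asarray(pred).astype(bool)
    label = np.asarray(label).astype(bool)
    if pred.shape != label.shape:
        raise ValueError("prediction and label must share shape")
    per_class = {}
    for c, (p, l) in enumerate([(~pred, ~label), (pred, label)]):
        union = (p | l).sum()
        if union == 0:
            continue
        per_class[c] = float((p & l).sum() / union)
    miou = float(np.mean(list(per_class.values()))) if per_class else float("nan")
    acc = float((pred == label).mean())
    return SegMetrics(mean_iou=miou, per_class_iou=per_class, pixel_accuracy=acc)


def rescaled_pixel_size(x_o: int, psz: float = 0.1977, out_size: int = 256) -> float:
    """Physical pixel pitch (µm) after resizing an x_o-px cell to out_size px:
    Dx = x_o * psz / out_size."""
    if x_o <= 0 or psz <= 0:
        raise ValueError("x_o and psz must be positive")
    return x_o * psz / out_size


def predict_and_rescale(model: TrainedUNet, cell_image, x_o: int, y_o: int,
                        psz: float = 0.1977) -> RescaledMask:
    """Predict a mask for one cell and restore its physical pixel sizes.

    The cell image is resized to the network input size, the argmax mask NB
    predicted, the masked grayscale NM = IM .* NB formed on the resized
    image, and Dx, Dy recomputed from the original dimensions.
    """
    img = as_grid(cell_image).values
    size = model.cfg.input_size
    im_rs = resize(img, (size, size), order=1, preserve_range=True,
                   anti_aliasing=True).astype(np.float32)
    nz = im_rs[im_rs > 0]
    scale = np.median(nz) if nz.size else 1.0
    NB = model.predict(im_rs / (scale if scale else 1.0))
    NM = im_rs * NB
    return RescaledMask(NB=NB, NM=NM,
                        dx_new=rescaled_pixel_size(x_o, psz, size),
                        dy_new=rescaled_pixel_size(y_o, psz, size),
                        x_o=x_o, y_o=y_o, psz=psz)
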