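"""Skip-architecture FCN and U-Net baseline, trained with negative soft Dice.

The FCN is a 19-convolution network for 128x128 short-axis slices: five
encoder stages of paired 3x3 convolutions separated by four max-pools of
size 3, a decoder of four kernel-4 transposed convolutions, and four 1x1
"skip" fusions that sum matched-resolution encoder features into the decoder
(coarse semantics + fine edges), ending in a 1x1 convolution and sigmoid
dense heatmap.  128 is not divisible by 3^4, so pooling pads with -inf up to
the next multiple and each upsampled map is center-cropped back to its
encoder partner's extent.

Training follows the published recipe: Glorot-uniform init, SGD with
Nesterov momentum (lr 0.002, momentum 0.9), batch size 5, 450 epochs,
minimizing the negative Dice coefficient; l2 regularization and dropout at
the bottleneck temper overfitting.  The model with the best validation loss
is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .nn.layers import DTYPE, center_crop_map, uncrop_grad
from .preprocess import ImageMaskPair

soft_dice_loss = nn.soft_dice_loss


@dataclass
class FcnSpec:
    filters: tuple = (16, 32, 64, 128, 256)  # per encoder stage (doubling)
    n_pools: int = 4
    pool_size: int = 3
    up_kernel: int = 4
    input_size: int = 128
    dropout_rate: float = 0.5
    l2_coeff: float = 1e-4
    seed: int = 0

    def validate(self) -> None:
        if self.n_pools != 4:
            raise ValueError(f"FCN requires exactly 4 pooling stages, got {self.n_pools}")
        if self.pool_size != 3:
            raise ValueError(f"FCN requires pool size 3, got {self.pool_size}")
        if self.up_kernel != 4:
            raise ValueError(f"FCN requires transposed-conv kernel 4, got {self.up_kernel}")
        if len(self.filters) != self.n_pools + 1:
            raise ValueError("filters must list one width per encoder stage "
                             f"({self.n_pools + 1}), got {len(self.filters)}")


@dataclass
class TrainConfig:
    learning_rate: float = 0.002
    momentum: float = 0.9
    nesterov: bool = True
    batch_size: int = 5
    epochs: int = 450
    init: str = "glorot_uniform"
    loss: str = "neg_dice"
    dice_smooth: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.loss != "neg_dice":
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.init != "glorot_uniform":
            raise ValueError(f"unknown init {self.init!r}")
        if min(self.learning_rate, self.momentum, self.batch_size, self.epochs) <= 0:
            raise ValueError("training hyperparameters must be positive")


class _ConvBlock(nn.Module):
    """Two 3x3 same-padded convolutions, each followed by ReLU."""

    def __init__(self, cin: int, cout: int, rng) -> None:
        super().__init__()
        self.seq = nn.Sequential(
            nn.Conv2d(cin, cout, 3, padding=1, rng=rng), nn.ReLU(),
            nn.Conv2d(cout, cout, 3, padding=1, rng=rng), nn.ReLU())

    forward = lambda self, x: self.seq.forward(x)
    backward = lambda self, g: self.seq.backward(g)


class Fcn(nn.Module):
    """19-convolution skip-architecture FCN (see module docstring)."""

    def __init__(self, spec: FcnSpec) -> None:
        super().__init__()
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        f = spec.filters
        self.enc = [_ConvBlock(1 if i == 0 else f[i - 1], f[i], rng)
                    for i in range(5)]
        self.pools = [nn.MaxPool2d(spec.pool_size) for _ in range(4)]
        self.dropout = nn.Dropout(spec.dropout_rate,
                                  rng=np.random.default_rng(spec.seed + 1))
        # decoder: upsample stage j+1 -> j, fuse with 1x1-projected encoder map
        self.ups = [nn.ConvTranspose2d(f[j + 1], f[j], spec.up_kernel,
                                       stride=spec.pool_size, rng=rng)
                    for j in range(4)]
        self.skips = [nn.Conv2d(f[j], f[j], 1, rng=rng) for j in range(4)]
        self.fuse_relu = [nn.ReLU() for _ in range(4)]
        self.final = nn.Conv2d(f[0], 1, 1, rng=rng)
        # chamber masks are sparse; bias the initial heatmap toward
        # background so the Dice loss escapes the half-gray plateau quickly
        self.final.bias.value[...] = -3.0
        self.out_act = nn.Sigmoid()
        self._check_spatial()

    def _check_spatial(self) -> None:
        n = self.spec.input_size
        sizes = [n]
        for p in self.pools:
            n = p.out_size(n)
            sizes.append(n)
        for j in range(3, -1, -1):
            up = self.ups[j].out_size(sizes[j + 1])
            if up < sizes[j]:
                raise ValueError(
                    f"spatial arithmetic mismatch at decoder stage {j}: "
                    f"upsampled {up} < encoder {sizes[j]} (sizes {sizes})")
        self._sizes = sizes

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats, self._crops = [], []
        h = x.astype(DTYPE, copy=False)
        for i in range(4):
            h = self.enc[i].forward(h)
            feats.append(h)
            h = self.pools[i].forward(h)
        h = self.enc[4].forward(h)
        h = self.dropout.forward(h)
        self._skip_out = []
        for j in range(3, -1, -1):
            up = self.ups[j].forward(h)
            tgt = feats[j].shape[2:]
            up, off = center_crop_map(up, tgt[0], tgt[1])
            self._crops.append(off)
            sk = self.skips[j].forward(feats[j])
            h = self.fuse_relu[j].forward(up + sk)
        out = self.final.forward(h)
        return self.out_act.forward(out)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.out_act.backward(grad)
        g = self.final.backward(g)
        enc_grads = [None] * 4
        crops = list(self._crops)  # recorded j = 3..0
        for j in range(4):
            g = self.fuse_relu[j].backward(g)
            enc_grads[j] = self.skips[j].backward(g)
            up_g = uncrop_grad(g, crops.pop())  # matching crop for stage j
            g = self.ups[j].backward(up_g)
        g = self.dropout.backward(g)
        g = self.enc[4].backward(g)
        for i in range(3, -1, -1):
            g = self.pools[i].backward(g)
            g = g + enc_grads[i]
            g = self.enc[i].backward(g)
        return g


class Unet(nn.Module):
    """Standard contracting/expanding U-Net baseline with concatenation
    skips; 128x128 in/out, pool size 2, base width configurable."""

    def __init__(self, base_filters: int = 16, input_size: int = 128,
                 seed: int = 0) -> None:
        super().__init__()
        if input_size % 16 != 0:
            raise ValueError("U-Net input size must be divisible by 16")
        rng = np.random.default_rng(seed)
        f = [base_filters * (2 ** i) for i in range(5)]
        self.base_filters, self.input_size = base_filters, input_size
        self.enc = [_ConvBlock(1 if i == 0 else f[i - 1], f[i], rng)
                    for i in range(4)]
        self.pools = [nn.MaxPool2d(2) for _ in range(4)]
        self.bott = _ConvBlock(f[3], f[4], rng)
        self.ups = [nn.ConvTranspose2d(f[j + 1], f[j], 2, stride=2, rng=rng)
                    for j in range(4)]
        self.dec = [_ConvBlock(2 * f[j], f[j], rng) for j in range(4)]
        self.final = nn.Conv2d(f[0], 1, 1, rng=rng)
        self.final.bias.value[...] = -3.0  # sparse-target prior, as in Fcn
        self.out_act = nn.Sigmoid()

    def forward(self, x: np.ndarray) -> np.ndarray:
        feats = []
        h = x.astype(DTYPE, copy=False)
        for i in range(4):
            h = self.enc[i].forward(h)
            feats.append(h)
            h = self.pools[i].forward(h)
        h = self.bott.forward(h)
        for j in range(3, -1, -1):
            up = self.ups[j].forward(h)
            h = np.concatenate([feats[j], up], axis=1)
            h = self.dec[j].forward(h)
        return self.out_act.forward(self.final.forward(h))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.out_act.backward(grad)
        g = self.final.backward(g)
        enc_grads = [None] * 4
        for j in range(4):
            g = self.dec[j].backward(g)
            c = self.enc[j].seq.layers[2].out_ch  # channels of feats[j]
            enc_grads[j] = g[:, :c]
            g = self.ups[j].backward(np.ascontiguousarray(g[:, c:]))
        g = self.bott.backward(g)
        for i in range(3, -1, -1):
            g = self.pools[i].backward(g)
            g = g + enc_grads[i]
            g = self.enc[i].backward(g)
        return g


def build_fcn(spec: FcnSpec | None = None) -> Fcn:
    return Fcn(spec or FcnSpec())


def build_unet(base_filters: int = 16, input_size: int = 128, seed: int = 0) -> Unet:
    return Unet(base_filters=base_filters, input_size=input_size, seed=seed)


def _stack(pairs: list[ImageMaskPair]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.image for p in pairs])[:, None].astype(DTYPE)
    y = np.stack([p.mask for p in pairs])[:, None].astype(DTYPE)
    return x, y


def _epoch_loss(model: nn.Module, x: np.ndarray, y: np.ndarray,
                batch: int, smooth: float) -> float:
    losses = []
    for s in range(0, x.shape[0], batch):
        out = model.forward(x[s:s + batch])
        losses.append(nn.soft_dice_loss(out, y[s:s + batch], smooth))
    return float(np.mean(losses))


def train_segmenter(model: nn.Module, train_pairs: list[ImageMaskPair],
                    val_pairs: list[ImageMaskPair] | None,
                    config: TrainConfig | None = None,
                    l2_coeff: float | None = None):
    """SGD-Nesterov training on negative soft Dice; returns (model, history).

    History has one entry per epoch with train/val loss; the parameter state
    with the best validation loss (train loss if no validation set) is
    restored into the model before returning.
    """
    config = config or TrainConfig()
    config.validate()
    if not train_pairs:
        raise ValueError("empty training set")
    if l2_coeff is None:
        l2_coeff = getattr(getattr(model, "spec", None), "l2_coeff", 0.0)
    x, y = _stack(train_pairs)
    xv, yv = _stack(val_pairs) if val_pairs else (None, None)
    rng = np.random.default_rng(config.seed)
    opt = nn.SGD(model.parameters(), lr=config.learning_rate,
                 momentum=config.momentum, nesterov=config.nesterov,
                 weight_decay=l2_coeff)
    history: list[dict] = []
    best = (np.inf, None)
    n = x.shape[0]
    for epoch in range(config.epochs):
        model.train()
        order = rng.permutation(n)
        ep_losses = []
        for s in range(0, n, config.batch_size):
            idx = order[s:s + config.batch_size]
            out = model.forward(x[idx])
            loss, dloss = nn.soft_dice_loss_grad(out, y[idx], config.dice_smooth)
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dloss)
            opt.step()
            ep_losses.append(loss)
        model.eval()
        train_loss = _epoch_loss(model, x, y, config.batch_size, config.dice_smooth)
        entry = {"epoch": epoch, "train_loss": train_loss,
                 "steps": len(ep_losses)}
        sel_loss = train_loss
        if xv is not None:
            val_loss = _epoch_loss(model, xv, yv, config.batch_size,
                                   config.dice_smooth)
            entry["val_loss"] = val_loss
            sel_loss = val_loss
        history.append(entry)
        if sel_loss < best[0]:
            best = (sel_loss, [p.value.copy() for p in model.parameters()])
    if best[1] is not None:
        for p, v in zip(model.parameters(), best[1]):
            p.value[...] = v
    model.eval()
    return model, history


def predict_mask(model: nn.Module, image: np.ndarray, threshold: float = 0.5,
                 largest_component: bool = False) -> np.ndarray:
    """Binary prediction: forward pass in eval mode, heatmap thresholded at
    0.5; optional largest-connected-component cleanup (default off)."""
    img = np.asarray(image, dtype=DTYPE)
    if abs(float(img.mean())) > 0.1:
        warnings.warn("input does not look z-normalized (|mean| > 0.1)")
    model.eval()
    heat = model.forward(img[None, None])[0, 0]
    mask = (heat >= threshold).astype(np.uint8)
    if largest_component and mask.any():
        lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
        if n > 1:
            areas = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
            mask = (lab == (1 + int(np.argmax(areas)))).astype(np.uint8)
    return mask
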