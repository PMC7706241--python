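"""Two-channel DCGAN that jointly synthesizes a CMR slice and its chamber mask.

The generator maps 100-dimensional standard-normal noise through six
kernel-4 transposed convolutions (stride 1 first, stride 2 thereafter:
spatial ladder 1 -> 4 -> 8 -> 16 -> 32 -> 64 -> 128) to a 2x128x128 Tanh
output — channel 0 the image, channel 1 a soft segmentation mask.  The
discriminator mirrors it: six kernel-4 convolutions (stride 2 except the
last), LeakyReLU slope 0.2, sigmoid scalar "real pair" probability.

Training alternates exactly two steps per iteration: (a) the discriminator
is updated on a real batch labelled 1 and then a generated batch labelled 0;
(b) the generator is updated through the frozen discriminator on a generated
batch labelled 1.  Both phases use binary cross-entropy; Adam optimizes both
networks and weights start from a zero-mean Gaussian (std 0.02).

Real pairs enter the GAN in Tanh range: masks mapped {0,1} -> {-1,1};
z-normalized images squashed clip(z,-3,3)/3 (unsquashed on sampling).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn.layers import DTYPE
from .preprocess import ImageMaskPair

IMG_SQUASH = 3.0  # z-score range mapped onto the Tanh interval


@dataclass
class GanSpec:
    noise_dim: int = 100
    out_size: int = 128
    gen_channels: tuple = (256, 128, 64, 32, 16)   # hidden widths, widest first
    disc_channels: tuple = (16, 32, 64, 128, 256)  # hidden widths, narrowest first
    out_channels: int = 2
    leaky_slope: float = 0.2
    batchnorm: bool = True

    def n_stride2(self) -> int:
        n = int(round(math.log2(self.out_size / 4)))
        if 4 * 2 ** n != self.out_size or self.out_size < 8:
            raise ValueError(f"out_size must be 4*2^k >= 8, got {self.out_size}")
        return n

    def validate(self) -> None:
        n = self.n_stride2()
        if len(self.gen_channels) < n or len(self.disc_channels) < n:
            raise ValueError(
                f"need >= {n} hidden channel widths for out_size {self.out_size}")


@dataclass
class GanTrainConfig:
    """Alternating-schedule training settings.

    ``init_std`` is the DCGAN-conventional 0.02 standard deviation for the
    zero-mean Gaussian weight init; a much larger scale saturates the
    discriminator's sigmoid from the first step and stalls the generator.
    """

    batch_size: int = 5
    iterations: int = 40_000
    init_std: float = 0.02
    adam_lr: float = 2e-4
    adam_betas: tuple = (0.5, 0.999)
    real_label: float = 1.0
    fake_label: float = 0.0
    checkpoint_every: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.batch_size < 1 or self.iterations < 1:
            raise ValueError("batch_size and iterations must be >= 1")
        if (self.real_label, self.fake_label) != (1.0, 0.0):
            raise ValueError("real/fake labels are fixed to 1/0")


def _init_std(cfg: GanTrainConfig | None) -> float:
    return (cfg or GanTrainConfig()).init_std


def build_generator(spec: GanSpec | None = None, seed: int = 0,
                    train_cfg: GanTrainConfig | None = None) -> nn.Sequential:
    """Noise (N, noise_dim, 1, 1) -> (N, 2, out, out) in [-1, 1]."""
    spec = spec or GanSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    std = _init_std(train_cfg)
    n2 = spec.n_stride2()
    chans = list(spec.gen_channels[:n2]) + [spec.out_channels]
    layers: list[nn.Module] = []
    cin = spec.noise_dim
    # stride-1 stage: 1 -> 4
    layers.append(nn.ConvTranspose2d(cin, chans[0], 4, stride=1, padding=0,
                                     rng=rng, init="gaussian", init_std=std))
    if spec.batchnorm:
        layers.append(nn.BatchNorm2d(chans[0]))
    layers.append(nn.ReLU())
    cin = chans[0]
    for i, cout in enumerate(chans[1:]):
        last = i == len(chans) - 2
        layers.append(nn.ConvTranspose2d(cin, cout, 4, stride=2, padding=1,
                                         rng=rng, init="gaussian", init_std=std))
        if last:
            layers.append(nn.Tanh())
        else:
            if spec.batchnorm:
                layers.append(nn.BatchNorm2d(cout))
            layers.append(nn.ReLU())
        cin = cout
    return nn.Sequential(*layers)


def build_discriminator(spec: GanSpec | None = None, seed: int = 1,
                        train_cfg: GanTrainConfig | None = None) -> nn.Sequential:
    """(N, 2, out, out) -> (N, 1, 1, 1) probability in (0, 1)."""
    spec = spec or GanSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    std = _init_std(train_cfg)
    n2 = spec.n_stride2()
    chans = list(spec.disc_channels[:n2])
    layers: list[nn.Module] = []
    cin = spec.out_channels
    for i, cout in enumerate(chans):
        layers.append(nn.Conv2d(cin, cout, 4, stride=2, padding=1,
                                rng=rng, init="gaussian", init_std=std))
        if spec.batchnorm and i > 0:
            layers.append(nn.BatchNorm2d(cout))
        layers.append(nn.LeakyReLU(spec.leaky_slope))
        cin = cout
    layers.append(nn.Conv2d(cin, 1, 4, stride=1, padding=0,
                            rng=rng, init="gaussian", init_std=std))
    layers.append(nn.Sigmoid())
    return nn.Sequential(*layers)


def pairs_to_gan_batch(pairs: list[ImageMaskPair]) -> np.ndarray:
    """Stack normalized pairs into (N, 2, H, W) arrays in Tanh range."""
    imgs = np.stack([np.clip(p.image, -IMG_SQUASH, IMG_SQUASH) / IMG_SQUASH
                     for p in pairs])
    masks = np.stack([2.0 * p.mask.astype(np.float64) - 1.0 for p in pairs])
    return np.stack([imgs, masks], axis=1).astype(DTYPE)


@dataclass
class SyntheticPair:
    """A generator sample: image (z-score scale), soft mask in [0, 1]."""

    image: np.ndarray
    soft_mask: np.ndarray
    noise_seed: int
    pair_id: int


def _snapshot(model: nn.Module) -> list[np.ndarray]:
    return [p.value.copy() for p in model.parameters()]


def gan_training_step(gen: nn.Module, disc: nn.Module, real_batch: np.ndarray,
                      opt_g: nn.Adam, opt_d: nn.Adam,
                      rng: np.random.Generator, noise_dim: int = 100,
                      counters: dict | None = None) -> tuple[float, float]:
    """One alternating iteration; returns (d_loss, g_loss).

    Phase (a) touches only discriminator weights, phase (b) only generator
    weights; ``counters`` (if given) tallies the batches each network sees.
    """
    n = real_batch.shape[0]

    # (a) discriminator: real batch labelled 1, then fake batch labelled 0
    opt_d.zero_grad()
    p_real = disc.forward(real_batch.astype(DTYPE))
    loss_r, g_r = nn.bce_loss_grad(p_real, 1.0)
    disc.backward(g_r)
    z = rng.standard_normal((n, noise_dim, 1, 1)).astype(DTYPE)
    fake = gen.forward(z)
    p_fake = disc.forward(fake)
    loss_f, g_f = nn.bce_loss_grad(p_fake, 0.0)
    disc.backward(g_f)
    opt_d.step()
    d_loss = loss_r + loss_f

    # (b) generator through the (frozen) discriminator: fakes labelled 1
    opt_g.zero_grad()
    z = rng.standard_normal((n, noise_dim, 1, 1)).astype(DTYPE)
    fake = gen.forward(z)
    p_mis = disc.forward(fake)
    g_loss, g_m = nn.bce_loss_grad(p_mis, 1.0)
    disc.zero_grad()               # discriminator is frozen in this phase
    dfake = disc.backward(g_m)
    gen.backward(dfake)
    opt_g.step()

    if counters is not None:
        counters["disc_real_batches"] = counters.get("disc_real_batches", 0) + 1
        counters["disc_fake_batches"] = counters.get("disc_fake_batches", 0) + 1
        counters["gen_updates"] = counters.get("gen_updates", 0) + 1
    if not (np.isfinite(d_loss) and np.isfinite(g_loss)):
        raise RuntimeError("non-finite GAN loss")
    return float(d_loss), float(g_loss)


def train_dcgan(pairs: list[ImageMaskPair], spec: GanSpec | None = None,
                cfg: GanTrainConfig | None = None,
                diagnostics_samples: int = 64):
    """Run the alternating schedule for ``cfg.iterations``; returns
    (generator, discriminator, history).

    ``pairs`` must already be normalized and pre-augmented (the pipeline
    applies the x76 rotation/flip scheme before calling this).  History
    records losses and, at each checkpoint, the std of generated mask areas
    (a mode-collapse diagnostic: near-zero spread means collapsed samples).
    """
    spec = spec or GanSpec()
    cfg = cfg or GanTrainConfig()
    cfg.validate()
    if not pairs:
        raise ValueError("empty training data")
    data = pairs_to_gan_batch(pairs)
    rng = np.random.default_rng(cfg.seed)
    gen = build_generator(spec, seed=int(rng.integers(2 ** 31)), train_cfg=cfg)
    disc = build_discriminator(spec, seed=int(rng.integers(2 ** 31)), train_cfg=cfg)
    opt_g = nn.Adam(gen.parameters(), lr=cfg.adam_lr, betas=cfg.adam_betas)
    opt_d = nn.Adam(disc.parameters(), lr=cfg.adam_lr, betas=cfg.adam_betas)
    counters: dict = {}
    history: list[dict] = []
    for it in range(cfg.iterations):
        idx = rng.integers(0, data.shape[0], size=cfg.batch_size)
        try:
            d_loss, g_loss = gan_training_step(
                gen, disc, data[idx], opt_g, opt_d, rng,
                noise_dim=spec.noise_dim, counters=counters)
        except RuntimeError as exc:
            raise RuntimeError(f"GAN training aborted at iteration {it}: {exc}")
        entry = {"iteration": it, "d_loss": d_loss, "g_loss": g_loss}
        if (it + 1) % cfg.checkpoint_every == 0 or it + 1 == cfg.iterations:
            areas = _sample_mask_areas(gen, spec, diagnostics_samples,
                                       seed=int(rng.integers(2 ** 31)))
            entry["mask_area_std"] = float(np.std(areas))
        history.append(entry)
    history.append({"counters": counters})
    return gen, disc, history


def _sample_mask_areas(gen: nn.Module, spec: GanSpec, n: int, seed: int) -> np.ndarray:
    samples = sample_synthetic(gen, n, seed, spec=spec)
    return np.array([float((s.soft_mask >= 0.5).sum()) for s in samples])


def sample_synthetic(gen: nn.Module, n: int = 6000, seed: int = 0,
                     spec: GanSpec | None = None, batch: int = 64,
                     use_running_stats: bool = False) -> list[SyntheticPair]:
    """Draw ``n`` synthetic pairs (deterministic per seed).  Mask channel is
    returned soft (un-quantized) in [0, 1]; quantization is the filter's job.

    By default batch statistics normalize each sampled batch (the training
    batch size of 5 makes running BatchNorm estimates unreliable);
    ``use_running_stats=True`` switches to the accumulated running moments.
    """
    spec = spec or GanSpec()
    rng = np.random.default_rng(seed)
    gen.eval() if use_running_stats else gen.train()
    out: list[SyntheticPair] = []
    while len(out) < n:
        k = min(batch, n - len(out))
        z = rng.standard_normal((k, spec.noise_dim, 1, 1)).astype(DTYPE)
        fake = gen.forward(z)
        for j in range(k):
            img = fake[j, 0].astype(np.float64) * IMG_SQUASH
            soft = (fake[j, 1].astype(np.float64) + 1.0) / 2.0
            out.append(SyntheticPair(image=img, soft_mask=soft,
                                     noise_seed=seed, pair_id=len(out)))
    gen.train()
    return out
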