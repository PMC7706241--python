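"""Source-resolution studies -> normalized 128x128 image-mask pairs.

The chain is fixed: center-crop (default 445 px, removing burned-in
identifiers at the frame edge) -> down-sample to the network input size
(nearest-neighbour or bicubic for images, always nearest for masks) ->
z-normalize the image.  Subject-level train/validation splitting lives here
too, so no subject can leak across the partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .phantom import CHAMBERS, PHASES, CineStudy

log = logging.getLogger(__name__)


@dataclass
class PreprocessConfig:
    crop_size: int = 445
    target_size: int = 128
    downsampling: str = "nearest"   # or "bicubic"
    split_ratio: float = 0.8
    split_seed: int = 0

    def validate(self) -> None:
        if self.downsampling not in ("nearest", "bicubic"):
            raise ValueError(f"unknown downsampling {self.downsampling!r}")
        if not (0.0 < self.split_ratio < 1.0):
            raise ValueError("split_ratio must be in (0, 1)")
        if self.target_size > self.crop_size:
            raise ValueError("target_size must be <= crop_size")


@dataclass
class ImageMaskPair:
    """One normalized slice image with its binary chamber mask.

    ``pixel_spacing_mm`` is the *effective* spacing at the pair's resolution
    (source spacing x crop_size / target_size), so mm-valued metrics computed
    on these grids are physically correct.
    """

    image: np.ndarray
    mask: np.ndarray
    chamber: str
    phase: str
    subject_id: str
    slice_index: int
    pixel_spacing_mm: float
    slice_thickness_mm: float


def center_crop(image: np.ndarray, crop_size: int) -> np.ndarray:
    """Centered crop; an odd remainder puts the extra pixel on the
    top/left margin (documented fixed rule)."""
    h, w = image.shape
    if crop_size > h or crop_size > w:
        raise ValueError(f"crop_size {crop_size} exceeds image shape {image.shape}")
    top = (h - crop_size + 1) // 2
    left = (w - crop_size + 1) // 2
    return image[top:top + crop_size, left:left + crop_size]


def _nearest_indices(n_src: int, n_dst: int) -> np.ndarray:
    # pixel-center alignment: dst i samples src floor((i + 0.5) * n_src / n_dst)
    idx = np.floor((np.arange(n_dst) + 0.5) * n_src / n_dst).astype(int)
    return np.clip(idx, 0, n_src - 1)


def resample(image: np.ndarray, target_size: int, method: str = "nearest",
             is_mask: bool = False) -> np.ndarray:
    """Down-sample to target_size^2.  Masks always use nearest-neighbour and
    are re-thresholded to {0,1}, whatever ``method`` says."""
    if method not in ("nearest", "bicubic"):
        raise ValueError(f"unknown downsampling method {method!r}")
    h, w = image.shape
    if is_mask or method == "nearest":
        ri = _nearest_indices(h, target_size)
        ci = _nearest_indices(w, target_size)
        out = image[np.ix_(ri, ci)]
        if is_mask:
            out = (out > 0.5).astype(np.uint8)
        return out
    out = _sk_resize(image.astype(np.float64), (target_size, target_size),
                     order=3, anti_aliasing=False, preserve_range=True)
    return out


def normalize(image: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance; a constant image maps to all zeros."""
    image = np.asarray(image, dtype=np.float64)
    sd = image.std()
    if sd == 0.0:
        warnings.warn("constant image: normalization returns zeros")
        return np.zeros_like(image)
    return (image - image.mean()) / sd


def preprocess_slice(image: np.ndarray, mask: np.ndarray,
                     config: PreprocessConfig) -> tuple[np.ndarray, np.ndarray]:
    """crop -> resample -> normalize for one (image, mask) slice."""
    img = center_crop(image, config.crop_size)
    msk = center_crop(mask, config.crop_size)
    img = resample(img, config.target_size, config.downsampling, is_mask=False)
    msk = resample(msk, config.target_size, config.downsampling, is_mask=True)
    return normalize(img), msk


def build_pairs(study: CineStudy, config: PreprocessConfig) -> list[ImageMaskPair]:
    """One pair per (chamber, phase, slice); slices whose mask is empty after
    resampling are excluded (the heart must be present in both channels)."""
    config.validate()
    eff_spacing = study.pixel_spacing_mm * config.crop_size / config.target_size
    pairs: list[ImageMaskPair] = []
    for ch in CHAMBERS:
        for ph in PHASES:
            stack = study.images(ph)
            for i in range(stack.shape[0]):
                img, msk = preprocess_slice(stack[i], study.masks[(ch, ph)][i],
                                            config)
                if msk.sum() == 0:
                    continue
                pairs.append(ImageMaskPair(
                    image=img, mask=msk, chamber=ch, phase=ph,
                    subject_id=study.study_id, slice_index=i,
                    pixel_spacing_mm=eff_spacing,
                    slice_thickness_mm=study.slice_thickness_mm))
    if not pairs:
        warnings.warn(f"study {study.study_id}: no retained pairs")
    return pairs


def split_subjects(subject_ids: list[str], ratio: float = 0.8,
                   seed: int = 0) -> tuple[list[str], list[str]]:
    """Subject-level split: round(ratio*n) train, rest validation."""
    n = len(subject_ids)
    if n < 2:
        raise ValueError("need at least 2 subjects to split")
    n_train = int(round(ratio * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"ratio {ratio} leaves one side of the split empty")
    order = np.random.default_rng(seed).permutation(n)
    ids = np.asarray(subject_ids, dtype=object)
    train = sorted(ids[order[:n_train]].tolist())
    val = sorted(ids[order[n_train:]].tolist())
    return train, val
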