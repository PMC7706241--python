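"""Geometric augmentation: the three exact rotation/flip schemes.

Only rotation and flipping are used — transformations that deform chamber
shape (shearing, elastic warps) are deliberately excluded.  The three
schemes and their multiplicities:

* ``classic40``: angles 0..180 step 20 (10) x flips {none,h,v,both} = 40,
  applied to real pairs before segmenter training;
* ``gan76``: angles 0..180 step 10 (19) x the same 4 flips = 76, applied
  before GAN training;
* ``synth7``: {identity, h-flip, v-flip, rot45, rot90, rot135, rot180} = 7,
  applied to filter-accepted synthetic pairs (2,500 accepted -> 17,500).

The identity transform is counted in each multiplicity and duplicates are
kept: the stated factors require it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .preprocess import ImageMaskPair

FLIP_STATES = ("none", "horizontal", "vertical", "both")

_SCHEMES = {
    "classic40": {"angles": tuple(range(0, 181, 20)), "flips": FLIP_STATES},
    "gan76": {"angles": tuple(range(0, 181, 10)), "flips": FLIP_STATES},
}


@dataclass(frozen=True)
class AugmentScheme:
    name: str
    angles_deg: tuple
    flip_states: tuple
    multiplicity: int

    @classmethod
    def by_name(cls, name: str) -> "AugmentScheme":
        if name in _SCHEMES:
            s = _SCHEMES[name]
            return cls(name, s["angles"], s["flips"],
                       len(s["angles"]) * len(s["flips"]))
        if name == "synth7":
            return cls(name, (45, 90, 135, 180), ("none", "horizontal", "vertical"), 7)
        raise ValueError(f"unknown augmentation scheme {name!r}")


def _flip(arr: np.ndarray, state: str) -> np.ndarray:
    if state == "none":
        return arr
    if state == "horizontal":
        return arr[:, ::-1]
    if state == "vertical":
        return arr[::-1, :]
    if state == "both":
        return arr[::-1, ::-1]
    raise ValueError(f"unknown flip state {state!r}")


def _rotate(arr: np.ndarray, angle: float, order: int) -> np.ndarray:
    if angle % 360 == 0:
        return arr
    if angle % 90 == 0:
        return np.rot90(arr, k=int(angle // 90) % 4)
    return ndimage.rotate(arr, angle, reshape=False, order=order,
                          mode="constant", cval=0.0)


def rotate_pair(pair: ImageMaskPair, angle_deg: float) -> ImageMaskPair:
    """Rotate about the canvas center; image bilinear, mask nearest then
    re-binarized; canvas size unchanged, out-of-canvas regions fill with 0."""
    img = _rotate(np.asarray(pair.image, dtype=np.float64), angle_deg, order=1)
    msk = _rotate(pair.mask.astype(np.float64), angle_deg, order=0)
    return replace(pair, image=img, mask=(msk > 0.5).astype(np.uint8))


def flip_pair(pair: ImageMaskPair, state: str) -> ImageMaskPair:
    return replace(pair, image=_flip(np.asarray(pair.image), state).copy(),
                   mask=_flip(pair.mask, state).copy())


def apply_scheme(pair: ImageMaskPair, scheme: AugmentScheme | str) -> list[ImageMaskPair]:
    """Expand one pair into ``scheme.multiplicity`` pairs, deterministically
    ordered (angles outer, flips inner)."""
    if isinstance(scheme, str):
        scheme = AugmentScheme.by_name(scheme)
    out: list[ImageMaskPair] = []
    if scheme.name == "synth7":
        out.append(flip_pair(pair, "none"))
        out.append(flip_pair(pair, "horizontal"))
        out.append(flip_pair(pair, "vertical"))
        for a in scheme.angles_deg:
            out.append(rotate_pair(pair, a))
        return out
    for a in scheme.angles_deg:
        rotated = rotate_pair(pair, a)
        for f in scheme.flip_states:
            out.append(flip_pair(rotated, f))
    return out


def augment_pairs(pairs: list[ImageMaskPair],
                  scheme: AugmentScheme | str) -> list[ImageMaskPair]:
    """Apply the scheme to every pair; yields multiplicity x len(pairs)."""
    if isinstance(scheme, str):
        scheme = AugmentScheme.by_name(scheme)
    out: list[ImageMaskPair] = []
    for p in pairs:
        out.extend(apply_scheme(p, scheme))
    return out
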