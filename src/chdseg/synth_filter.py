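"""Quality filters that turn raw generator outputs into accepted training pairs.

Order is fixed: quantize the soft mask at 0.5, then keep only samples whose
mask-area fraction of the 128x128 frame falls inside a window (0.005-0.025
for nearest-neighbour preprocessed data, 0.02-0.05 for bicubic — bicubic
masks are systematically larger), then drop masks with a spurious second
blob: if there is more than one connected component and the largest-to-
second-largest area ratio is below 20, the pair is removed.  Bounds are
inclusive; components use 8-connectivity (both configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .gan import SyntheticPair

AREA_WINDOWS = {"nearest": (0.005, 0.025), "bicubic": (0.02, 0.05)}


@dataclass
class FilterConfig:
    quantize_threshold: float = 0.5
    area_ratio_range: tuple[float, float] = AREA_WINDOWS["nearest"]
    component_ratio_min: float = 20.0
    connectivity: int = 8

    @classmethod
    def for_downsampling(cls, method: str) -> "FilterConfig":
        return cls(area_ratio_range=AREA_WINDOWS[method])

    def validate(self) -> None:
        lo, hi = self.area_ratio_range
        if not (0.0 < lo < hi < 1.0):
            raise ValueError("area_ratio_range must satisfy 0 < low < high < 1")
        if self.component_ratio_min <= 1:
            raise ValueError("component_ratio_min must be > 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


@dataclass
class FilterVerdict:
    pair_id: int
    passed: bool
    area_ratio: float
    n_components: int
    component_ratio: float | None
    rejection_reason: str  # none | area_low | area_high | component_ratio


def quantize_mask(soft_mask: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Pixel < threshold -> 0, >= threshold -> 1.  Values outside [0, 1]
    (numerical spill from the inverse Tanh map) are clipped with a warning."""
    m = np.asarray(soft_mask, dtype=np.float64)
    if m.min() < 0.0 or m.max() > 1.0:
        warnings.warn("soft mask values outside [0, 1]; clipping")
        m = np.clip(m, 0.0, 1.0)
    return (m >= threshold).astype(np.uint8)


def area_ratio(mask: np.ndarray) -> float:
    return float(mask.sum()) / mask.size


def area_ratio_filter(mask: np.ndarray,
                      window: tuple[float, float]) -> tuple[bool, float, str]:
    """Inclusive window on mask pixel count / total pixels."""
    r = area_ratio(mask)
    if r < window[0]:
        return False, r, "area_low"
    if r > window[1]:
        return False, r, "area_high"
    return True, r, "none"


def _component_areas(mask: np.ndarray, connectivity: int) -> np.ndarray:
    structure = np.ones((3, 3)) if connectivity == 8 else None
    lab, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.array([])
    areas = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    return np.sort(np.asarray(areas))[::-1]


def component_ratio_filter(mask: np.ndarray, ratio_min: float = 20.0,
                           connectivity: int = 8) -> tuple[bool, int, float | None]:
    """<= 1 component passes; otherwise pass iff largest/second >= ratio_min."""
    areas = _component_areas(mask, connectivity)
    n = len(areas)
    if n <= 1:
        return True, n, None
    ratio = float(areas[0] / areas[1])
    return ratio >= ratio_min, n, ratio


def filter_pipeline(pairs: list[SyntheticPair],
                    cfg: FilterConfig | None = None,
                    take: int | None = None,
                    sample_seed: int | None = None
                    ) -> tuple[list[SyntheticPair], pd.DataFrame]:
    """quantize -> area window -> component rule; one verdict row per input.

    ``take`` caps the accepted set: the first N accepted by default, or a
    seeded random draw of N when ``sample_seed`` is given.
    """
    cfg = cfg or FilterConfig()
    cfg.validate()
    accepted: list[SyntheticPair] = []
    rows: list[FilterVerdict] = []
    for pair in pairs:
        mask = quantize_mask(pair.soft_mask, cfg.quantize_threshold)
        ok_a, ratio, reason = area_ratio_filter(mask, cfg.area_ratio_range)
        n_comp, comp_ratio = 0, None
        if ok_a:
            ok_c, n_comp, comp_ratio = component_ratio_filter(
                mask, cfg.component_ratio_min, cfg.connectivity)
            if not ok_c:
                reason = "component_ratio"
        passed = reason == "none"
        rows.append(FilterVerdict(pair.pair_id, passed, ratio, n_comp,
                                  comp_ratio, reason))
        if passed:
            accepted.append(pair)
    if take is not None and len(accepted) > take:
        if sample_seed is not None:
            idx = np.random.default_rng(sample_seed).choice(
                len(accepted), size=take, replace=False)
            accepted = [accepted[i] for i in sorted(idx)]
        else:
            accepted = accepted[:take]
    table = pd.DataFrame([vars(v) for v in rows])
    return accepted, table
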