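"""Synthetic short-axis cine CMR phantom with exact ground-truth masks.

Generates studies that structurally resemble a pediatric short-axis
acquisition — a stack of 12–15 slices per cardiac phase at 512×512, a bright
left-ventricular blood pool inside a darker myocardial ring, a crescent-shaped
right ventricle, end-systolic geometry shrunk relative to end-diastole, and a
linear base-to-apex taper — so every downstream stage (preprocessing,
augmentation, GAN training, evaluation) can be tested without any data
download.  Shapes are deliberately simple (disk LV, half-annulus RV): the
phantom exists for testability, not bSSFP realism.

Masks are rasterized analytically *before* intensity noise is added, so the
ground truth is exact and chamber volumes have a closed-form reference
(sum over slices of the rasterized disk areas x pixel area x thickness).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

CHAMBERS = ("LV", "RV")
PHASES = ("ED", "ES")


@dataclass
class PhantomConfig:
    """Geometry and intensity controls for one synthetic study.

    Radii are in source-resolution pixels.  Defaults put the preprocessed
    (445-crop, 128-resize) mask area ratios inside the nearest-neighbour
    synthetic-quality window used downstream.
    """

    n_slices: int = 13
    source_size: int = 512
    pixel_spacing_mm: float = 1.7
    slice_thickness_mm: float = 8.0
    lv_radius_range_px: tuple[float, float] = (36.0, 44.0)
    wall_thickness_px: float = 8.0
    rv_thickness_px: float = 10.0
    es_shrink_factor: float = 0.6
    apex_taper: float = 0.55         # apical radius as a fraction of basal
    apical_empty_slice: bool = True  # render the last slice with no chambers
    noise_sd: float = 0.05
    center_jitter_px: float = 12.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if not (0.0 < self.es_shrink_factor <= 1.0):
            raise ValueError("es_shrink_factor must be in (0, 1]")
        if self.source_size < 64:
            raise ValueError("source_size must be >= 64")
        max_extent = (self.lv_radius_range_px[1] + self.wall_thickness_px
                      + self.rv_thickness_px + self.center_jitter_px)
        if 2 * max_extent >= self.source_size:
            raise ValueError(
                f"geometry (max radial extent {max_extent:.1f} px) does not fit "
                f"inside a {self.source_size} px image")


@dataclass
class CineStudy:
    """One subject: per-phase image stacks, per-chamber binary masks, spacing."""

    study_id: str
    images_ed: np.ndarray   # (n_slices, S, S) float
    images_es: np.ndarray
    masks: dict             # (chamber, phase) -> (n_slices, S, S) uint8
    pixel_spacing_mm: float
    slice_thickness_mm: float
    geometry: dict = field(default_factory=dict)  # analytic radii per slice

    def images(self, phase: str) -> np.ndarray:
        return self.images_ed if phase == "ED" else self.images_es


def _disk(size: int, cx: float, cy: float, r: float) -> np.ndarray:
    if r <= 0:
        return np.zeros((size, size), dtype=bool)
    yy, xx = np.ogrid[:size, :size]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def _slice_geometry(cfg: PhantomConfig, rng: np.random.Generator) -> dict:
    """Draw per-study geometry: center, basal LV radius, per-slice taper."""
    c = cfg.source_size / 2.0
    jitter = cfg.center_jitter_px
    cx = c + rng.uniform(-jitter, jitter)
    cy = c + rng.uniform(-jitter, jitter)
    r_base = rng.uniform(*cfg.lv_radius_range_px)
    n = cfg.n_slices
    radii = []
    for i in range(n):
        if cfg.apical_empty_slice and i == n - 1:
            radii.append(0.0)
            continue
        span = max(n - 1, 1)
        frac = 1.0 - (i / span) * (1.0 - cfg.apex_taper)
        radii.append(r_base * frac)
    return {"cx": cx, "cy": cy, "lv_radii_ed": radii}


def _render_slice(cfg: PhantomConfig, cx: float, cy: float, r_lv: float,
                  shrink: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one slice; returns (clean image, lv mask, rv mask)."""
    S = cfg.source_size
    r = r_lv * shrink
    img = np.full((S, S), 0.2, dtype=np.float64)
    lv = np.zeros((S, S), dtype=np.uint8)
    rv = np.zeros((S, S), dtype=np.uint8)
    if r > 0:
        r_epi = r + cfg.wall_thickness_px
        r_rv = r_epi + cfg.rv_thickness_px * shrink
        epi = _disk(S, cx, cy, r_epi)
        lv_m = _disk(S, cx, cy, r)
        xx = np.arange(S)[None, :]
        crescent = _disk(S, cx, cy, r_rv) & ~epi & (xx < cx)
        img[_disk(S, cx, cy, r_rv) & (xx < cx)] = 0.35  # RV free wall
        img[epi] = 0.35                                  # myocardium
        img[crescent] = 0.85                             # RV blood pool
        img[lv_m] = 0.9                                  # LV blood pool
        lv = lv_m.astype(np.uint8)
        rv = crescent.astype(np.uint8)
    return img, lv, rv


def generate_study(config: PhantomConfig) -> CineStudy:
    """Deterministically render one synthetic cine study from its config."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    geo = _slice_geometry(config, rng)
    S, n = config.source_size, config.n_slices
    images = {ph: np.zeros((n, S, S)) for ph in PHASES}
    masks = {(ch, ph): np.zeros((n, S, S), dtype=np.uint8)
             for ch in CHAMBERS for ph in PHASES}
    for ph, shrink in (("ED", 1.0), ("ES", config.es_shrink_factor)):
        for i, r in enumerate(geo["lv_radii_ed"]):
            img, lv, rv = _render_slice(config, geo["cx"], geo["cy"], r, shrink)
            images[ph][i] = img
            masks[("LV", ph)][i] = lv
            masks[("RV", ph)][i] = rv
    # noise after mask extraction so ground truth stays exact
    for ph in PHASES:
        images[ph] = images[ph] + rng.normal(0.0, config.noise_sd, images[ph].shape)
    return CineStudy(
        study_id=f"phantom-{config.seed:06d}",
        images_ed=images["ED"], images_es=images["ES"], masks=masks,
        pixel_spacing_mm=config.pixel_spacing_mm,
        slice_thickness_mm=config.slice_thickness_mm,
        geometry=geo,
    )


def generate_cohort(n_subjects: int, base_seed: int,
                    config: PhantomConfig | None = None) -> list[CineStudy]:
    """Reproducible cohort; per-subject seeds derived from ``base_seed``."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    config = config or PhantomConfig()
    seeds = np.random.SeedSequence(base_seed).generate_state(n_subjects) % (2 ** 31)
    studies = []
    for s in seeds:
        cfg = PhantomConfig(**{**asdict(config), "seed": int(s)})
        studies.append(generate_study(cfg))
    return studies


def analytic_volume_ml(study: CineStudy, chamber: str, phase: str) -> float:
    """Rasterized-mask chamber volume (slice summation), the phantom's exact
    ground truth: sum over slices of pixel count x spacing^2 x thickness."""
    m = study.masks[(chamber, phase)]
    area_px = float(m.reshape(m.shape[0], -1).sum())
    return area_px * study.pixel_spacing_mm ** 2 * study.slice_thickness_mm / 1000.0


# ---------------------------------------------------------------------------
# on-disk formats


def write_study_nifti(study: CineStudy, out_dir: str | Path) -> Path:
    """One 3-D NIfTI per phase per channel (image, LV mask, RV mask)."""
    import nibabel as nib

    out = Path(out_dir) / study.study_id
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([study.pixel_spacing_mm, study.pixel_spacing_mm,
                      study.slice_thickness_mm, 1.0])
    for ph in PHASES:
        vols = {"image": study.images(ph).transpose(1, 2, 0)}
        for ch in CHAMBERS:
            vols[f"{ch.lower()}_mask"] = study.masks[(ch, ph)].transpose(1, 2, 0)
        for name, vol in vols.items():
            nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine),
                     out / f"{ph.lower()}_{name}.nii")
    meta = {"study_id": study.study_id,
            "pixel_spacing_mm": study.pixel_spacing_mm,
            "slice_thickness_mm": study.slice_thickness_mm}
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return out


def read_study_nifti(study_dir: str | Path) -> CineStudy:
    import nibabel as nib

    study_dir = Path(study_dir)
    meta = json.loads((study_dir / "meta.json").read_text())
    images, masks = {}, {}
    for ph in PHASES:
        images[ph] = np.asarray(
            nib.load(study_dir / f"{ph.lower()}_image.nii").get_fdata()
        ).transpose(2, 0, 1)
        for ch in CHAMBERS:
            vol = np.asarray(
                nib.load(study_dir / f"{ph.lower()}_{ch.lower()}_mask.nii").get_fdata())
            masks[(ch, ph)] = (vol.transpose(2, 0, 1) > 0.5).astype(np.uint8)
    return CineStudy(study_id=meta["study_id"], images_ed=images["ED"],
                     images_es=images["ES"], masks=masks,
                     pixel_spacing_mm=meta["pixel_spacing_mm"],
                     slice_thickness_mm=meta["slice_thickness_mm"])


def write_study_png(study: CineStudy, out_dir: str | Path) -> Path:
    """Per-slice 16-bit PNGs plus a JSON sidecar carrying spacing and the
    intensity scaling needed to invert the uint16 quantization."""
    import imageio.v3 as iio

    out = Path(out_dir) / study.study_id
    out.mkdir(parents=True, exist_ok=True)
    lo = float(min(study.images_ed.min(), study.images_es.min()))
    hi = float(max(study.images_ed.max(), study.images_es.max()))
    scale = (hi - lo) or 1.0
    for ph in PHASES:
        imgs = study.images(ph)
        for i in range(imgs.shape[0]):
            q = np.round((imgs[i] - lo) / scale * 65535).astype(np.uint16)
            iio.imwrite(out / f"{ph.lower()}_image_{i:02d}.png", q)
            for ch in CHAMBERS:
                m = (study.masks[(ch, ph)][i] * 255).astype(np.uint8)
                iio.imwrite(out / f"{ph.lower()}_{ch.lower()}_mask_{i:02d}.png", m)
    meta = {"study_id": study.study_id,
            "pixel_spacing_mm": study.pixel_spacing_mm,
            "slice_thickness_mm": study.slice_thickness_mm,
            "n_slices": int(study.images_ed.shape[0]),
            "intensity_lo": lo, "intensity_hi": hi}
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return out


def read_study_png(study_dir: str | Path) -> CineStudy:
    import imageio.v3 as iio

    study_dir = Path(study_dir)
    meta = json.loads((study_dir / "meta.json").read_text())
    n = meta["n_slices"]
    lo, hi = meta["intensity_lo"], meta["intensity_hi"]
    scale = (hi - lo) or 1.0
    images, masks = {}, {}
    for ph in PHASES:
        images[ph] = np.stack([
            iio.imread(study_dir / f"{ph.lower()}_image_{i:02d}.png")
            .astype(np.float64) / 65535 * scale + lo for i in range(n)])
        for ch in CHAMBERS:
            masks[(ch, ph)] = np.stack([
                (iio.imread(study_dir / f"{ph.lower()}_{ch.lower()}_mask_{i:02d}.png")
                 > 127).astype(np.uint8) for i in range(n)])
    return CineStudy(study_id=meta["study_id"], images_ed=images["ED"],
                     images_es=images["ES"], masks=masks,
                     pixel_spacing_mm=meta["pixel_spacing_mm"],
                     slice_thickness_mm=meta["slice_thickness_mm"])
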