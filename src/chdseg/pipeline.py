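"""End-to-end reproducible driver: phantom -> preprocess -> augment ->
(optional GAN -> filter -> synthetic merge) -> train -> evaluate.

Every stage logs its input/output counts and seeds into a JSON manifest in
the run directory; re-running with the same config and seed reproduces the
manifest counts exactly.  The synthetically augmented dataset (SAD)
configuration merges filter-accepted generator samples — expanded by the
7-fold post-synthesis scheme — into the real classic-40-augmented training
set, so with the published full-scale counts the training set holds
40 x n_real + 17,500 pairs per chamber.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import augment_pairs
from .evaluation import evaluate_cohort
from .gan import GanSpec, GanTrainConfig, sample_synthetic, train_dcgan
from .models import FcnSpec, TrainConfig, build_fcn, build_unet, predict_mask, train_segmenter
from .phantom import CHAMBERS, PHASES, PhantomConfig, generate_cohort
from .preprocess import ImageMaskPair, PreprocessConfig, build_pairs, preprocess_slice, split_subjects
from .synth_filter import FilterConfig, filter_pipeline


@dataclass
class RunConfig:
    """One config object for the whole pipeline.  Full-scale defaults follow
    the published recipe; tests and the smoke CLI pass scaled-down values."""

    seed: int = 0
    chambers: tuple = CHAMBERS
    n_train_subjects: int = 26
    n_test_subjects: int = 38
    arch: str = "fcn"                 # or "unet"
    sad: bool = False                 # merge accepted synthetic pairs
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    fcn: FcnSpec = field(default_factory=FcnSpec)
    unet_base_filters: int = 16
    train: TrainConfig = field(default_factory=TrainConfig)
    gan: GanSpec = field(default_factory=GanSpec)
    gan_train: GanTrainConfig = field(default_factory=GanTrainConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    n_synthetic: int = 6000
    synthetic_take: int = 2500
    classic_scheme: str = "classic40"
    gan_scheme: str = "gan76"
    synth_scheme: str = "synth7"


def _log(run_dir: Path, stage: str, **info) -> None:
    entry = {"t": time.time(), "stage": stage, **info}
    with open(run_dir / "log.jsonl", "a") as fh:
        fh.write(json.dumps(entry) + "\n")


def _synthetic_to_pairs(samples, template: ImageMaskPair) -> list[ImageMaskPair]:
    from .synth_filter import quantize_mask

    out = []
    for s in samples:
        out.append(dataclasses.replace(
            template, image=s.image,
            mask=quantize_mask(s.soft_mask),
            subject_id=f"synthetic-{s.pair_id}", slice_index=0))
    return out


def run_pipeline(config: RunConfig, run_dir: str | Path) -> dict:
    """Execute every enabled stage; returns (and writes) the manifest."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    rng = np.random.SeedSequence(config.seed)
    sub_seeds = rng.generate_state(8) % (2 ** 31)

    stage = "phantom"
    try:
        train_cohort = generate_cohort(config.n_train_subjects,
                                       int(sub_seeds[0]), config.phantom)
        test_cohort = generate_cohort(config.n_test_subjects,
                                      int(sub_seeds[1]), config.phantom)
        manifest["stages"]["phantom"] = {
            "n_train_subjects": len(train_cohort),
            "n_test_subjects": len(test_cohort)}
        _log(run_dir, stage, **manifest["stages"]["phantom"])

        stage = "preprocess"
        pairs_by_study = {s.study_id: build_pairs(s, config.preprocess)
                          for s in train_cohort}
        train_ids, val_ids = split_subjects(
            sorted(pairs_by_study), config.preprocess.split_ratio,
            config.preprocess.split_seed)
        manifest["stages"]["preprocess"] = {
            "n_pairs": sum(len(v) for v in pairs_by_study.values()),
            "train_subjects": len(train_ids), "val_subjects": len(val_ids)}
        _log(run_dir, stage, **manifest["stages"]["preprocess"])

        results = {}
        for chamber in config.chambers:
            results[chamber] = _run_chamber(
                config, run_dir, chamber, pairs_by_study, train_ids, val_ids,
                test_cohort, int(sub_seeds[2]))
        manifest["stages"]["chambers"] = {
            ch: res["counts"] for ch, res in results.items()}

        stage = "evaluate"
        predictions, truth, spacing = {}, {}, {}
        for study in test_cohort:
            spacing[study.study_id] = (
                study.pixel_spacing_mm * config.preprocess.crop_size
                / config.preprocess.target_size,
                study.slice_thickness_mm)
            for ch in config.chambers:
                model = results[ch]["model"]
                for ph in PHASES:
                    key = (study.study_id, ch, ph)
                    pred_stack, true_stack = [], []
                    imgs = study.images(ph)
                    for i in range(imgs.shape[0]):
                        img, msk = preprocess_slice(
                            imgs[i], study.masks[(ch, ph)][i], config.preprocess)
                        import warnings as _w
                        with _w.catch_warnings():
                            _w.simplefilter("ignore")
                            pred_stack.append(predict_mask(model, img))
                        true_stack.append(msk)
                    predictions[key] = np.stack(pred_stack)
                    truth[key] = np.stack(true_stack)
        report = evaluate_cohort(predictions, truth, spacing)
        report.metrics.to_csv(run_dir / "metrics.csv", index=False)
        report.volumetrics.to_csv(run_dir / "volumetrics.csv", index=False)
        report.agreement.to_csv(run_dir / "agreement.csv", index=False)
        manifest["stages"]["evaluate"] = {
            "n_metric_rows": len(report.metrics),
            "n_excluded_slices": report.n_excluded_slices}
        _log(run_dir, stage, **manifest["stages"]["evaluate"])
    except Exception as exc:
        manifest["failed_stage"] = stage
        (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _run_chamber(config: RunConfig, run_dir: Path, chamber: str,
                 pairs_by_study: dict, train_ids: list, val_ids: list,
                 test_cohort, seed: int) -> dict:
    train_pairs = [p for sid in train_ids for p in pairs_by_study[sid]
                   if p.chamber == chamber]
    val_pairs = [p for sid in val_ids for p in pairs_by_study[sid]
                 if p.chamber == chamber]
    counts = {"real_train_pairs": len(train_pairs),
              "real_val_pairs": len(val_pairs)}

    aug_train = augment_pairs(train_pairs, config.classic_scheme)
    counts["classic_augmented"] = len(aug_train)

    if config.sad:
        gan_pairs = augment_pairs(train_pairs, config.gan_scheme)
        counts["gan_training_pairs"] = len(gan_pairs)
        gen, _disc, _hist = train_dcgan(gan_pairs, config.gan, config.gan_train)
        samples = sample_synthetic(gen, config.n_synthetic, seed=seed,
                                   spec=config.gan)
        accepted, verdicts = filter_pipeline(samples, config.filter,
                                             take=config.synthetic_take)
        verdicts.to_csv(run_dir / f"filter_{chamber}.csv", index=False)
        counts["synthetic_generated"] = len(samples)
        counts["synthetic_accepted"] = len(accepted)
        synth_pairs = _synthetic_to_pairs(accepted, train_pairs[0])
        synth_aug = augment_pairs(synth_pairs, config.synth_scheme)
        counts["synthetic_augmented"] = len(synth_aug)
        aug_train = aug_train + synth_aug
    counts["training_set_size"] = len(aug_train)
    _log(run_dir, f"augment[{chamber}]", **counts)

    if config.arch == "fcn":
        spec = dataclasses.replace(config.fcn, seed=seed,
                                   input_size=config.preprocess.target_size)
        model = build_fcn(spec)
    elif config.arch == "unet":
        model = build_unet(config.unet_base_filters,
                           input_size=config.preprocess.target_size, seed=seed)
    else:
        raise ValueError(f"unknown arch {config.arch!r}")
    train_cfg = dataclasses.replace(config.train, seed=seed)
    model, history = train_segmenter(model, aug_train, val_pairs, train_cfg)
    pd.DataFrame(history).to_csv(run_dir / f"history_{chamber}.csv", index=False)
    _log(run_dir, f"train[{chamber}]", epochs=len(history))
    return {"model": model, "counts": counts, "history": history}


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a finished run: cohort metric means,
    volumetric agreement with t-test / ICC pass flags, stage counts."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}")
    manifest = json.loads(manifest_path.read_text())
    lines = [f"Run summary: {run_dir}", f"  seed: {manifest.get('seed')}"]
    for stage in ("phantom", "preprocess", "chambers", "evaluate"):
        info = manifest.get("stages", {}).get(stage)
        lines.append(f"  {stage}: " + (json.dumps(info) if info else "not run"))
    metrics_path = run_dir / "metrics.csv"
    if metrics_path.exists():
        df = pd.read_csv(metrics_path)
        if len(df):
            for (ch, ph), grp in df.groupby(["chamber", "phase"]):
                lines.append(
                    f"  {ch} {ph}: Dice {grp.dice_pct.mean():.1f}% "
                    f"Jaccard {grp.jaccard_pct.mean():.1f}% "
                    f"HD {grp.hd_mm.mean():.2f} mm MCD {grp.mcd_mm.mean():.2f} mm")
    else:
        lines.append("  metrics: not run")
    agree_path = run_dir / "agreement.csv"
    if agree_path.exists() and agree_path.stat().st_size > 1:
        try:
            df = pd.read_csv(agree_path)
        except pd.errors.EmptyDataError:
            df = pd.DataFrame()
        for _, r in df.iterrows():
            t_flag = "pass" if r.t_passed else "FAIL"
            icc_flag = r.icc_category
            lines.append(
                f"  {r.chamber} {r['index']}: t-test p={r.t_p_value:.3f} "
                f"[{t_flag}]  ICC={r.icc:.3f} [{icc_flag}]  "
                f"bias={r.ba_bias:.2f} LoA=({r.ba_loa_low:.2f}, {r.ba_loa_high:.2f})")
    else:
        lines.append("  agreement: not run")
    return "\n".join(lines)
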