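"""Geometric, clinical, and statistical evaluation of predicted segmentations.

Geometric metrics compare binary masks: Dice 2|P∩T|/(|P|+|T|) and Jaccard
|P∩T|/|P∪T| (reported as percentages), pixel-classification rates
(sensitivity, specificity, PPV, NPV), and contour distances in mm — the
exact symmetric Hausdorff distance and the mean contour distance (mean of
nearest-contour distances over both directed point sets).

Clinical volumetrics use slice summation: V = sum over slices of mask pixel
count x spacing^2 x thickness (mL); SV = EDV - ESV; EF = 100*SV/EDV.

Cohort agreement between predicted and manual indices uses the paired
Student t-test (passing means p > 0.05: no detectable systematic
difference), Fisher's intraclass correlation with the Koo-Li interpretation
bins (<0.5 poor, 0.5-0.75 moderate, 0.75-0.90 good, >0.90 excellent),
Bland-Altman bias with +/-1.96 sd limits of agreement, and the squared
Pearson correlation of volumes (R^2, %).

Conventions for degenerate inputs: both masks empty -> Dice = Jaccard = 100;
one empty -> overlap 0 and distance metrics missing (excluded from
averages, with the exclusion counted); ratios with zero denominator are
reported missing, never as 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

ICC_BINS = ((0.5, "poor"), (0.75, "moderate"), (0.90, "good"), (np.inf, "excellent"))


def _check_masks(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    for m in (pred, truth):
        u = np.unique(m)
        if not np.isin(u, (0, 1)).all():
            raise ValueError("masks must be binary {0,1}")
    return pred.astype(bool), truth.astype(bool)


def overlap_metrics(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Dice/Jaccard/sens/spec/PPV/NPV in percent; undefined ratios -> NaN."""
    p, t = _check_masks(pred, truth)
    tp = float(np.logical_and(p, t).sum())
    fp = float(np.logical_and(p, ~t).sum())
    fn = float(np.logical_and(~p, t).sum())
    tn = float(np.logical_and(~p, ~t).sum())

    def ratio(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else np.nan

    if not p.any() and not t.any():
        dice = jaccard = 100.0  # perfect agreement on an empty field
    else:
        dice = ratio(2 * tp, 2 * tp + fp + fn)
        jaccard = ratio(tp, tp + fp + fn)
    return {
        "dice_pct": dice,
        "jaccard_pct": jaccard,
        "sensitivity_pct": ratio(tp, tp + fn),
        "specificity_pct": ratio(tn, tn + fp),
        "ppv_pct": ratio(tp, tp + fp),
        "npv_pct": ratio(tn, tn + fn),
    }


def contour_points(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels: mask pixels with at least one 4-neighbour outside."""
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    boundary = m & ~interior
    return np.argwhere(boundary)


def contour_distance_metrics(pred: np.ndarray, truth: np.ndarray,
                             pixel_spacing_mm: float = 1.0) -> dict:
    """Exact symmetric Hausdorff and mean contour distance in mm; either
    mask empty -> both metrics missing (NaN) with a reason."""
    p, t = _check_masks(pred, truth)
    if not p.any() or not t.any():
        return {"hd_mm": np.nan, "mcd_mm": np.nan, "reason": "empty_mask"}
    a = contour_points(p) * pixel_spacing_mm
    b = contour_points(t) * pixel_spacing_mm
    d = cdist(a, b)
    d_ab = d.min(axis=1)   # each pred contour point -> nearest truth point
    d_ba = d.min(axis=0)
    hd = max(d_ab.max(), d_ba.max())
    mcd = float(np.concatenate([d_ab, d_ba]).mean())
    return {"hd_mm": float(hd), "mcd_mm": mcd, "reason": "none"}


def chamber_volume(mask_stack: np.ndarray, pixel_spacing_mm: float,
                   slice_thickness_mm: float) -> float:
    """Slice-summation volume in mL.  Slices with no segmentation simply
    contribute zero (which can underestimate a chamber that extends into
    an unsegmented slice — a documented property of slice summation)."""
    if pixel_spacing_mm <= 0 or slice_thickness_mm <= 0:
        raise ValueError("spacing and thickness must be positive")
    stack = np.asarray(mask_stack)
    if stack.size == 0:
        return 0.0
    area_px = float((stack > 0).sum())
    return area_px * pixel_spacing_mm ** 2 * slice_thickness_mm / 1000.0


def clinical_indices(edv_ml: float, esv_ml: float) -> dict:
    """SV = EDV - ESV; EF = 100 * SV / EDV (missing when EDV = 0)."""
    if esv_ml > edv_ml:
        warnings.warn("ESV exceeds EDV; indices computed anyway")
    sv = edv_ml - esv_ml
    ef = 100.0 * sv / edv_ml if edv_ml > 0 else np.nan
    return {"sv_ml": sv, "ef_pct": ef}


def paired_t_test(pred_values, truth_values) -> dict:
    """Two-sided paired Student t-test; pass means p > 0.05 (no evidence of
    a systematic difference).  Zero-variance differences -> p = 1, flagged."""
    x = np.asarray(pred_values, dtype=float)
    y = np.asarray(truth_values, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        return {"p_value": 1.0, "passed": True, "degenerate": True}
    p = float(stats.ttest_rel(x, y).pvalue)
    return {"p_value": p, "passed": p > 0.05, "degenerate": False}


def icc_category(icc: float) -> str:
    for hi, name in ICC_BINS:
        if icc < hi:
            return name
    return "excellent"


def fisher_icc(pred_values, truth_values) -> dict:
    """Fisher's intraclass correlation for paired measurements.

    With pooled mean m and pooled (population) variance s^2 over all 2n
    values: ICC = (1/n) * sum (x_i - m)(y_i - m) / s^2.
    """
    x = np.asarray(pred_values, dtype=float)
    y = np.asarray(truth_values, dtype=float)
    if x.shape != y.shape or len(x) < 3:
        raise ValueError("need >= 3 equal-length pairs")
    n = len(x)
    pooled = np.concatenate([x, y])
    m = pooled.mean()
    s2 = pooled.var()  # divisor 2n
    if s2 == 0.0:
        return {"icc": np.nan, "category": "undefined"}
    icc = float(((x - m) * (y - m)).sum() / (n * s2))
    return {"icc": icc, "category": icc_category(icc)}


def bland_altman(pred_values, truth_values) -> dict:
    """Bias (mean of pred - truth) and 1.96-sd limits of agreement."""
    x = np.asarray(pred_values, dtype=float)
    y = np.asarray(truth_values, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need >= 2 equal-length pairs")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return {"bias": bias, "loa_low": bias - 1.96 * sd, "loa_high": bias + 1.96 * sd,
            "sd": sd}


def r2_vol(pred_values, truth_values, method: str = "pearson") -> float:
    """Coefficient of determination of predicted vs true volumes, in %.

    Default is the squared Pearson correlation (scale/offset invariant);
    ``method='identity'`` instead scores agreement with the y = x line:
    1 - SS_res/SS_tot with residuals taken against the identity.
    """
    x = np.asarray(pred_values, dtype=float)
    y = np.asarray(truth_values, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant inputs: correlation undefined")
    if method == "pearson":
        r = np.corrcoef(x, y)[0, 1]
        return float(100.0 * r * r)
    if method == "identity":
        ss_res = float(((x - y) ** 2).sum())
        ss_tot = float(((y - y.mean()) ** 2).sum())
        return float(100.0 * (1.0 - ss_res / ss_tot))
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# cohort-level evaluation

VOLUME_INDICES = ("EDV", "ESV", "SV", "EF")


@dataclass
class CohortEvaluation:
    metrics: pd.DataFrame       # per (subject, chamber, phase) geometric metrics
    volumetrics: pd.DataFrame   # per (subject, chamber, source) volumes + diffs
    agreement: pd.DataFrame     # per (chamber, index) agreement statistics
    n_excluded_slices: int      # empty-truth slices excluded from distances


def _phase_metrics(pred_stack: np.ndarray, truth_stack: np.ndarray,
                   spacing: float) -> tuple[dict, int]:
    """Slice-wise metrics averaged over the stack; empty-truth slices are
    excluded from all metrics and counted."""
    rows, excluded = [], 0
    for ps, ts in zip(pred_stack, truth_stack):
        if not np.asarray(ts).any():
            excluded += 1
            continue
        rec = overlap_metrics(ps, ts)
        rec.update({k: v for k, v in
                    contour_distance_metrics(ps, ts, spacing).items()
                    if k != "reason"})
        rows.append(rec)
    if not rows:
        return {}, excluded
    df = pd.DataFrame(rows)
    return df.mean(skipna=True).to_dict(), excluded


def evaluate_cohort(predictions: dict, ground_truth: dict,
                    spacing: dict) -> CohortEvaluation:
    """Evaluate a cohort of predicted mask stacks against manual truth.

    ``predictions`` and ``ground_truth`` map (subject, chamber, phase) ->
    per-slice binary mask stack; ``spacing`` maps subject ->
    (pixel_spacing_mm, slice_thickness_mm).
    """
    missing = set(ground_truth) - set(predictions)
    if missing:
        raise KeyError(f"predictions missing for {sorted(missing)[:5]} ...")

    met_rows, vol_rows = [], []
    n_excluded = 0
    subjects = sorted({k[0] for k in ground_truth})
    chambers = sorted({k[1] for k in ground_truth})
    for subj in subjects:
        px, thick = spacing[subj]
        for ch in chambers:
            vols = {}
            for ph in ("ED", "ES"):
                key = (subj, ch, ph)
                if key not in ground_truth:
                    continue
                rec, excl = _phase_metrics(predictions[key], ground_truth[key], px)
                n_excluded += excl
                if rec:
                    met_rows.append({"subject": subj, "chamber": ch,
                                     "phase": ph, **rec})
                for src, stacks in (("predicted", predictions),
                                    ("manual", ground_truth)):
                    vols[(src, ph)] = chamber_volume(stacks[key], px, thick)
            if len(vols) == 4:
                for src in ("predicted", "manual"):
                    idx = clinical_indices(vols[(src, "ED")], vols[(src, "ES")])
                    vol_rows.append({
                        "subject": subj, "chamber": ch, "source": src,
                        "edv_ml": vols[(src, "ED")], "esv_ml": vols[(src, "ES")],
                        "sv_ml": idx["sv_ml"], "ef_pct": idx["ef_pct"]})

    metrics = pd.DataFrame(met_rows)
    volumetrics = pd.DataFrame(vol_rows)
    agreement = _agreement_table(volumetrics) if len(volumetrics) else pd.DataFrame()
    if len(volumetrics):
        volumetrics = _attach_differences(volumetrics)
    return CohortEvaluation(metrics=metrics, volumetrics=volumetrics,
                            agreement=agreement, n_excluded_slices=n_excluded)


_INDEX_COLS = {"EDV": "edv_ml", "ESV": "esv_ml", "SV": "sv_ml", "EF": "ef_pct"}


def _attach_differences(vol: pd.DataFrame) -> pd.DataFrame:
    """Per-subject absolute and relative differences vs the manual source."""
    wide = vol.pivot_table(index=["subject", "chamber"], columns="source",
                           values=list(_INDEX_COLS.values()), dropna=False)
    rows = []
    for (subj, ch), r in wide.iterrows():
        row = {"subject": subj, "chamber": ch}
        for name, col in _INDEX_COLS.items():
            pred, man = r[(col, "predicted")], r[(col, "manual")]
            row[f"{name.lower()}_abs_diff"] = abs(pred - man)
            row[f"{name.lower()}_rel_diff_pct"] = (
                100.0 * abs(pred - man) / abs(man) if man != 0 else np.nan)
        rows.append(row)
    diffs = pd.DataFrame(rows)
    return vol.merge(diffs, on=["subject", "chamber"])


def _agreement_table(vol: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for ch, grp in vol.groupby("chamber"):
        wide = grp.pivot_table(index="subject", columns="source",
                               values=list(_INDEX_COLS.values()), dropna=False)
        for name, col in _INDEX_COLS.items():
            pred = wide[(col, "predicted")].to_numpy()
            man = wide[(col, "manual")].to_numpy()
            keep = np.isfinite(pred) & np.isfinite(man)
            pred, man = pred[keep], man[keep]
            if len(pred) < 3:
                continue
            t = paired_t_test(pred, man)
            icc = fisher_icc(pred, man)
            ba = bland_altman(pred, man)
            try:
                r2 = r2_vol(pred, man)
            except ValueError:
                r2 = np.nan
            rows.append({
                "chamber": ch, "index": name, "n": len(pred),
                "t_p_value": t["p_value"], "t_passed": t["passed"],
                "icc": icc["icc"], "icc_category": icc["category"],
                "ba_bias": ba["bias"], "ba_loa_low": ba["loa_low"],
                "ba_loa_high": ba["loa_high"], "r2_pct": r2})
    return pd.DataFrame(rows)


def bland_altman_plot(pred_values, truth_values, path, label: str = "") -> None:
    """Write a Bland-Altman scatter with bias and 1.96-sd limit lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(pred_values, dtype=float)
    y = np.asarray(truth_values, dtype=float)
    ba = bland_altman(x, y)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((x + y) / 2, x - y, s=14)
    ax.axhline(ba["bias"], color="k")
    for v in (ba["loa_low"], ba["loa_high"]):
        ax.axhline(v, color="k", linestyle="--")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (pred - manual)")
    ax.set_title(label or "Bland-Altman")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
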