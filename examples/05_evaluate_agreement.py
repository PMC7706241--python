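"""Cohort evaluation: geometric metrics and volumetric agreement statistics.

Compares predicted mask stacks against manual truth on a small phantom
cohort.  With predictions equal to the truth every Dice is 100%, every
paired t-test passes (p > 0.05) and every ICC is excellent; eroding each
prediction by one pixel shows how the metrics and agreement respond to a
systematic under-segmentation.
"""

import numpy as np
from scipy import ndimage

from chdseg import PhantomConfig, generate_cohort
from chdseg.evaluation import evaluate_cohort

cohort = generate_cohort(6, 3, PhantomConfig(n_slices=4,
                                             apical_empty_slice=False))
truth, spacing = {}, {}
for st in cohort:
    spacing[st.study_id] = (st.pixel_spacing_mm, st.slice_thickness_mm)
    for key, m in st.masks.items():
        truth[(st.study_id, *key)] = m

for label, pred in (
        ("identity", truth),
        ("eroded 1px", {k: np.stack([ndimage.binary_erosion(s).astype(np.uint8)
                                     for s in v]) for k, v in truth.items()})):
    rep = evaluate_cohort(pred, truth, spacing)
    dice = rep.metrics.dice_pct.mean()
    row = rep.agreement[(rep.agreement.chamber == "LV")
                        & (rep.agreement["index"] == "EDV")].iloc[0]
    print(f"{label}: mean Dice {dice:.1f}%  LV EDV t-test p={row.t_p_value:.3f} "
          f"({'pass' if row.t_passed else 'fail'})  ICC {row.icc:.3f} "
          f"({row.icc_category})  bias {row.ba_bias:.1f} mL")
# Erosion lowers Dice and produces a negative volume bias; whether the
# t-test still "passes" depends on the bias-to-variability ratio.
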