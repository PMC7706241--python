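"""Generate a synthetic short-axis phantom study and report its ground-truth
chamber volumes.

The phantom renders a bright LV blood pool inside a darker myocardial ring
and a crescent-shaped RV on every slice, shrinks the end-systolic geometry
by a fixed factor, and tapers radii toward the apex.  Because masks are
rasterized before noise is added, the volumes below are exact ground truth.
"""

from chdseg import PhantomConfig, generate_study
from chdseg.evaluation import chamber_volume, clinical_indices

study = generate_study(PhantomConfig(seed=5))
print(f"study {study.study_id}: {study.images_ed.shape[0]} slices, "
      f"{study.pixel_spacing_mm} mm spacing, "
      f"{study.slice_thickness_mm} mm thickness")
for chamber in ("LV", "RV"):
    edv = chamber_volume(study.masks[(chamber, "ED")],
                         study.pixel_spacing_mm, study.slice_thickness_mm)
    esv = chamber_volume(study.masks[(chamber, "ES")],
                         study.pixel_spacing_mm, study.slice_thickness_mm)
    idx = clinical_indices(edv, esv)
    print(f"{chamber}: EDV {edv:.1f} mL  ESV {esv:.1f} mL  "
          f"SV {idx['sv_ml']:.1f} mL  EF {idx['ef_pct']:.1f}%")
# EF ~64% follows from the 0.6 end-systolic shrink factor (area ratio 0.36).
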