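"""Run the preprocessing chain and the three exact augmentation schemes.

Each source slice is center-cropped to 445 px, down-sampled to the network
input size and z-normalized; slices with an empty mask are dropped.  The
three rotation/flip schemes multiply pair counts by exactly 40 (classic
training augmentation), 76 (GAN pre-training) and 7 (accepted synthetic
pairs).
"""

from chdseg import PhantomConfig, PreprocessConfig, generate_study
from chdseg.augment import augment_pairs
from chdseg.preprocess import build_pairs

study = generate_study(PhantomConfig(seed=5))
pairs = build_pairs(study, PreprocessConfig(target_size=128))
print(f"{len(pairs)} pairs from {study.images_ed.shape[0]} slices "
      "(2 chambers x 2 phases, empty apical slice excluded)")

lv_ed = [p for p in pairs if p.chamber == "LV" and p.phase == "ED"]
for scheme in ("classic40", "gan76", "synth7"):
    out = augment_pairs(lv_ed[:2], scheme)
    print(f"{scheme}: 2 pairs -> {len(out)} augmented pairs")
# 2500 filter-accepted synthetic pairs would expand to 2500 x 7 = 17,500.
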