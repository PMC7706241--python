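"""Train a scaled-down two-channel DCGAN and filter its synthetic pairs.

The generator maps 100-d noise to a joint (image, soft mask) sample; the
quality filter quantizes the mask at 0.5, keeps mask-area fractions inside
the nearest-neighbour window (0.005-0.025) and drops fragmented masks
(largest/second-largest component < 20).  At 32x32 with 1,500 alternating
steps this takes a minute or two on a CPU; the full-scale recipe is the
same code at 128x128 for 40,000 iterations.
"""

from chdseg import PhantomConfig, PreprocessConfig, generate_cohort
from chdseg.augment import augment_pairs
from chdseg.gan import GanSpec, GanTrainConfig, sample_synthetic, train_dcgan
from chdseg.preprocess import build_pairs
from chdseg.synth_filter import FilterConfig, filter_pipeline

cohort = generate_cohort(4, 7, PhantomConfig(n_slices=5,
                                             apical_empty_slice=False))
pairs = [p for s in cohort
         for p in build_pairs(s, PreprocessConfig(target_size=32))
         if p.chamber == "LV"]
train_set = augment_pairs(pairs, "gan76")
print(f"{len(pairs)} real pairs -> {len(train_set)} after x76 pre-augmentation")

spec = GanSpec(out_size=32, gen_channels=(64, 32, 16),
               disc_channels=(16, 32, 64))
gen, disc, hist = train_dcgan(train_set, spec,
                              GanTrainConfig(iterations=1500, seed=3,
                                             checkpoint_every=500))
last = [h for h in hist if "d_loss" in h][-1]
print(f"after 1500 iterations: d_loss {last['d_loss']:.3f} "
      f"g_loss {last['g_loss']:.3f}")

samples = sample_synthetic(gen, 500, seed=11, spec=spec)
accepted, verdicts = filter_pipeline(samples, FilterConfig())
print(f"filter: {len(accepted)}/500 accepted "
      f"({100 * len(accepted) / 500:.0f}%)")
print(verdicts.rejection_reason.value_counts().to_string())
# Accepted pairs would be expanded x7 and merged into the training set (SAD).
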