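"""Overfit a small skip-architecture FCN on a handful of phantom slices.

A desk-scale version of the training recipe (SGD + Nesterov momentum,
lr 0.002, batch 5, negative soft-Dice loss): 300 epochs on 8 pairs at
32x32 should reach a training Dice well above 90%, demonstrating that the
learning stack can fit its own data.  Runs in well under a minute on a CPU.
"""

import warnings

import numpy as np

from chdseg import PhantomConfig, PreprocessConfig, generate_study
from chdseg.evaluation import overlap_metrics
from chdseg.models import (FcnSpec, TrainConfig, build_fcn, predict_mask,
                           train_segmenter)
from chdseg.preprocess import build_pairs

study = generate_study(PhantomConfig(seed=5))
pairs = [p for p in build_pairs(study, PreprocessConfig(target_size=32))
         if p.chamber == "LV"][:8]

model = build_fcn(FcnSpec(filters=(8, 8, 8, 8, 8), input_size=32,
                          dropout_rate=0.0, l2_coeff=0.0, seed=0))
print(f"FCN with {model.num_parameters()} parameters on {len(pairs)} pairs")
model, history = train_segmenter(model, pairs, None,
                                 TrainConfig(epochs=300, seed=0))
print(f"epoch 1 loss {history[0]['train_loss']:.3f} -> "
      f"epoch 300 loss {history[-1]['train_loss']:.3f}")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    dices = [overlap_metrics(predict_mask(model, p.image), p.mask)["dice_pct"]
             for p in pairs]
print(f"training-set Dice: {np.mean(dices):.1f}%  (loss -> -1 means perfect overlap)")
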