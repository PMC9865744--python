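"""Label a synthetic ensemble by probe distance and balance the classes.

Generates a small intermediate-dominated ensemble (as raw receptor MD
ensembles are), labels every frame from the probe-pair Cα distance
(active ≥ 14 Å, inactive ≤ 8.5 Å, intermediate between), then undersamples
to the minority class and splits 70/30 stratified.
"""

import numpy as np

from conformotif import (SplitSpec, SynthConfig, assemble_dataset,
                         class_imbalance_preset, generate, stratified_split,
                         undersample)
from conformotif.labeling import STATES

cfg = class_imbalance_preset(SynthConfig(n_trajectories=120, seed=0))
trajectories, _ = generate(cfg)
X, y, _ = assemble_dataset(trajectories)

counts = np.bincount(y, minlength=3)
print("raw label distribution (frames):")
for state, count in zip(STATES, counts):
    print(f"  {state:>12}: {count:5d}  ({100 * count / len(y):5.2f}%)")

kept = undersample(y, seed=0)
train_idx, val_idx = stratified_split(kept, y, SplitSpec(0.7, 0))
print(f"\nafter undersampling to the minority class: {len(kept)} frames")
print(f"train counts: {np.bincount(y[train_idx], minlength=3).tolist()}  "
      f"val counts: {np.bincount(y[val_idx], minlength=3).tolist()}")
print("(equal per-class counts in both splits: the balanced-split contract)")
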