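"""Explain single predictions with layer-wise relevance propagation.

Seeds the output layer with the explained class's raw logit and propagates
relevance back to the 3M input coordinates with the ε rule.  Also shows the
conservation diagnostic: per-layer relevance sums and the relevance absorbed
by biases and the ε stabilizer.
"""

import numpy as np

from conformotif import (LRPConfig, NetworkSpec, SplitSpec, SynthConfig,
                         TrainConfig, assemble_dataset, build_network,
                         conservation_report, explain, fit_minmax, generate,
                         residue_relevance, stratified_split, train,
                         undersample)
from conformotif.labeling import STATES

cfg = SynthConfig(n_trajectories=100, frames_per_trajectory=20, seed=2)
trajectories, planted = generate(cfg)
X, y, _ = assemble_dataset(trajectories)
kept = undersample(y, seed=2)
train_idx, _ = stratified_split(kept, y, SplitSpec(0.7, 2))
scaler = fit_minmax(X[train_idx])
model = build_network(NetworkSpec(input_length=X.shape[1], blocks=(16,),
                                  fc_sizes=(64, 3)), seed=2)
train(model, scaler.transform(X[train_idx]), y[train_idx],
      TrainConfig(epochs=30, batch_size=256, learning_rate=1e-3, seed=2))

frame_idx = int(train_idx[0])
x = scaler.transform(X[frame_idx])[0]
true_state = STATES[y[frame_idx]]
result = explain(model, x, y[frame_idx], LRPConfig(rule="lrp_epsilon",
                                                   epsilon=0.01))
print(f"frame {frame_idx}: true state {true_state}, "
      f"logits {np.round(result.logits, 3)}")
print(f"explained logit (relevance seed): {result.seed:.4f}")

per_residue = residue_relevance(result.input_relevance, cfg.n_residues)
top = np.argsort(-np.abs(per_residue))[:8] + 1
print(f"top residues by |relevance|: {top.tolist()}")
print(f"planted state-discriminative residues: {planted}")

print("\nper-layer relevance sums (conservation diagnostic):")
print(conservation_report(result).to_string(index=False))
print("(deficits come from bias absorption and the ε stabilizer; for a "
      "bias-free network under the basic rule every deficit is zero)")
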