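"""Motif tables and region summaries from averaged relevance maps.

Explains correctly predicted frames (equal numbers per state) sampled from
randomly chosen trajectories, averages the per-residue relevance per state,
flags residues outside the Tukey IQR fences as motifs, and totals relevance
per receptor region.
"""

import numpy as np

from conformotif import (LRPConfig, NetworkSpec, SplitSpec, SynthConfig,
                         TrainConfig, assemble_dataset, average_maps,
                         build_network, fit_minmax, generate, iqr_motifs,
                         region_summary, select_explanation_frames,
                         stratified_split, train, undersample)
from conformotif.analysis import explain_frames
from conformotif.labeling import STATES
from conformotif.trajectory import synthetic_region_annotations

cfg = SynthConfig(seed=7)   # the committed fixture conditions
trajectories, planted = generate(cfg)
X, y, _ = assemble_dataset(trajectories)
kept = undersample(y, seed=7)
train_idx, val_idx = stratified_split(kept, y, SplitSpec(0.7, 7))
scaler = fit_minmax(X[train_idx])
model = build_network(NetworkSpec(input_length=X.shape[1], blocks=(32,),
                                  fc_sizes=(64, 3)), seed=7)
train(model, scaler.transform(X[train_idx]), y[train_idx],
      TrainConfig(epochs=50, batch_size=256, learning_rate=1e-3, seed=7))

annotations = synthetic_region_annotations(cfg.n_residues)
frames = select_explanation_frames(model, trajectories, scaler,
                                   n_traj=100, per_state=100, seed=7)
per_frame = explain_frames(model, trajectories, scaler, frames,
                           LRPConfig(epsilon=0.01))

print(f"planted residues: {planted}\n")
for c, stack in sorted(per_frame.items()):
    rel_map = average_maps(stack, c)
    motifs = iqr_motifs(rel_map, annotations)
    print(f"--- {STATES[c]} ({rel_map.n_frames} frames) ---")
    print("motif residues outside the IQR fences:")
    print(motifs.to_string(index=False) if len(motifs) else "  (none)")
    summary = region_summary(stack, annotations)
    strongest = summary.iloc[summary["total"].abs().idxmax()]
    print(f"strongest-contributing region: {strongest['region']} "
          f"(total {strongest['total']:.3f}, average {strongest['average']:.5f})\n")
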