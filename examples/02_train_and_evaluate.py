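"""Train the block-structured 1D-CNN on a synthetic ensemble and evaluate.

The network sees each frame as a flattened, min–max-normalized vector of
residue center-of-mass coordinates (length 3M).  A reduced two-layer-block
variant is used here so the example runs in seconds; the receptor-scale
default (blocks 64/128/256/512, FC 1024, input 846) is NetworkSpec().
"""

from conformotif import (NetworkSpec, SplitSpec, SynthConfig, TrainConfig,
                         assemble_dataset, build_network, evaluate, fit_minmax,
                         generate, parameter_count, stratified_split, train,
                         undersample)

# the receptor-scale default, for reference
per_layer, total = parameter_count(NetworkSpec())
print("receptor-scale default architecture parameter counts:")
for layer, n in per_layer.items():
    print(f"  {layer:>9}: {n:>12,}")
print(f"  {'total':>9}: {total:>12,}\n")

cfg = SynthConfig(n_trajectories=100, frames_per_trajectory=20, seed=1)
trajectories, _ = generate(cfg)
X, y, _ = assemble_dataset(trajectories)
kept = undersample(y, seed=1)
train_idx, val_idx = stratified_split(kept, y, SplitSpec(0.7, 1))
scaler = fit_minmax(X[train_idx])

model = build_network(NetworkSpec(input_length=X.shape[1], blocks=(16,),
                                  fc_sizes=(64, 3)), seed=1)
train(model, scaler.transform(X[train_idx]), y[train_idx],
      TrainConfig(epochs=30, batch_size=256, learning_rate=1e-3, seed=1))

report = evaluate(model, scaler.transform(X[val_idx]), y[val_idx])
print(report.to_frame().to_string(index=False))
print("\nrow-normalized confusion matrix (rows: true state):")
print(report.confusion_normalized.round(3))
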