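# Methods

## Problem and model

The package classifies MD trajectory frames of a receptor into three
conformational states and explains the classifier's decisions at residue
resolution. The state of a frame is *defined* by one geometric criterion —
the Cα–Cα distance between a probe residue pair bridging two helices — with
inclusive outer thresholds (active ≥ `high`, inactive ≤ `low`, intermediate
strictly between). The defaults (pair 131/272, 8.5 Å, 14 Å) are the β2AR
convention; both pair and thresholds are configurable so other receptors can
be analyzed. The three predicates partition [0, ∞): every distance yields
exactly one state, and states are ordered inactive → intermediate → active
as the distance grows.

The classifier never sees the probe distance. It sees only the flattened
per-residue center-of-mass coordinates (length 3M, residue-major, so residue
*i* always owns features 3i−3…3i−1), min–max normalized per feature.
Normalization parameters are fitted on the training split only and applied
unclipped to validation data; clipping would break the linear relationship
between input and relevance that the attribution analysis relies on.
Whether to normalize before or after splitting is genuinely open; fitting on
the training split only is this package's contract, since it is the only
choice that keeps the validation set untouched.

## Class imbalance and splitting

Raw ensembles dwell overwhelmingly in the intermediate band, so frames are
randomly under-sampled to the minority class before splitting. Both
operations carry exact count contracts: undersampling keeps exactly
`min(class counts)` frames per class; the stratified split assigns
`round(fraction × class count)` per class to training. Undersample-first
(rather than split-first) is the only order that guarantees equal per-class
counts in *both* subsets. All randomness flows through explicitly threaded
`numpy` generators — no global RNG state anywhere in the package.

## Network and training

The architecture is a ladder of blocks `Conv1d(k=3, s=1, p=0) → ReLU →
MaxPool1d(w=2)` with channel counts 64/128/256/512 at receptor scale,
followed by `Flatten → Linear(1024) → ReLU → Dropout(0.5) → Linear(3)`.
Dropout sits after the ReLU of the first linear layer (the summary-table
order) and only there. Class indices are fixed as active=0, intermediate=1,
inactive=2 throughout. Shape arithmetic (`conv_output_length`,
`pool_output_length`, `parameter_count`) is exposed separately from the
built network and property-tested to agree with actual forward passes; a
spec whose signal shrinks below the kernel length refuses to build.

Training is cross-entropy with Adam (β₁=0.9, β₂=0.999), L2 weight decay
added to the gradient, Kaiming-uniform initialization
(U(±√(6/fan_in)), zero biases), per-epoch reshuffling reseeded from the
master seed, and dropout masks drawn from a dedicated generator.
Determinism is best-effort: seeds fix initialization, shuffling and dropout;
bit-reproducibility across BLAS builds is not promised. The receptor-scale
protocol (500 epochs, batch 1024, lr 1e-4, wd 1e-5) is the default
`TrainConfig`; small synthetic systems use explicitly reduced settings (see
below). The network is implemented on NumPy so the relevance engine can
operate directly on stored weights and recorded activations; the same
backward machinery provides the gradient×input oracle used in testing, and
it is itself validated against central finite differences.

## Relevance propagation

The engine implements the basic rule and the ε rule only. Conventions:

- **Seeding.** The output relevance vector is the explained class's *raw
  logit* at its index and zero elsewhere (the logit, not a one-hot, is the
  quantity the explanation decomposes).
- **Bias handling.** The bias participates in the denominator z_k but its
  relevance share is absorbed, not propagated. Conservation of the
  per-layer relevance sum is therefore exact only for bias-free networks
  under ε=0 — the conservation report quantifies the absorbed relevance per
  layer in the general case.
- **Stabilizer.** ε is applied sign-matched, ε·sign(z) with sign(0)=+1, so
  near-zero denominators are damped without flipping the sign of any share.
  Default ε=1e-2, configurable; no result in the package depends on a
  specific ε. An exact zero denominator under the basic rule raises an
  error directing the user to the ε rule (0/0 with zero upstream relevance
  is defined as a zero share, so a zero input vector yields zero relevance
  everywhere).
- **Pooling.** Winner-takes-all onto the recorded forward maxima, ties
  split equally; conserves the sum exactly. ReLU and dropout (inference
  mode) pass relevance through unchanged.
- **Convolution.** The dense rule under weight sharing; it is tested to be
  numerically identical to dense propagation on the explicitly unrolled
  convolution matrix, and basic-rule relevance on bias-free ReLU networks is
  tested elementwise against gradient×input.

## Aggregation, motifs, regions

Input relevance is collapsed per residue as the mean of its three coordinate
relevances (total conserved up to the 1/3 factor). Per-class maps average
over correctly predicted frames, sampled in equal numbers per state from
randomly chosen trajectories; each frame is explained with respect to its
own (correct) class. The per-state frame count is a config choice; larger
counts suppress background relevance roughly as 1/√n.

Motifs are residues outside `Q1 − f·IQR, Q3 + f·IQR` with the Tukey default
f=1.5 (configurable) and quartiles by linear interpolation between order
statistics, so motif sets are bit-reproducible. An all-equal map yields an
empty table (exceedance is strict). Region summaries report per region the
total relevance over all selected frames and the average per residue per
frame (total / (residue count × frame count)); totals are additive across
any region partition. The default β2AR annotation is a programmatic,
explicitly synthetic reconstruction (282 positions over author numbering
29–342 with the ICL3 span 231–262 absent, Ballesteros–Weinstein labels from
the canonical x.50 anchors); it reproduces all published residue/region
pairs used in tests and is user-replaceable.

## Synthetic ensembles

The generator emulates what the pipeline assumes about real ensembles —
many short parallel trajectories, a state-determining probe distance, and
state-dependent residue displacements — and nothing more (no force field, no
solvent, no thermodynamics). Design choices:

- The probe distance follows a **reflected bounded random walk** (simplest
  process with controllable dwell times in all three bands); bounds must
  straddle both thresholds or generation refuses. Labels always come from
  the labeling module applied to the actual Cα–Cα distance.
- Planted residues are displaced by δ along a fixed random unit vector per
  (residue, state); all residues get isotropic Gaussian noise σ. The base
  structure is a 3.8 Å-step random chain, giving protein-like coordinate
  ranges.
- Probe residues carry explicit Cα atoms (exercising the atom-level
  labeling path), but their center-of-mass features do **not** track the
  probe geometry. Otherwise the features would encode the label
  deterministically through the probe residues, the δ=0 chance-level
  contract would be false, and probe residues would crowd planted residues
  out of the relevance ranking.
- Fixture defaults: M=60, 6 planted residues, δ=2.5 Å over σ=0.5 Å
  (δ/σ=5, a clearly resolvable signal), 200 trajectories × 30 frames, walk
  step 1 Å in bounds 5–17 Å (populating all three bands). The
  imbalance preset (start 10.5 Å, step 0.3 Å, bounds 8.3–14.2 Å) dwells
  between the thresholds, reproducing the strongly intermediate-dominated
  composition of real ensembles.

What passing on synthetic data does *not* show: robustness to correlated
residue motions, slow conformational drift, anharmonic noise, or
imperfectly separable states — real trajectories have all of these, and the
planted-signal construction has none.

## Reduced protocol for the committed fixture

End-to-end tests train on the fixture with a deliberately small network —
one block of 32 filters, FC 64, dropout 0.5 — for 50 epochs at lr 1e-3,
batch 256. Two reasons. First, a 50-epoch run at the receptor-scale
lr=1e-4 would be undertrained by construction; the higher rate is the
appropriate counterpart of the shorter schedule. Second, attribution
granularity: each pooling stage doubles the input span a single deep unit
covers, smearing relevance onto residues adjacent to the truly informative
ones. With single-residue planted signals, one conv/pool stage is the depth
that keeps attributions residue-sharp while still classifying essentially
perfectly — mirroring the general observation that deeper block ladders
stop paying once the feature vector gets short. Explanation averaging uses
100 trajectories and 100 correctly predicted frames per state.

## Numerical conventions and edge cases

- Canonical tables store coordinates in Å at fixed 6-decimal precision;
  round-trips are bit-identical at that precision. Residue indices are
  1-based everywhere.
- Min–max scaling of a constant feature maps it to 0 (no division error).
- Argmax ties in prediction break toward the lowest class index.
- Macro-F1 is the unweighted arithmetic mean of per-class F1 scores;
  accuracy is the trace of the unnormalized confusion matrix over its total;
  confusion-matrix rows are normalized by true-class support.
- `parameter_count` treats per-layer counts as ground truth (conv:
  out·in·k + out; linear: out·in + out) and is tested to equal the number
  of trainable scalars in the built network.

## Known limitations

- Training determinism across platforms/BLAS builds is best-effort.
- Only the basic and ε propagation rules are implemented (no αβ, γ, or
  flat input-layer rules).
- The standard-format adapter (`ingest`) is a thin optional MDAnalysis
  wrapper: no periodic-boundary unwrapping, no trajectory alignment, and it
  falls back to a center-of-mass distance (flagged approximate) when Cα
  atoms are absent.
- Motif extraction treats residues independently; contiguous-motif
  clustering is out of scope.
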