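# conformotif

Interpretable conformational-state analysis of molecular-dynamics (MD)
trajectory ensembles for G-protein-coupled receptors (GPCRs) and similar
systems: a 1-D convolutional network classifies each frame as **active**,
**intermediate**, or **inactive**, and **layer-wise relevance propagation
(LRP)** attributes every prediction back to individual residues and receptor
regions, ending in tables of key residues ("motifs") and region-level
relevance summaries.

It is aimed at structural bioinformaticians who have large ensembles of short
MD trajectories (e.g. the β2-adrenergic receptor bound to a full agonist,
simulated from the inactive 2RH1 structure) and want to know *which parts of
the protein* a state classifier is looking at.

## The method

**Labeling.** Each frame is assigned a state from the Cα–Cα distance *d*
between a probe residue pair (for β2AR: R131³·⁵⁰ on helix 3 and L272⁶·³⁴ on
helix 6): active if *d* ≥ 14 Å, inactive if *d* ≤ 8.5 Å, intermediate
otherwise.

**Featurization.** The 3-D position of each of the M residues is its
center of mass; a frame becomes a residue-major vector of length 3M
(846 for the 282-residue β2AR construct), min–max normalized per feature
on the training split.

**Classifier.** Blocks of `Conv1d(kernel 3, stride 1, no padding) → ReLU →
MaxPool1d(window 2)` with 64/128/256/512 filters, then FC 1024 (ReLU,
dropout 0.5) → 3 logits. Trained with cross-entropy, Adam (lr 1e-4, weight
decay 1e-5), batches of 1024, 500 epochs, Kaiming-uniform init. The raw
ensembles are heavily intermediate-dominated, so frames are randomly
under-sampled to the minority class and split 70/30 stratified first.
The network is implemented directly on NumPy so that every layer's weights
and activations are exposed to the relevance engine.

**Attribution.** The explained class's raw logit seeds the output relevance,
which is redistributed backwards layer by layer. For lower neuron *j* and
upper neuron *k*:

```
basic rule:  R_j = Σ_k  a_j w_jk / z_k · R_k ,   z_k = Σ_{0,j} a_j w_jk
ε rule:      R_j = Σ_k  a_j w_jk / (ε·sign(z_k) + z_k) · R_k
```

Max-pooling redistributes winner-takes-all onto the recorded maxima; ReLU
and dropout pass relevance through. Input relevance is collapsed to one
value per residue (mean over x, y, z) and averaged over correctly predicted
frames sampled in equal numbers per state from randomly chosen trajectories.
Residues outside the Tukey fences `Q1 − 1.5·IQR, Q3 + 1.5·IQR` of a class's
average map form that state's **motif table**; summing relevance inside each
annotated region (helices H1–H7, loops ICL1–3/ECL1–3, termini) gives the
**region summary**.

A synthetic-ensemble generator (`conformotif.synthetic`) produces labeled
multi-trajectory ensembles with *planted* state-discriminative residues, so
the whole pipeline — including motif recovery — is testable without external
data.

## Worked example

`examples/` holds one short script per capability. For instance, motif
extraction on a synthetic ensemble with planted residues
(`python examples/04_motifs_and_regions.py`; M=60, planted residues
5, 12, 23, 34, 41, 55, δ/σ = 5, 200 trajectories × 30 frames):

```
--- active (100 frames) ---
motif residues outside the IQR fences:
residue     region  avg_relevance        side
   UNK4 N-terminus      -0.168621 below-lower
   UNK5         H1       0.769374 above-upper
  UNK12       ICL1       0.907913 above-upper
  UNK23         H3       0.187502 above-upper
  UNK33       ECL2      -0.178894 below-lower
  UNK34       ECL2       1.316260 above-upper
  UNK41       ICL3       0.834117 above-upper
  UNK55         H7       0.832255 above-upper
strongest-contributing region: ECL2 (total 100.361, average 0.25090)
```

All six planted residues are flagged (positive relevance: their positions
*support* the active-state prediction; negative rows counteract it), with a
couple of neighbor/noise residues at much smaller magnitude — the expected
behavior of attribution on a convolutional model. The full pipeline is one
call (`conformotif run --out-dir out --seed 7`, or
`conformotif.run_pipeline(...)` from Python) and writes the model
checkpoint, classification report, per-class relevance maps, motif and
region tables, figures, and a provenance manifest.

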