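"""End-to-end orchestration: generate/load → label → featurize → split →
train → evaluate → explain → motifs/regions, with one master seed.

Every stage communicates through the documented file formats, so any stage
can be re-run in isolation from persisted intermediates.  The master seed
deterministically derives one sub-seed per stochastic stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .analysis import (average_maps, explain_frames, iqr_motifs, region_summary,
                       render_outputs, select_explanation_frames)
from .dataset import SplitSpec, stratified_split, undersample
from .featurize import assemble_dataset, fit_minmax
from .labeling import STATES, LabelingConfig
from .lrp import LRPConfig
from .network import NetworkSpec, TrainConfig, build_network, evaluate, train
from .synthetic import SynthConfig, generate
from .trajectory import (Trajectory, read_com_table, save_annotations,
                         synthetic_region_annotations, write_com_table)

log = logging.getLogger("conformotif")


@dataclass
class PipelineConfig:
    """All stage configurations plus the master seed."""

    synth: SynthConfig | None = field(default_factory=SynthConfig)
    input_tables: list[str] = field(default_factory=list)  # used when synth is None
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    network: NetworkSpec = field(default_factory=NetworkSpec)
    training: TrainConfig = field(default_factory=TrainConfig)
    lrp: LRPConfig = field(default_factory=LRPConfig)
    n_traj: int = 100
    per_state: int = 10
    fence_factor: float = 1.5
    seed: int = 0

    def stage_seeds(self) -> dict[str, int]:
        rng = np.random.default_rng(self.seed)
        return {name: int(rng.integers(2**31))
                for name in ("synth", "undersample", "split", "train", "select")}


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> Path:
    """Run the full workflow; returns the artifact directory.

    Artifacts: model checkpoint, classification report, per-class relevance
    maps, motif and region tables, figures, and a provenance manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = cfg.stage_seeds()
    timings: dict[str, float] = {}

    def stage(name):
        log.info("stage %s (seed %s)", name, seeds.get(name, "-"))
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    # -- data -------------------------------------------------------------
    stage("synth")
    if cfg.synth is not None:
        synth_cfg = SynthConfig(**{**cfg.synth.__dict__, "seed": seeds["synth"]})
        trajectories, planted = generate(synth_cfg, cfg.labeling)
        annotations = synthetic_region_annotations(synth_cfg.n_residues)
        (out_dir / "ground_truth.json").write_text(
            json.dumps({"planted_residues": planted}))
    else:
        if not cfg.input_tables:
            raise FileNotFoundError("no input tables configured and synthesis disabled")
        missing = [p for p in cfg.input_tables if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"input tables not found: {missing}")
        trajectories = [read_com_table(p) for p in cfg.input_tables]
        annotations = synthetic_region_annotations(trajectories[0].n_residues)
    save_annotations(annotations, out_dir / "annotations.csv")
    done("synth")

    # -- featurize / balance / split --------------------------------------
    stage("split")
    X, y, _ = assemble_dataset(trajectories)
    kept = undersample(y, seed=seeds["undersample"])
    train_idx, val_idx = stratified_split(
        kept, y, SplitSpec(cfg.split.train_fraction, seeds["split"]))
    scaler = fit_minmax(X[train_idx])
    scaler.to_json(out_dir / "scaler.json")
    done("split")

    # -- train / evaluate --------------------------------------------------
    stage("train")
    spec = NetworkSpec(**{**cfg.network.__dict__, "input_length": X.shape[1]})
    model = build_network(spec, seed=seeds["train"])
    train_cfg = TrainConfig(**{**cfg.training.__dict__, "seed": seeds["train"]})
    train(model, scaler.transform(X[train_idx]), y[train_idx], train_cfg)
    model.save(out_dir / "model.npz")
    report = evaluate(model, scaler.transform(X[val_idx]), y[val_idx])
    report.to_frame().to_csv(out_dir / "classification_report.csv", index=False)
    done("train")
    log.info("validation accuracy %.4f, macro-F1 %.4f", report.accuracy, report.macro_f1)

    # -- explain / aggregate ----------------------------------------------
    stage("select")
    frames = select_explanation_frames(model, trajectories, scaler,
                                       n_traj=min(cfg.n_traj, len(trajectories)),
                                       per_state=cfg.per_state, seed=seeds["select"])
    per_frame = explain_frames(model, trajectories, scaler, frames, cfg.lrp)
    maps = {c: average_maps(stack, c) for c, stack in per_frame.items()}
    motifs = {c: iqr_motifs(maps[c], annotations, cfg.fence_factor) for c in maps}
    summaries = {c: region_summary(per_frame[c], annotations) for c in per_frame}
    render_outputs(maps, per_frame, motifs, summaries, annotations, out_dir,
                   eval_report=report)
    done("select")

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "n_trajectories": len(trajectories),
        "n_frames_total": int(len(y)),
        "n_balanced": int(len(kept)),
        "validation_accuracy": report.accuracy,
        "macro_f1": report.macro_f1,
        "states": list(STATES),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out_dir
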