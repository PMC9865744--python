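"""Residue- and region-level relevance aggregation and motif extraction.

Input-layer relevance (length 3M) is collapsed to one value per residue by
averaging the three coordinate relevances of its center of mass.  Per-class
relevance maps are averages over correctly predicted frames sampled in equal
numbers per conformational state from randomly chosen trajectories.  Key
residues ("motifs") are those whose average relevance falls outside the
Tukey fences Q1 − f·IQR, Q3 + f·IQR (quartiles by linear interpolation);
region summaries report each region's total and per-residue-per-frame
average relevance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .featurize import MinMaxScaler, flatten_frame
from .labeling import STATES
from .lrp import LRPConfig, explain
from .network import Network, predict
from .trajectory import ResidueAnnotation, Trajectory


class AnalysisError(ValueError):
    pass


def residue_relevance(input_relevance: np.ndarray, n_residues: int) -> np.ndarray:
    """Collapse a length-3M relevance vector to per-residue values.

    Residue i's relevance is the mean of its x, y, z coordinate relevances,
    so the residue total conserves the input total up to the 1/3 factor.
    """
    r = np.asarray(input_relevance, dtype=float)
    if r.ndim != 1 or r.size != 3 * n_residues:
        raise AnalysisError(
            f"relevance length {r.size} is not 3×{n_residues}"
        )
    return r.reshape(n_residues, 3).mean(axis=1)


@dataclass
class FrameRef:
    """One explained frame: where it lives and its (correct) class."""

    traj_id: str
    traj_pos: int     # position in the trajectory list
    frame_pos: int    # position within the trajectory
    class_idx: int


def select_explanation_frames(model: Network, trajectories: Sequence[Trajectory],
                              scaler: MinMaxScaler, n_traj: int = 100,
                              per_state: int = 10, seed: int = 0) -> list[FrameRef]:
    """Sample correctly predicted frames, in equal numbers per state.

    ``n_traj`` trajectories are drawn without replacement; among their frames
    the model's predictions are compared with the stored labels, and exactly
    ``per_state`` correct frames per class are drawn.  Deterministic given
    the seed; raises naming the class and shortfall when a class lacks
    enough correctly predicted frames.
    """
    if n_traj > len(trajectories):
        raise AnalysisError(
            f"asked for {n_traj} trajectories but only {len(trajectories)} available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(trajectories), size=n_traj, replace=False)
    candidates: dict[int, list[FrameRef]] = {c: [] for c in range(len(STATES))}
    for t in chosen:
        traj = trajectories[t]
        X = np.array([flatten_frame(f.com) for f in traj.frames])
        _, y_hat = predict(model, scaler.transform(X))
        for k, frame in enumerate(traj.frames):
            if frame.label is None:
                raise AnalysisError(f"unlabeled frame in trajectory {traj.id!r}")
            c = frame.label.index
            if y_hat[k] == c:
                candidates[c].append(FrameRef(traj.id, int(t), k, c))
    selected: list[FrameRef] = []
    for c in range(len(STATES)):
        pool = candidates[c]
        if len(pool) < per_state:
            raise AnalysisError(
                f"class {STATES[c]!r}: only {len(pool)} correctly predicted frames "
                f"available, {per_state} requested (short by {per_state - len(pool)})"
            )
        picks = rng.choice(len(pool), size=per_state, replace=False)
        selected.extend(pool[int(p)] for p in picks)
    return selected


def explain_frames(model: Network, trajectories: Sequence[Trajectory],
                   scaler: MinMaxScaler, frames: Sequence[FrameRef],
                   cfg: LRPConfig | None = None) -> dict[int, np.ndarray]:
    """Per-class stacks of per-frame residue relevance maps.

    Each frame is explained with respect to its own (correctly predicted)
    class.  Returns ``{class index: (n_frames, M) array}``.
    """
    cfg = cfg or LRPConfig()
    stacks: dict[int, list[np.ndarray]] = {c: [] for c in range(len(STATES))}
    for ref in frames:
        traj = trajectories[ref.traj_pos]
        m = traj.n_residues
        x = scaler.transform(flatten_frame(traj.frames[ref.frame_pos].com))[0]
        result = explain(model, x, ref.class_idx, cfg)
        stacks[ref.class_idx].append(residue_relevance(result.input_relevance, m))
    return {c: np.array(v) for c, v in stacks.items() if v}


@dataclass
class RelevanceMap:
    """Average per-residue relevance for one explained class."""

    class_idx: int
    values: np.ndarray  # length M
    n_frames: int

    @property
    def state(self) -> str:
        return STATES[self.class_idx]


def average_maps(per_frame_maps: np.ndarray, class_idx: int = 0) -> RelevanceMap:
    """Elementwise mean over a (n_frames, M) stack of residue maps."""
    maps = np.atleast_2d(np.asarray(per_frame_maps, dtype=float))
    if maps.size == 0:
        raise AnalysisError("cannot average an empty set of relevance maps")
    return RelevanceMap(class_idx=class_idx, values=maps.mean(axis=0),
                        n_frames=maps.shape[0])


def iqr_motifs(relevance_map: RelevanceMap | np.ndarray,
               annotations: Sequence[ResidueAnnotation],
               fence_factor: float = 1.5) -> pd.DataFrame:
    """Residues whose average relevance falls outside the IQR fences.

    Fences are Q1 − f·IQR and Q3 + f·IQR with quartiles computed by linear
    interpolation between order statistics.  Rows (residue, region,
    avg_relevance, side) are sorted by residue index; an all-equal map
    yields an empty table (exceedance is strict).
    """
    if fence_factor < 0:
        raise AnalysisError("fence factor must be nonnegative")
    values = relevance_map.values if isinstance(relevance_map, RelevanceMap) \
        else np.asarray(relevance_map, dtype=float)
    if values.size < 4:
        raise AnalysisError("need at least 4 residues to form quartiles")
    if len(annotations) != values.size:
        raise AnalysisError(
            f"{len(annotations)} annotations for {values.size} residues"
        )
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    lower, upper = q1 - fence_factor * iqr, q3 + fence_factor * iqr
    rows = []
    for ann, value in zip(annotations, values):
        if value > upper or value < lower:
            rows.append({
                "residue": ann.name,
                "region": ann.region,
                "avg_relevance": value,
                "side": "above-upper" if value > upper else "below-lower",
            })
    return pd.DataFrame(rows, columns=["residue", "region", "avg_relevance", "side"])


def region_summary(per_frame_maps: np.ndarray,
                   annotations: Sequence[ResidueAnnotation]) -> pd.DataFrame:
    """Total and average relevance per region over the selected frames.

    ``total`` sums relevance over the region's residues across all frames;
    ``average`` divides by (region residue count × frame count).  Region
    totals sum to the grand total over all residues and frames.
    """
    maps = np.atleast_2d(np.asarray(per_frame_maps, dtype=float))
    n_frames, m = maps.shape
    if len(annotations) != m:
        raise AnalysisError(f"{len(annotations)} annotations for {m} residues")
    regions = np.array([a.region for a in annotations])
    rows = []
    for region in sorted(set(regions)):
        mask = regions == region
        total = float(maps[:, mask].sum())
        rows.append({
            "region": region,
            "total": total,
            "average": total / (int(mask.sum()) * n_frames),
            "n_residues": int(mask.sum()),
        })
    return pd.DataFrame(rows, columns=["region", "total", "average", "n_residues"])


# ---------------------------------------------------------------------------
# Output rendering
# ---------------------------------------------------------------------------

def render_outputs(maps: dict[int, RelevanceMap],
                   per_frame: dict[int, np.ndarray],
                   motifs: dict[int, pd.DataFrame],
                   summaries: dict[int, pd.DataFrame],
                   annotations: Sequence[ResidueAnnotation],
                   out_dir: str | Path,
                   eval_report=None) -> list[Path]:
    """Write relevance-map plots, histograms, region box plots, the confusion
    heatmap, and CSV twins of every table into ``out_dir``."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    regions = [a.region for a in annotations]
    unique_regions = list(dict.fromkeys(regions))
    cmap = plt.get_cmap("tab20")
    region_color = {reg: cmap(i % 20) for i, reg in enumerate(unique_regions)}

    for c, rel_map in maps.items():
        state = STATES[c]
        # region-colored relevance map
        fig, ax = plt.subplots(figsize=(9, 3))
        ax.bar(np.arange(1, rel_map.values.size + 1), rel_map.values,
               color=[region_color[r] for r in regions], width=1.0)
        ax.set_xlabel("residue index")
        ax.set_ylabel("avg relevance")
        ax.set_title(f"average residue relevance — {state}")
        path = out_dir / f"relevance_map_{state}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

        fig, ax = plt.subplots(figsize=(4, 3))
        ax.hist(rel_map.values, bins=40)
        ax.set_xlabel("avg relevance")
        ax.set_title(f"relevance distribution — {state}")
        path = out_dir / f"relevance_hist_{state}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

        csv = out_dir / f"relevance_{state}.csv"
        pd.DataFrame({
            "res_index": np.arange(1, rel_map.values.size + 1),
            "residue": [a.name for a in annotations],
            "region": regions,
            "avg_relevance": rel_map.values,
        }).to_csv(csv, index=False)
        written.append(csv)

        if c in per_frame:
            fig, ax = plt.subplots(figsize=(7, 3.5))
            data = [per_frame[c][:, [i for i, r in enumerate(regions) if r == reg]].ravel()
                    for reg in unique_regions]
            ax.boxplot(data, tick_labels=unique_regions, showmeans=True)
            ax.set_ylabel("relevance")
            ax.set_title(f"per-region relevance — {state}")
            ax.tick_params(axis="x", rotation=60)
            path = out_dir / f"region_boxplot_{state}.png"
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append(path)

        motifs[c].to_csv(out_dir / f"motifs_{state}.csv", index=False)
        summaries[c].to_csv(out_dir / f"regions_{state}.csv", index=False)
        written += [out_dir / f"motifs_{state}.csv", out_dir / f"regions_{state}.csv"]

    if eval_report is not None:
        fig, ax = plt.subplots(figsize=(4, 3.5))
        im = ax.imshow(eval_report.confusion_normalized, vmin=0, vmax=1, cmap="Blues")
        ax.set_xticks(range(len(STATES)), STATES)
        ax.set_yticks(range(len(STATES)), STATES)
        for i in range(len(STATES)):
            for j in range(len(STATES)):
                ax.text(j, i, f"{eval_report.confusion_normalized[i, j]:.2f}",
                        ha="center", va="center")
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        fig.colorbar(im)
        path = out_dir / "confusion_matrix.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
        csv = out_dir / "confusion_matrix.csv"
        pd.DataFrame(eval_report.confusion_normalized,
                     index=STATES, columns=STATES).to_csv(csv)
        written.append(csv)
        eval_report.to_frame().to_csv(out_dir / "classification_report.csv", index=False)
        written.append(out_dir / "classification_report.csv")
    return written
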