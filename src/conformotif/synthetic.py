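"""Synthetic labeled trajectory ensembles with planted discriminative residues.

The generator emulates the statistical structure the pipeline assumes about
receptor ensembles — many short parallel trajectories, a state-determining
probe-pair Cα distance, and residues whose position depends on the
conformational state — without any claim of physical realism.

Per trajectory, the probe distance follows a reflected bounded random walk
whose bounds straddle both labeling thresholds so all three states occur;
each frame's label is obtained by running the labeling module on the actual
Cα–Cα Euclidean distance (the generator never bypasses the labeling rule).
Planted residues' centers of mass are displaced from their base position by
a fixed per-(residue, state) unit direction scaled by δ; every residue also
receives isotropic Gaussian noise of scale σ.  Probe residues carry explicit
Cα atoms so the atom-level labeling path is exercised; their center-of-mass
features deliberately do not track the probe geometry, so the label is
recoverable from the features only through the planted residues (with δ=0
the features carry no state information at all).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .labeling import STATES, LabelingConfig, label_state, probe_distance
from .trajectory import FrameRecord, Trajectory


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SynthConfig:
    """Generator conditions.

    Defaults define the committed small-receptor fixture: M=60 residues,
    200 trajectories × 30 frames, 6 planted residues with displacement
    δ=2.5 Å over background noise σ=0.5 Å (δ/σ = 5, i.e. a clearly resolvable
    but not degenerate state signal), probe pair (20, 45), and a distance
    walk with unit step scale reflected inside 5–17 Å so the ensemble
    populates all three states around the 8.5/14 Å thresholds.
    """

    n_residues: int = 60
    n_trajectories: int = 200
    frames_per_trajectory: int = 30
    probe_pair: tuple[int, int] = (20, 45)
    distance_start: float | None = None   # None: uniform in bounds per trajectory
    distance_step: float = 1.0
    distance_bounds: tuple[float, float] = (5.0, 17.0)
    planted_residues: tuple[int, ...] = (5, 12, 23, 34, 41, 55)
    displacement: float = 2.5   # δ, Å
    noise: float = 0.5          # σ, Å
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise <= 0 or self.displacement < 0:
            raise SyntheticError("require σ > 0 and δ >= 0")
        bad = [r for r in self.planted_residues
               if not (1 <= r <= self.n_residues)]
        if bad:
            raise SyntheticError(f"planted residues outside 1..M: {bad}")
        i, j = self.probe_pair
        if not (1 <= i <= self.n_residues and 1 <= j <= self.n_residues and i != j):
            raise SyntheticError(f"invalid probe pair {self.probe_pair}")


def _reflect(value: float, low: float, high: float) -> float:
    """Reflect a scalar into [low, high]."""
    span = high - low
    value = (value - low) % (2 * span)
    if value > span:
        value = 2 * span - value
    return low + value


def _random_unit(rng: np.random.Generator, size=()) -> np.ndarray:
    v = rng.normal(size=size + (3,))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def generate(cfg: SynthConfig,
             labeling: LabelingConfig | None = None
             ) -> tuple[list[Trajectory], list[int]]:
    """Generate a labeled ensemble; returns (trajectories, planted residues).

    Deterministic given ``cfg.seed``.  Raises if the distance bounds do not
    straddle both labeling thresholds (a state would be unreachable).
    """
    labeling = labeling or LabelingConfig(probe_pair=cfg.probe_pair)
    lo, hi = cfg.distance_bounds
    if not (lo < labeling.low and hi > labeling.high):
        raise SyntheticError(
            f"distance bounds {cfg.distance_bounds} must straddle the labeling "
            f"thresholds ({labeling.low}, {labeling.high}); a state would be unreachable"
        )
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_residues
    # base structure: a coarse 3.8 Å-step random chain, protein-like in extent
    steps = 3.8 * _random_unit(rng, size=(m - 1,))
    base = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    # fixed per-(planted residue, state) displacement directions
    planted = sorted(cfg.planted_residues)
    directions = {(r, s): _random_unit(rng)
                  for r in planted for s in range(len(STATES))}
    # probe Cα geometry: residue i anchored, residue j placed along a fixed axis
    i_probe, j_probe = cfg.probe_pair
    ca_i = base[i_probe - 1].copy()
    probe_axis = _random_unit(rng)

    trajectories: list[Trajectory] = []
    for t in range(cfg.n_trajectories):
        d = (rng.uniform(lo, hi) if cfg.distance_start is None
             else float(cfg.distance_start))
        frames: list[FrameRecord] = []
        for f in range(cfg.frames_per_trajectory):
            d = _reflect(d + rng.normal(scale=cfg.distance_step), lo, hi)
            ca_j = ca_i + d * probe_axis
            dist = probe_distance(ca_i, ca_j)   # exercises the atom-level path
            label = label_state(dist, labeling)
            com = base + rng.normal(scale=cfg.noise, size=(m, 3))
            if cfg.displacement > 0:
                for r in planted:
                    com[r - 1] += cfg.displacement * directions[(r, label.index)]
            frames.append(FrameRecord(frame_index=f, com=com,
                                      probe_distance=dist, label=label))
        trajectories.append(Trajectory(id=f"synth-{t:04d}", frames=frames,
                                       labeling=labeling))
    return trajectories, planted


def class_imbalance_preset(cfg: SynthConfig | None = None) -> SynthConfig:
    """A configuration whose distance walk dwells between the thresholds,
    producing a strongly intermediate-dominated ensemble (as raw receptor
    ensembles are) to exercise the undersampling path."""
    cfg = cfg or SynthConfig()
    return replace(cfg, distance_start=10.5, distance_step=0.3,
                   distance_bounds=(8.3, 14.2))
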