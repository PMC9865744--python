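"""Conformational-state labeling from a probe-pair Cα–Cα distance.

A receptor frame is assigned one of three conformational states from the
Euclidean distance between the alpha-carbons of a configured probe residue
pair (for β2AR: R131 on helix 3 and L272 on helix 6).  Distances at or above
the ``high`` threshold are *active*, at or below ``low`` *inactive*, and
everything strictly in between *intermediate*.  The three predicates
partition [0, ∞): every distance receives exactly one state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Fixed class order used everywhere downstream (network outputs, metrics,
#: relevance maps): active=0, intermediate=1, inactive=2.
STATES: tuple[str, str, str] = ("active", "intermediate", "inactive")

STATE_INDEX = {name: i for i, name in enumerate(STATES)}


class LabelingError(ValueError):
    """Invalid labeling configuration or missing probe data."""


@dataclass(frozen=True)
class LabelingConfig:
    """Probe pair and distance thresholds for state assignment.

    Parameters
    ----------
    probe_pair:
        1-based residue indices of the two probe residues (default 131, 272,
        the β2AR R131–L272 helix-3/helix-6 pair).
    low:
        Inactive bound in Å; ``distance <= low`` labels a frame inactive.
    high:
        Active bound in Å; ``distance >= high`` labels a frame active.
    """

    probe_pair: tuple[int, int] = (131, 272)
    low: float = 8.5
    high: float = 14.0

    def __post_init__(self) -> None:
        if not (0 < self.low < self.high):
            raise LabelingError(
                f"thresholds must satisfy 0 < low < high, got low={self.low}, high={self.high}"
            )


@dataclass(frozen=True)
class StateLabel:
    """A state name together with the distance that produced it."""

    state: str
    distance: float

    @property
    def index(self) -> int:
        return STATE_INDEX[self.state]


def probe_distance(ca_i: Sequence[float], ca_j: Sequence[float]) -> float:
    """Euclidean Cα–Cα distance (Å) between the two probe residues.

    Raises
    ------
    LabelingError
        If either coordinate triple is missing or non-finite.
    """
    for name, ca in (("i", ca_i), ("j", ca_j)):
        if ca is None:
            raise LabelingError(f"missing Cα coordinates for probe residue {name}")
        arr = np.asarray(ca, dtype=float)
        if arr.shape != (3,) or not np.all(np.isfinite(arr)):
            raise LabelingError(f"invalid Cα coordinates for probe residue {name}: {ca!r}")
    return float(np.linalg.norm(np.asarray(ca_i, float) - np.asarray(ca_j, float)))


def label_state(distance: float, cfg: LabelingConfig | None = None) -> StateLabel:
    """Map a probe distance to its unique conformational state.

    active iff ``distance >= cfg.high``; inactive iff ``distance <= cfg.low``;
    intermediate otherwise.  Both boundaries are inclusive on the outer states.
    """
    cfg = cfg or LabelingConfig()
    if distance < 0 or not np.isfinite(distance):
        raise LabelingError(f"distance must be finite and >= 0, got {distance}")
    if distance >= cfg.high:
        state = "active"
    elif distance <= cfg.low:
        state = "inactive"
    else:
        state = "intermediate"
    return StateLabel(state=state, distance=float(distance))


def label_states(distances: np.ndarray, cfg: LabelingConfig | None = None) -> np.ndarray:
    """Vectorized :func:`label_state`: distances → integer class indices."""
    cfg = cfg or LabelingConfig()
    d = np.asarray(distances, dtype=float)
    if d.size and (np.any(d < 0) or not np.all(np.isfinite(d))):
        raise LabelingError("all distances must be finite and >= 0")
    out = np.full(d.shape, STATE_INDEX["intermediate"], dtype=np.int64)
    out[d >= cfg.high] = STATE_INDEX["active"]
    out[d <= cfg.low] = STATE_INDEX["inactive"]
    return out


def label_trajectory(traj, cfg: LabelingConfig | None = None):
    """Label every frame of a trajectory in place (via its probe distance).

    Returns ``(trajectory, distribution)`` where ``distribution`` maps each
    state name to its frame count (zero counts included).
    """
    cfg = cfg or LabelingConfig()
    counts = {s: 0 for s in STATES}
    for frame in traj.frames:
        if frame.probe_distance is None:
            raise LabelingError(
                f"frame {frame.frame_index} of trajectory {traj.id!r} has no probe distance"
            )
        frame.label = label_state(frame.probe_distance, cfg)
        counts[frame.label.state] += 1
    return traj, counts
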