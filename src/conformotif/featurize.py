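"""Frame featurization: center-of-mass, flattening, min–max normalization.

A frame of M residue center-of-mass positions becomes a residue-major
length-3M vector (x1,y1,z1,x2,…), so residue ``i`` (1-based) always owns
features ``3i-3 .. 3i-1`` (0-based).  Feature matrices are min–max scaled
per feature, fitted on the training split only; held-out values are not
clipped, preserving the linearity assumed by relevance analysis of inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.preprocessing import MinMaxScaler as _SkMinMax

from .labeling import STATE_INDEX


class FeaturizationError(ValueError):
    pass


def center_of_mass(atom_coords: np.ndarray, masses: np.ndarray,
                   residue_of_atom: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position per residue.

    Parameters
    ----------
    atom_coords:
        (A, 3) atom positions in Å.
    masses:
        length-A atomic masses in amu, all strictly positive.
    residue_of_atom:
        length-A 1-based residue index of each atom; every residue in
        ``1..max`` must own at least one atom.

    Returns
    -------
    (M, 3) array of residue centers of mass.
    """
    coords = np.asarray(atom_coords, dtype=float)
    m = np.asarray(masses, dtype=float)
    res = np.asarray(residue_of_atom, dtype=int)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] != m.shape[0] \
            or res.shape[0] != m.shape[0]:
        raise FeaturizationError("atom_coords, masses and residue_of_atom disagree in shape")
    if np.any(m <= 0):
        raise FeaturizationError("atomic masses must be strictly positive")
    n_res = int(res.max())
    counts = np.bincount(res - 1, minlength=n_res)
    if np.any(counts == 0):
        empty = np.nonzero(counts == 0)[0] + 1
        raise FeaturizationError(f"residues with no atoms: {empty.tolist()}")
    total_mass = np.bincount(res - 1, weights=m, minlength=n_res)
    com = np.empty((n_res, 3))
    for axis in range(3):
        com[:, axis] = np.bincount(res - 1, weights=m * coords[:, axis],
                                   minlength=n_res) / total_mass
    return com


def flatten_frame(com: np.ndarray) -> np.ndarray:
    """(M, 3) residue COM block → residue-major length-3M vector."""
    com = np.asarray(com, dtype=float)
    if com.ndim != 2 or com.shape[1] != 3:
        raise FeaturizationError(f"expected (M, 3) coordinates, got {com.shape}")
    return com.reshape(-1)


def unflatten_frame(vector: np.ndarray) -> np.ndarray:
    """Inverse of :func:`flatten_frame`."""
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1 or v.size % 3:
        raise FeaturizationError(f"feature vector length {v.shape} is not 3M")
    return v.reshape(-1, 3)


@dataclass
class MinMaxScaler:
    """Per-feature min–max normalization, JSON-serializable.

    Thin wrapper over scikit-learn's scaler (``clip=False``): transformed
    training data lies in [0, 1]; constant features map to 0; held-out values
    may fall outside [0, 1].
    """

    data_min: np.ndarray
    data_max: np.ndarray

    @property
    def n_features(self) -> int:
        return self.data_min.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise FeaturizationError(
                f"expected {self.n_features} feature columns, got {X.shape[1]}"
            )
        scale = self.data_max - self.data_min
        scale = np.where(scale == 0, 1.0, scale)  # constant features -> 0
        return (X - self.data_min) / scale

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "data_min": self.data_min.tolist(),
            "data_max": self.data_max.tolist(),
        }))

    @classmethod
    def from_json(cls, path: str | Path) -> "MinMaxScaler":
        blob = json.loads(Path(path).read_text())
        return cls(data_min=np.array(blob["data_min"], dtype=float),
                   data_max=np.array(blob["data_max"], dtype=float))


def fit_minmax(train: np.ndarray) -> MinMaxScaler:
    """Learn per-feature minima/maxima from a (N, 3M) training matrix."""
    X = np.asarray(train, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise FeaturizationError("training matrix must be 2-D with at least one row")
    sk = _SkMinMax(clip=False).fit(X)
    return MinMaxScaler(data_min=sk.data_min_.copy(), data_max=sk.data_max_.copy())


def apply_minmax(scaler: MinMaxScaler, X: np.ndarray) -> np.ndarray:
    return scaler.transform(X)


def assemble_dataset(trajectories) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Stack labeled trajectories into (X, y, provenance).

    Returns the (N, 3M) raw (unscaled) feature matrix, integer class labels
    in the fixed (active, intermediate, inactive) order, and a per-row
    ``(trajectory id, frame index)`` provenance list.
    """
    rows, labels, provenance = [], [], []
    for traj in trajectories:
        for frame in traj.frames:
            if frame.label is None:
                raise FeaturizationError(
                    f"frame {frame.frame_index} of {traj.id!r} is unlabeled"
                )
            rows.append(flatten_frame(frame.com))
            labels.append(STATE_INDEX[frame.label.state])
            provenance.append((traj.id, frame.frame_index))
    if not rows:
        raise FeaturizationError("no labeled frames")
    return np.array(rows), np.array(labels, dtype=np.int64), provenance
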