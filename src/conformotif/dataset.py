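"""Class balancing and stratified splitting.

The raw ensembles are dominated by the intermediate state, so the frame set
is first randomly under-sampled to the minority class and then split into
stratified train/validation subsets.  Both operations are pure functions of
their inputs and a seed, with exact per-class count contracts:
undersampling keeps exactly ``min(class counts)`` frames per class and the
split puts ``round(fraction × class count)`` of each class into training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/validation split specification."""

    train_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise DatasetError(
                f"train_fraction must lie in (0, 1), got {self.train_fraction}"
            )


def undersample(labels: np.ndarray, seed: int, n_classes: int = 3) -> np.ndarray:
    """Randomly under-sample every class to the minority-class count.

    Returns sorted frame indices; each class retains exactly the minority
    count, sampled uniformly without replacement.  Deterministic given seed.
    """
    y = np.asarray(labels, dtype=np.int64)
    counts = np.bincount(y, minlength=n_classes)
    if np.any(counts == 0):
        missing = np.nonzero(counts == 0)[0].tolist()
        raise DatasetError(f"classes absent from the label vector: {missing}")
    target = int(counts.min())
    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for c in range(n_classes):
        members = np.nonzero(y == c)[0]
        keep.append(rng.choice(members, size=target, replace=False))
    return np.sort(np.concatenate(keep))


def stratified_split(indices: np.ndarray, labels: np.ndarray,
                     spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Split frame indices into disjoint, exhaustive train/validation sets.

    Per class, exactly ``round(train_fraction × class count)`` indices go to
    training; the rest to validation.  ``labels`` is indexed by the values in
    ``indices`` (i.e. it is the full per-frame label vector).
    """
    idx = np.asarray(indices, dtype=np.int64)
    y = np.asarray(labels, dtype=np.int64)[idx]
    rng = np.random.default_rng(spec.seed)
    train_parts, val_parts = [], []
    for c in np.unique(y):
        members = idx[y == c]
        perm = rng.permutation(members)
        n_train = int(round(spec.train_fraction * len(members)))
        train_parts.append(perm[:n_train])
        val_parts.append(perm[n_train:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(val_parts))
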