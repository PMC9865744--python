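"""Canonical trajectory container and text-based I/O.

The canonical on-disk form of an ensemble member is a delimited text table,
one row per residue per frame (``frame,res_index,x,y,z`` plus optional
``probe_distance,label`` columns), with a JSON sidecar holding trajectory
metadata.  Coordinates are Å at fixed 6-decimal precision, residue indices
are 1-based, and read∘write is the identity on valid trajectories.

Residue annotations (name, optional Ballesteros–Weinstein generic number,
region membership) live in a separate CSV.  Regions form a closed vocabulary:
the seven transmembrane helices H1–H7, the intracellular and extracellular
loops ICL1–ICL3 / ECL1–ECL3, and the two termini.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .labeling import STATES, LabelingConfig, StateLabel, label_state, probe_distance

REGIONS: tuple[str, ...] = (
    "H1", "H2", "H3", "H4", "H5", "H6", "H7",
    "ICL1", "ICL2", "ICL3",
    "ECL1", "ECL2", "ECL3",
    "N-terminus", "C-terminus",
)

_NAME_RE = re.compile(r"^[A-Z]{3}\d+$")
COORD_DECIMALS = 6


class TrajectoryIOError(ValueError):
    """Malformed canonical table or annotation file."""


@dataclass(frozen=True)
class ResidueAnnotation:
    """One residue's identity and region membership.

    ``index`` is the 1-based position in the modeled chain; ``name`` combines
    the 3-letter amino-acid code with the author sequence number (e.g.
    ``VAL31``); ``generic_number`` is the optional Ballesteros–Weinstein
    label (e.g. ``1.30``); ``region`` is one of :data:`REGIONS`.
    """

    index: int
    name: str
    generic_number: Optional[str]
    region: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise TrajectoryIOError(
                f"unknown region {self.region!r} for residue {self.name!r}; "
                f"allowed: {', '.join(REGIONS)}"
            )
        if not _NAME_RE.match(self.name):
            raise TrajectoryIOError(
                f"residue name {self.name!r} is not <3-letter code><number>"
            )


@dataclass
class FrameRecord:
    """Per-residue center-of-mass coordinates for one frame."""

    frame_index: int
    com: np.ndarray  # (M, 3) Å
    probe_distance: Optional[float] = None
    label: Optional[StateLabel] = None

    def validate(self, n_residues: int) -> None:
        com = np.asarray(self.com, dtype=float)
        if com.shape != (n_residues, 3):
            raise TrajectoryIOError(
                f"frame {self.frame_index}: expected {n_residues} residue rows "
                f"of 3 coordinates, got shape {com.shape}"
            )
        if not np.all(np.isfinite(com)):
            raise TrajectoryIOError(f"frame {self.frame_index}: non-finite coordinate")
        if self.probe_distance is not None and self.probe_distance < 0:
            raise TrajectoryIOError(
                f"frame {self.frame_index}: negative probe distance"
            )


@dataclass
class Trajectory:
    """An ordered list of frames plus residue annotations."""

    id: str
    frames: list[FrameRecord]
    annotations: list[ResidueAnnotation] = field(default_factory=list)
    labeling: Optional[LabelingConfig] = None

    @property
    def n_residues(self) -> int:
        if self.annotations:
            return len(self.annotations)
        if self.frames:
            return int(np.asarray(self.frames[0].com).shape[0])
        return 0

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def validate(self) -> None:
        m = self.n_residues
        for frame in self.frames:
            frame.validate(m)


# ---------------------------------------------------------------------------
# Canonical COM table I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_com_table(traj: Trajectory, path: str | Path) -> None:
    """Write the canonical CSV table plus its JSON metadata sidecar.

    Coordinates (and probe distances) are written with 6 decimal places so a
    read-back is bit-identical at the declared precision.
    """
    path = Path(path)
    traj.validate()
    rows: list[dict] = []
    has_dist = any(f.probe_distance is not None for f in traj.frames)
    has_label = any(f.label is not None for f in traj.frames)
    for frame in traj.frames:
        com = np.asarray(frame.com, dtype=float)
        for r in range(com.shape[0]):
            row: dict = {
                "frame": frame.frame_index,
                "res_index": r + 1,
                "x": com[r, 0],
                "y": com[r, 1],
                "z": com[r, 2],
            }
            if has_dist:
                row["probe_distance"] = frame.probe_distance
            if has_label:
                row["label"] = frame.label.state if frame.label else ""
            rows.append(row)
    columns = ["frame", "res_index", "x", "y", "z"]
    if has_dist:
        columns.append("probe_distance")
    if has_label:
        columns.append("label")
    df = pd.DataFrame(rows, columns=columns)
    df.to_csv(path, index=False, float_format=f"%.{COORD_DECIMALS}f")

    meta = {"id": traj.id, "n_residues": traj.n_residues}
    if traj.labeling is not None:
        meta["probe_pair"] = list(traj.labeling.probe_pair)
        meta["thresholds"] = [traj.labeling.low, traj.labeling.high]
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_com_table(path: str | Path) -> Trajectory:
    """Read a canonical COM table (and sidecar, if present) back to a Trajectory.

    Raises :class:`TrajectoryIOError` naming the offending frame when a frame
    has missing or extra residue rows, and a parse error with the line number
    for non-numeric coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except ValueError as exc:  # pragma: no cover - pandas formats the message
        raise TrajectoryIOError(f"{path}: cannot parse table: {exc}") from exc
    required = {"frame", "res_index", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise TrajectoryIOError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    for col in ("x", "y", "z"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise TrajectoryIOError(
                f"{path}: non-numeric coordinate in column {col!r} at line {line}"
            )
        df[col] = pd.to_numeric(df[col])

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    labeling = None
    if "probe_pair" in meta and "thresholds" in meta:
        labeling = LabelingConfig(
            probe_pair=tuple(meta["probe_pair"]),
            low=meta["thresholds"][0],
            high=meta["thresholds"][1],
        )

    frames: list[FrameRecord] = []
    if len(df):
        m_expected = int(meta.get("n_residues") or df["res_index"].max())
        for frame_idx, group in df.groupby("frame", sort=True):
            idx = np.sort(group["res_index"].to_numpy())
            if len(group) != m_expected or not np.array_equal(
                idx, np.arange(1, m_expected + 1)
            ):
                raise TrajectoryIOError(
                    f"{path}: frame {frame_idx} has {len(group)} residue rows, "
                    f"expected contiguous 1..{m_expected}"
                )
            g = group.sort_values("res_index")
            com = g[["x", "y", "z"]].to_numpy(dtype=float)
            dist = None
            if "probe_distance" in g.columns and g["probe_distance"].notna().any():
                dist = float(g["probe_distance"].iloc[0])
            label = None
            if "label" in g.columns and isinstance(g["label"].iloc[0], str):
                state = g["label"].iloc[0]
                if state not in STATES:
                    raise TrajectoryIOError(
                        f"{path}: frame {frame_idx}: unknown state label {state!r}"
                    )
                label = StateLabel(state=state, distance=dist if dist is not None else float("nan"))
            frames.append(
                FrameRecord(frame_index=int(frame_idx), com=com,
                            probe_distance=dist, label=label)
            )
    traj = Trajectory(id=str(meta.get("id", path.stem)), frames=frames, labeling=labeling)
    traj.validate()
    return traj


# ---------------------------------------------------------------------------
# Residue annotations
# ---------------------------------------------------------------------------

def load_annotations(path: str | Path) -> list[ResidueAnnotation]:
    """Load a residue annotation CSV (``index,name,generic_number,region``).

    Enforces contiguous 1..M indices, unique indices, the closed region
    vocabulary, and contiguous region segments.
    """
    df = pd.read_csv(path, dtype={"generic_number": str})
    required = {"index", "name", "region"}
    if not required.issubset(df.columns):
        raise TrajectoryIOError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    annotations = [
        ResidueAnnotation(
            index=int(row["index"]),
            name=str(row["name"]),
            generic_number=(
                str(row["generic_number"])
                if "generic_number" in df.columns and pd.notna(row.get("generic_number"))
                else None
            ),
            region=str(row["region"]),
        )
        for _, row in df.iterrows()
    ]
    validate_annotations(annotations)
    return annotations


def save_annotations(annotations: Iterable[ResidueAnnotation], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "index": a.index,
                "name": a.name,
                "generic_number": a.generic_number or "",
                "region": a.region,
            }
            for a in annotations
        ]
    )
    df.to_csv(path, index=False)


def validate_annotations(annotations: list[ResidueAnnotation]) -> None:
    indices = [a.index for a in annotations]
    if len(set(indices)) != len(indices):
        dupes = sorted({i for i in indices if indices.count(i) > 1})
        raise TrajectoryIOError(f"duplicate residue indices: {dupes}")
    if indices != list(range(1, len(indices) + 1)):
        raise TrajectoryIOError("residue indices must be contiguous 1..M in order")
    # region segments must be contiguous runs
    seen: set[str] = set()
    previous = None
    for a in annotations:
        if a.region != previous:
            if a.region in seen:
                raise TrajectoryIOError(
                    f"region {a.region!r} appears in non-contiguous segments"
                )
            seen.add(a.region)
            previous = a.region


# ---------------------------------------------------------------------------
# Default β2AR annotation (synthetic reconstruction)
# ---------------------------------------------------------------------------

# Ballesteros–Weinstein x.50 anchor residues for the seven helices.
_BW_ANCHORS = {1: 51, 2: 79, 3: 131, 4: 158, 5: 211, 6: 288, 7: 323}

# (first_seq, last_seq, region) boundaries over author numbering 29..342,
# with the 231..262 span absent from the modeled construct.
_B2AR_SEGMENTS = [
    (29, 29, "N-terminus"),
    (30, 60, "H1"),
    (61, 66, "ICL1"),
    (67, 96, "H2"),
    (97, 105, "ECL1"),
    (106, 136, "H3"),
    (137, 146, "ICL2"),
    (147, 171, "H4"),
    (172, 196, "ECL2"),
    (197, 229, "H5"),
    (230, 266, "ICL3"),
    (267, 298, "H6"),
    (299, 305, "ECL3"),
    (306, 329, "H7"),
    (330, 342, "C-terminus"),
]

_B2AR_GAP = set(range(231, 263))  # ICL3 span absent from the modeled construct

# Residue names with published identities; everything else is UNK (this
# default table is a synthetic reconstruction, meant to be user-replaceable).
_B2AR_KNOWN_NAMES = {
    31: "VAL", 32: "TRP", 33: "VAL", 34: "VAL", 35: "GLY", 36: "MET", 37: "GLY",
    38: "ILE", 39: "VAL", 40: "MET", 41: "SER", 42: "LEU", 43: "ILE", 44: "VAL",
    45: "LEU", 46: "ALA", 47: "ILE", 48: "VAL", 49: "PHE", 50: "GLY", 51: "ASN",
    52: "VAL", 53: "LEU", 62: "GLU", 64: "LEU", 65: "GLN", 66: "THR", 67: "VAL",
    69: "ASN", 70: "TYR", 81: "VAL", 82: "MET", 83: "GLY", 87: "VAL", 88: "PRO",
    94: "ILE", 95: "LEU", 96: "MET", 97: "LYS", 99: "TRP", 100: "THR",
    101: "PHE", 102: "GLY", 131: "ARG", 137: "SER", 140: "LYS", 141: "TYR",
    142: "GLN", 148: "ASN", 149: "LYS", 151: "ARG", 156: "MET", 178: "HIS",
    179: "GLN", 195: "THR", 272: "LEU", 296: "HIS", 299: "GLN", 300: "ASP",
    301: "ASN",
}


def b2ar_default_annotations() -> list[ResidueAnnotation]:
    """Synthetic default annotation table for the 282-residue β2AR construct.

    Positions 1..282 map to author sequence numbers 29..342 minus the 231..262
    intracellular-loop-3 span absent from the modeled inactive-state construct.
    Helix boundaries are approximate; generic numbers are derived from the
    canonical x.50 anchors.  Residue identities not published alongside the
    regions are filled with ``UNK`` — replace with a real annotation file for
    production analyses of β2AR.
    """
    annotations: list[ResidueAnnotation] = []
    position = 0
    for first, last, region in _B2AR_SEGMENTS:
        for seq in range(first, last + 1):
            if seq in _B2AR_GAP:
                continue
            position += 1
            generic = None
            if region.startswith("H") and len(region) == 2:
                helix = int(region[1])
                generic = f"{helix}.{50 + seq - _BW_ANCHORS[helix]}"
            name = f"{_B2AR_KNOWN_NAMES.get(seq, 'UNK')}{seq}"
            annotations.append(
                ResidueAnnotation(index=position, name=name,
                                  generic_number=generic, region=region)
            )
    validate_annotations(annotations)
    return annotations


def uniform_annotations(n_residues: int, region: str = "H1") -> list[ResidueAnnotation]:
    """A minimal single-region annotation for synthetic systems."""
    return [
        ResidueAnnotation(index=i + 1, name=f"UNK{i + 1}", generic_number=None, region=region)
        for i in range(n_residues)
    ]


def synthetic_region_annotations(n_residues: int) -> list[ResidueAnnotation]:
    """Annotations splitting 1..M into contiguous runs over all 15 regions.

    Used for synthetic ensembles where region identity is arbitrary but a
    full region vocabulary is wanted for the region-summary path.
    """
    bounds = np.linspace(0, n_residues, len(REGIONS) + 1).astype(int)
    annotations = []
    order = ("N-terminus", "H1", "ICL1", "H2", "ECL1", "H3", "ICL2", "H4",
             "ECL2", "H5", "ICL3", "H6", "ECL3", "H7", "C-terminus")
    for seg, region in enumerate(order):
        for i in range(bounds[seg], bounds[seg + 1]):
            annotations.append(
                ResidueAnnotation(index=i + 1, name=f"UNK{i + 1}",
                                  generic_number=None, region=region)
            )
    validate_annotations(annotations)
    return annotations


# ---------------------------------------------------------------------------
# Optional standard-format adapter (MDAnalysis plugin; core never imports it)
# ---------------------------------------------------------------------------

def ingest_md(topology: str | Path, trajectory_files: list[str | Path],
              labeling: LabelingConfig | None = None,
              traj_id: str = "ingested") -> Trajectory:
    """Convert a standard topology+trajectory pair to the canonical form.

    Computes per-residue center-of-mass coordinates and, when a labeling
    config is given, the probe-pair Cα distance per frame before atom detail
    is discarded.  Requires the optional MDAnalysis dependency.
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "standard-format ingestion requires the optional MDAnalysis dependency"
        ) from exc

    u = mda.Universe(str(topology), *[str(t) for t in trajectory_files])
    residues = u.residues
    frames: list[FrameRecord] = []
    for k, _ in enumerate(u.trajectory):
        com = np.array([res.atoms.center_of_mass() for res in residues])
        dist = None
        label = None
        if labeling is not None:
            i, j = labeling.probe_pair
            ca_i = residues[i - 1].atoms.select_atoms("name CA")
            ca_j = residues[j - 1].atoms.select_atoms("name CA")
            if len(ca_i) == 0 or len(ca_j) == 0:
                # documented fallback: approximate the probe distance from COMs
                dist = float(np.linalg.norm(com[i - 1] - com[j - 1]))
            else:
                dist = probe_distance(ca_i.positions[0], ca_j.positions[0])
            label = label_state(dist, labeling)
        frames.append(FrameRecord(frame_index=k, com=com,
                                  probe_distance=dist, label=label))
    return Trajectory(id=traj_id, frames=frames, labeling=labeling)
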