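"""Trajectory dihedral analysis: substrate IN/OUT states, rotamer maps, H-bonds.

The substrate orientation in the active site is tracked through a
pseudo-dihedral over four atoms (an anchoring Calpha, the substrate C and N
atoms, and a second anchoring Calpha).  Frames with an angle above 50
degrees are classified IN (productive pose, nominal range 51--180), the
rest OUT (nominal range -180--50); the published ranges leave (50, 51)
unassigned, so a single configurable boundary at 50 is used.  State
fractions are frame-count percentages and always sum to exactly 100.

Hydrogen-bond occupancy uses a heavy-atom donor--acceptor distance
criterion (default 3.5 angstrom) with the distance per frame taken to the
closest candidate acceptor (side-chain rotation can swap equivalent
oxygens).  Side-chain chi1/chi2 joint histograms with connected-component
mode counting expose metastable rotamer states.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "Trajectory",
    "DihedralSpec",
    "StateSeries",
    "dihedral",
    "normalize_angle",
    "classify_in_out",
    "state_fractions",
    "dihedral_series",
    "chi_joint_distribution",
    "hbond_occupancy",
    "occupancy_from_distances",
    "read_coordinate_table",
    "read_multimodel_pdb",
]

IN_OUT_BOUNDARY = 50.0  # degrees; IN iff angle > boundary

AtomSelector = tuple[int, str]  # (residue_index, atom_name)


@dataclass
class Trajectory:
    """Topology (``residue_index, residue_name, atom_name`` rows) plus an
    ``(n_frames, n_atoms, 3)`` coordinate array in angstrom."""

    topology: pd.DataFrame
    coords: np.ndarray
    frame_interval_ps: float = 10.0

    def __post_init__(self):
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.topology):
            raise ValueError("atom count mismatch between topology and coords")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def atom_index(self, selector: AtomSelector) -> int:
        res, name = selector
        hits = self.topology.index[
            (self.topology["residue_index"] == res)
            & (self.topology["atom_name"] == name)
        ]
        if len(hits) == 0:
            raise KeyError(f"atom ({res}, {name!r}) not found in topology")
        return int(hits[0])

    def atom_coords(self, selector: AtomSelector) -> np.ndarray:
        return self.coords[:, self.atom_index(selector), :]


@dataclass(frozen=True)
class DihedralSpec:
    """Four atom selectors defining a torsion, plus a label."""

    atoms: tuple[AtomSelector, AtomSelector, AtomSelector, AtomSelector]
    label: str = ""

    def __post_init__(self):
        if len(set(self.atoms)) != 4:
            raise ValueError("a dihedral needs four distinct atoms")


@dataclass
class StateSeries:
    """Per-frame IN/OUT labels with the angles that produced them."""

    labels: np.ndarray  # bool, True = IN
    angles: np.ndarray  # degrees in (-180, 180]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, bool)
        self.angles = np.asarray(self.angles, float)
        if self.labels.shape != self.angles.shape:
            raise ValueError("labels and angles must have matching shapes")

    @classmethod
    def from_angles(cls, angles: np.ndarray, boundary: float = IN_OUT_BOUNDARY):
        angles = normalize_angle(np.asarray(angles, float))
        return cls(labels=angles > boundary, angles=angles)


# ---------------------------------------------------------------------------
# geometry


def normalize_angle(angle):
    """Wrap degrees into (-180, 180], mapping -180 to +180."""
    a = np.mod(np.asarray(angle, float) + 180.0, 360.0) - 180.0
    a = np.where(a == -180.0, 180.0, a)
    return float(a) if a.ndim == 0 else a


def dihedral(p1, p2, p3, p4) -> float | np.ndarray:
    """Signed IUPAC torsion angle in degrees, in (-180, 180].

    Accepts single points (shape (3,)) or per-frame stacks (n, 3).
    Raises on a torsion left undefined by collinear bond vectors.
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    if np.any(b2n == 0) or np.any(np.linalg.norm(n1, axis=-1) < 1e-12) or np.any(
        np.linalg.norm(n2, axis=-1) < 1e-12
    ):
        raise ValueError("undefined torsion: collinear or coincident atoms")
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * (b2 / b2n[..., None] if b1.ndim > 1 else b2 / b2n), axis=-1)
    return normalize_angle(np.degrees(np.arctan2(y, x)))


def dihedral_series(traj: Trajectory, spec: DihedralSpec) -> np.ndarray:
    """Torsion angle of ``spec`` in every frame (degrees)."""
    try:
        pts = [traj.atom_coords(sel) for sel in spec.atoms]
    except KeyError as err:
        raise KeyError(f"dihedral {spec.label or spec.atoms}: {err}") from None
    return dihedral(*pts)


# ---------------------------------------------------------------------------
# IN/OUT states


def classify_in_out(angle: float, boundary: float = IN_OUT_BOUNDARY) -> str:
    """``"IN"`` when the (normalized) angle exceeds the boundary, else ``"OUT"``."""
    return "IN" if normalize_angle(angle) > boundary else "OUT"


def state_fractions(series: StateSeries | np.ndarray) -> tuple[float, float]:
    """(%IN, %OUT) frame-count percentages; the pair sums to exactly 100."""
    labels = series.labels if isinstance(series, StateSeries) else np.asarray(series, bool)
    if labels.size == 0:
        raise ValueError("empty state series")
    pct_in = 100.0 * float(np.count_nonzero(labels)) / labels.size
    return pct_in, 100.0 - pct_in


# ---------------------------------------------------------------------------
# rotamer maps


def chi_joint_distribution(
    traj: Trajectory,
    spec1: DihedralSpec,
    spec2: DihedralSpec,
    bins: int = 36,
    mode_threshold: float = 0.05,
):
    """Normalized joint histogram of two torsions over (-180, 180]^2.

    Returns ``(hist, edges1, edges2, n_modes)`` where ``n_modes`` counts
    connected components of bins whose density exceeds ``mode_threshold``
    times the maximum bin (connectivity does not wrap across the +/-180
    seam; modes straddling it merge only through occupied interior bins).
    """
    a1 = dihedral_series(traj, spec1)
    a2 = dihedral_series(traj, spec2)
    hist, e1, e2 = np.histogram2d(
        a1, a2, bins=bins, range=[[-180.0, 180.0], [-180.0, 180.0]]
    )
    hist = hist / hist.sum()
    labeled, n_modes = ndimage.label(hist > mode_threshold * hist.max())
    return hist, e1, e2, int(n_modes)


# ---------------------------------------------------------------------------
# hydrogen bonds


def occupancy_from_distances(
    distances: np.ndarray, cutoff: float = 3.5
) -> tuple[float, float, float]:
    """(occupancy, mean distance, sd) with statistics over bonded frames only."""
    d = np.asarray(distances, float)
    if d.size == 0:
        raise ValueError("empty distance series")
    bonded = d <= cutoff
    occ = float(np.count_nonzero(bonded)) / d.size
    if bonded.any():
        mean = float(d[bonded].mean())
        sd = float(d[bonded].std())
    else:
        mean = sd = float("nan")
    return occ, mean, sd


def hbond_occupancy(
    traj: Trajectory,
    donor: AtomSelector,
    acceptors: Sequence[AtomSelector],
    cutoff: float = 3.5,
) -> tuple[float, float, float]:
    """Heavy-atom H-bond occupancy with the closest-acceptor convention.

    Per frame the donor--acceptor distance is the minimum over all
    candidate acceptors; the bond counts as formed when that distance is
    within ``cutoff`` (angstrom).
    """
    if len(acceptors) == 0:
        raise ValueError("no candidate acceptor atoms")
    dcoords = traj.atom_coords(donor)
    dists = np.stack(
        [np.linalg.norm(traj.atom_coords(a) - dcoords, axis=1) for a in acceptors],
        axis=1,
    )
    return occupancy_from_distances(dists.min(axis=1), cutoff=cutoff)


# ---------------------------------------------------------------------------
# IO


def read_coordinate_table(path: str | Path, frame_interval_ps: float = 10.0) -> Trajectory:
    """Read a plain per-frame coordinate table.

    Expected tab/whitespace-separated columns:
    ``frame, residue_index, atom_name, x, y, z`` (optionally
    ``residue_name``); every frame must list the same atoms in the same
    order.
    """
    df = pd.read_csv(path, sep=r"\s+")
    required = {"frame", "residue_index", "atom_name", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coordinate table missing columns: {sorted(missing)}")
    frames = sorted(df["frame"].unique())
    first = df[df["frame"] == frames[0]].reset_index(drop=True)
    cols = ["residue_index", "atom_name"] + (
        ["residue_name"] if "residue_name" in df.columns else []
    )
    topology = first[cols].copy()
    n_atoms = len(topology)
    coords = np.empty((len(frames), n_atoms, 3), float)
    for i, fr in enumerate(frames):
        sub = df[df["frame"] == fr]
        if len(sub) != n_atoms:
            raise ValueError(f"frame {fr} has {len(sub)} atoms, expected {n_atoms}")
        coords[i] = sub[["x", "y", "z"]].to_numpy(float)
    return Trajectory(topology=topology, coords=coords, frame_interval_ps=frame_interval_ps)


def write_coordinate_table(traj: Trajectory, path: str | Path) -> None:
    rows = []
    for fr in range(traj.n_frames):
        for i, atom in traj.topology.iterrows():
            x, y, z = traj.coords[fr, i]
            rows.append((fr, atom["residue_index"], atom["atom_name"], x, y, z))
    pd.DataFrame(rows, columns=["frame", "residue_index", "atom_name", "x", "y", "z"]).to_csv(
        path, sep="\t", index=False
    )


def read_multimodel_pdb(path: str | Path, frame_interval_ps: float = 10.0) -> Trajectory:
    """Read a MODEL/ENDMDL multi-model PDB as a trajectory (heavy atoms and
    hydrogens alike; whatever the file contains)."""
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("traj", str(path))
    frames = []
    topology = None
    for model in structure:
        atoms = [
            (res.id[1], res.resname.strip(), atom.get_name(), atom.coord)
            for chain in model
            for res in chain
            for atom in res
        ]
        top = pd.DataFrame(
            [(a[0], a[1], a[2]) for a in atoms],
            columns=["residue_index", "residue_name", "atom_name"],
        )
        if topology is None:
            topology = top
        elif len(top) != len(topology):
            raise ValueError("atom count varies between models")
        frames.append(np.asarray([a[3] for a in atoms], float))
    if topology is None:
        raise ValueError("no models found in PDB file")
    return Trajectory(
        topology=topology, coords=np.stack(frames), frame_interval_ps=frame_interval_ps
    )
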