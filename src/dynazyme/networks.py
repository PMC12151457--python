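"""Interaction-network scoring: ligand-state importance (KIF) and
evolutionary conservation (KIN).

Noncovalent interactions (hydrogen bonds, salt bridges, hydrophobic
contacts) are tracked per frame in two ensembles, with and without the
bound ligand.  After excluding interactions formed in less than half of
the frames of *both* ensembles (an AND-exclusion would discard exactly the
state-discriminating contacts the method looks for), each surviving
interaction is scored by the plug-in mutual information (bits) between its
per-frame presence and the apo/holo ensemble label; a residue inherits the
maximum (optionally the sum) over its interactions, and residues scoring
above 0.1 are flagged as predicted hotspots.

Conservation scoring counts, for each interaction of a reference
structure, the fraction of a homologous structure family (mapped through a
user-supplied residue correspondence) that forms the equivalent
interaction; interactions conserved in at least half the family define the
conserved network, and a residue inherits its maximum conservation.
Residues combining high importance with low conservation are the preferred
engineering targets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InteractionRecord",
    "KIFScore",
    "KINScore",
    "detect_interactions",
    "occupancy_filter",
    "mutual_information",
    "kif_scores",
    "kin_conservation",
    "filter_hotspots",
    "read_fingerprint_table",
]

logger = logging.getLogger(__name__)

APOLAR_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TRP", "PRO", "TYR"}
POSITIVE_RESIDUES = {"ARG": ("NH1", "NH2", "NE"), "LYS": ("NZ",), "HIS": ("ND1", "NE2")}
NEGATIVE_RESIDUES = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}

STANDARD_RESIDUES = APOLAR_RESIDUES | {
    "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "LYS", "SER", "THR",
}


@dataclass
class InteractionRecord:
    """One noncovalent interaction with per-frame presence per ensemble."""

    interaction_id: str
    type: str  # hbond | saltbridge | hydrophobic
    res_i: int
    res_j: int
    presence: dict[str, np.ndarray] = field(default_factory=dict)  # ensemble -> bool series

    def __post_init__(self):
        if self.res_i == self.res_j:
            raise ValueError("interaction residues must be distinct")

    def occupancy(self, ensemble: str) -> float:
        series = self.presence[ensemble]
        return float(np.count_nonzero(series)) / len(series)


@dataclass
class KIFScore:
    per_interaction_mi: dict[str, float]  # bits
    per_residue: dict[int, float]
    threshold: float = 0.1

    @property
    def predicted_hotspots(self) -> set[int]:
        return {r for r, s in self.per_residue.items() if s > self.threshold}


@dataclass
class KINScore:
    per_interaction_fraction: dict[tuple[int, int], float]
    per_residue: dict[int, float]
    conservation_cutoff: float = 0.5

    @property
    def conserved_network(self) -> set[tuple[int, int]]:
        return {
            pair
            for pair, f in self.per_interaction_fraction.items()
            if f >= self.conservation_cutoff
        }


# ---------------------------------------------------------------------------
# interaction detection


def detect_interactions(
    coords: Mapping[int, Mapping[str, np.ndarray]],
    residue_names: Mapping[int, str],
    hbond_cutoff: float = 3.5,
    saltbridge_cutoff: float = 4.0,
    hydrophobic_cutoff: float = 4.5,
) -> list[tuple[str, int, int]]:
    """Noncovalent interactions present in one structure/frame.

    ``coords`` maps residue -> {atom_name -> xyz}.  Criteria (geometric
    conventions, configurable): hydrogen bond, any N/O--N/O heavy-atom pair
    within ``hbond_cutoff``; salt bridge, charged side-chain N+/O- group
    atoms of oppositely charged residues within ``saltbridge_cutoff``;
    hydrophobic, side-chain carbon--carbon contact within
    ``hydrophobic_cutoff`` between apolar residues.  A 2.0 angstrom floor
    excludes covalent-distance artifacts.  Unknown residue types are
    skipped with a logged warning.  Returns ``(type, res_i, res_j)``
    triples with ``res_i < res_j``.
    """
    known = []
    for res, name in residue_names.items():
        if name not in STANDARD_RESIDUES:
            logger.warning("skipping unknown residue type %s at %s", name, res)
            continue
        known.append(res)

    def atoms_matching(res, predicate):
        return np.asarray(
            [xyz for a, xyz in coords[res].items() if predicate(a)], float
        ).reshape(-1, 3)

    def min_dist(a, b):
        if a.size == 0 or b.size == 0:
            return math.inf
        d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
        d = d[d > 2.0]  # ignore covalent-range contacts
        return float(d.min()) if d.size else math.inf

    found = []
    for ii, res_a in enumerate(known):
        for res_b in known[ii + 1 :]:
            name_a, name_b = residue_names[res_a], residue_names[res_b]
            no_a = atoms_matching(res_a, lambda a: a.startswith(("N", "O")))
            no_b = atoms_matching(res_b, lambda a: a.startswith(("N", "O")))
            if min_dist(no_a, no_b) <= hbond_cutoff:
                found.append(("hbond", res_a, res_b))
            pos, neg = None, None
            if name_a in POSITIVE_RESIDUES and name_b in NEGATIVE_RESIDUES:
                pos, neg = (res_a, name_a), (res_b, name_b)
            elif name_b in POSITIVE_RESIDUES and name_a in NEGATIVE_RESIDUES:
                pos, neg = (res_b, name_b), (res_a, name_a)
            if pos is not None:
                p = atoms_matching(pos[0], lambda a: a in POSITIVE_RESIDUES[pos[1]])
                q = atoms_matching(neg[0], lambda a: a in NEGATIVE_RESIDUES[neg[1]])
                if min_dist(p, q) <= saltbridge_cutoff:
                    found.append(("saltbridge", res_a, res_b))
            if name_a in APOLAR_RESIDUES and name_b in APOLAR_RESIDUES:
                c_a = atoms_matching(
                    res_a, lambda a: a.startswith("C") and a not in BACKBONE_ATOMS
                )
                c_b = atoms_matching(
                    res_b, lambda a: a.startswith("C") and a not in BACKBONE_ATOMS
                )
                if min_dist(c_a, c_b) <= hydrophobic_cutoff:
                    found.append(("hydrophobic", res_a, res_b))
    return found


# ---------------------------------------------------------------------------
# scoring


def occupancy_filter(
    records: Iterable[InteractionRecord], min_occupancy: float = 0.5
) -> list[InteractionRecord]:
    """Keep interactions formed at least ``min_occupancy`` of the time in at
    least one ensemble (inclusive boundary)."""
    return [
        rec
        for rec in records
        if any(rec.occupancy(e) >= min_occupancy for e in rec.presence)
    ]


def mutual_information(feature: np.ndarray, labels: np.ndarray) -> float:
    """Plug-in mutual information (bits) between two binary series.

    Symmetric, nonnegative, and bounded by each marginal entropy; a
    degenerate (constant) marginal gives exactly 0.
    """
    x = np.asarray(feature, bool)
    y = np.asarray(labels, bool)
    if x.shape != y.shape or x.ndim != 1 or x.size == 0:
        raise ValueError("feature and labels must be matching non-empty 1-D series")
    n = x.size
    mi = 0.0
    for xv in (False, True):
        px = np.count_nonzero(x == xv) / n
        if px == 0:
            continue
        for yv in (False, True):
            py = np.count_nonzero(y == yv) / n
            pxy = np.count_nonzero((x == xv) & (y == yv)) / n
            if pxy > 0 and py > 0:
                mi += pxy * math.log2(pxy / (px * py))
    return max(mi, 0.0)


def kif_scores(
    records: Sequence[InteractionRecord],
    aggregation: str = "max",
    threshold: float = 0.1,
    min_occupancy: float = 0.5,
    apply_occupancy_filter: bool = True,
) -> KIFScore:
    """Per-interaction MI against the apo/holo label, aggregated per residue.

    Frames of both ensembles are pooled; the label series marks which
    ensemble each frame came from.  ``aggregation`` is ``"max"`` (default:
    one strong interaction suffices to mark a residue) or ``"sum"``.
    """
    if aggregation not in ("max", "sum"):
        raise ValueError("aggregation must be 'max' or 'sum'")
    records = list(records)
    if apply_occupancy_filter:
        records = occupancy_filter(records, min_occupancy=min_occupancy)
    if not records:
        logger.warning("no interactions retained after occupancy filtering")
        return KIFScore(per_interaction_mi={}, per_residue={}, threshold=threshold)
    per_mi: dict[str, float] = {}
    per_res: dict[int, float] = {}
    for rec in records:
        if not {"apo", "holo"} <= set(rec.presence):
            raise ValueError(f"{rec.interaction_id}: needs both apo and holo series")
        feature = np.concatenate([rec.presence["holo"], rec.presence["apo"]])
        label = np.concatenate(
            [
                np.ones(len(rec.presence["holo"]), bool),
                np.zeros(len(rec.presence["apo"]), bool),
            ]
        )
        mi = mutual_information(feature, label)
        per_mi[rec.interaction_id] = mi
        for res in (rec.res_i, rec.res_j):
            if aggregation == "max":
                per_res[res] = max(per_res.get(res, 0.0), mi)
            else:
                per_res[res] = per_res.get(res, 0.0) + mi
    return KIFScore(per_interaction_mi=per_mi, per_residue=per_res, threshold=threshold)


def kin_conservation(
    reference_interactions: Iterable[tuple[int, int]],
    family: Sequence[Iterable[tuple[int, int]]],
    mapping: Sequence[Mapping[int, int]] | None = None,
    conservation_cutoff: float = 0.5,
) -> KINScore:
    """Fraction of family structures forming each reference interaction.

    ``family[k]`` is the interaction set (residue pairs, each structure's
    own numbering) of the k-th family member and ``mapping[k]`` maps that
    structure's residues onto reference numbering (identity when omitted).
    A residue appearing in an interaction but absent from its structure's
    mapping raises an error naming it.  Per-residue score is the maximum
    conservation over the residue's interactions; pairs below the cutoff
    stay reported but drop out of the conserved network.
    """
    ref = {tuple(sorted(p)) for p in reference_interactions}
    if not family:
        raise ValueError("empty structure family")
    counts = {pair: 0 for pair in ref}
    for k, interactions in enumerate(family):
        mapped = set()
        m = mapping[k] if mapping is not None else None
        for a, b in interactions:
            if m is not None:
                for res in (a, b):
                    if res not in m:
                        raise KeyError(
                            f"residue {res} of family structure {k} is unmapped"
                        )
                a, b = m[a], m[b]
            mapped.add(tuple(sorted((a, b))))
        for pair in ref:
            if pair in mapped:
                counts[pair] += 1
    fractions = {pair: counts[pair] / len(family) for pair in ref}
    per_res: dict[int, float] = {}
    for (a, b), f in fractions.items():
        for res in (a, b):
            per_res[res] = max(per_res.get(res, 0.0), f)
    return KINScore(
        per_interaction_fraction=fractions,
        per_residue=per_res,
        conservation_cutoff=conservation_cutoff,
    )


def filter_hotspots(
    kif: KIFScore,
    kin: KINScore | None,
    kif_min: float = 0.1,
    kin_max: float = 0.1,
) -> set[int]:
    """Engineering candidates: importance above ``kif_min`` and conservation
    at most ``kin_max`` (residues missing from the KIN scores count as 0)."""
    kin_scores = kin.per_residue if kin is not None else {}
    return {
        res
        for res, s in kif.per_residue.items()
        if s > kif_min and kin_scores.get(res, 0.0) <= kin_max
    }


# ---------------------------------------------------------------------------
# IO


def read_fingerprint_table(path: str | Path | pd.DataFrame) -> list[InteractionRecord]:
    """Read a long-format fingerprint table
    (``interaction_id,type,res_i,res_j,ensemble,frame,present``)."""
    df = path if isinstance(path, pd.DataFrame) else pd.read_csv(path, sep=None, engine="python")
    required = {"interaction_id", "type", "res_i", "res_j", "ensemble", "frame", "present"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fingerprint table missing columns: {sorted(missing)}")
    records = []
    for iid, grp in df.groupby("interaction_id", sort=False):
        presence = {}
        for ensemble, sub in grp.groupby("ensemble"):
            presence[str(ensemble)] = (
                sub.sort_values("frame")["present"].to_numpy(int).astype(bool)
            )
        first = grp.iloc[0]
        records.append(
            InteractionRecord(
                interaction_id=str(iid),
                type=str(first["type"]),
                res_i=int(first["res_i"]),
                res_j=int(first["res_j"]),
                presence=presence,
            )
        )
    return records
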