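"""Chemical-shift-perturbation (CSP) analysis of a transition-state-analogue titration.

Amide ``1H``/``15N`` shifts of the apo enzyme and of a titration series are
combined into the weighted average perturbation

    delta_avg = sqrt((( 0.4 * dN )**2 + dH**2) / 2)

which is standardized per experiment into a Z-score,

    Z = (delta_avg - mu) / sigma,

with ``mu``/``sigma`` the mean and (population) standard deviation over all
assigned residues.  Residues with ``Z >= 1`` are called catalysis hotspots;
a geometric classifier then sorts hotspots into active-site / shell / distal
sets relative to a ligand reference point.

Missing assignments (prolines, overlapped or broadened cross-peaks)
propagate as missing values and never contribute a zero CSP.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NITROGEN_WEIGHT",
    "TitrationDataset",
    "StructureAnnotation",
    "CSPResult",
    "delta_avg",
    "compute_delta_avg",
    "z_scores",
    "call_hotspots",
    "classify_hotspots",
    "analyze_titration",
    "read_shift_table",
    "write_shift_table",
]

#: Scaling applied to 15N shift differences before combining with 1H.
NITROGEN_WEIGHT = 0.4

APO = "apo"

_SHIFT_COLUMNS = ["residue_index", "residue_name", "atom", "shift_ppm", "condition"]


class TitrationDataset:
    """Apo + per-ratio amide shifts sharing one residue index space.

    Wraps a long-format table with columns
    ``residue_index, residue_name, atom, shift_ppm, condition`` where
    ``atom`` is ``H`` or ``N`` and ``condition`` is ``"apo"`` or the
    ligand:protein molar ratio as a string.
    """

    def __init__(self, table: pd.DataFrame, conditions: Sequence[str] | None = None):
        missing = set(_SHIFT_COLUMNS) - set(table.columns)
        if missing:
            raise ValueError(f"shift table missing columns: {sorted(missing)}")
        table = table.copy()
        table["condition"] = table["condition"].astype(str)
        if conditions is None:
            ligand = sorted(
                (c for c in table["condition"].unique() if c != APO),
                key=float,
            )
            conditions = [APO] + ligand
        self.conditions = list(conditions)
        if APO not in self.conditions:
            raise ValueError("titration dataset requires an 'apo' condition")
        if len(self.conditions) < 2:
            raise ValueError("titration dataset requires at least one ligand condition")
        dup = table.duplicated(subset=["residue_index", "atom", "condition"])
        if dup.any():
            raise ValueError("duplicate (residue, atom, condition) records")
        self.table = table

    @property
    def ligand_conditions(self) -> list[str]:
        return [c for c in self.conditions if c != APO]

    @property
    def endpoint(self) -> str:
        """Highest-ratio condition (the CSP endpoint)."""
        return self.ligand_conditions[-1]

    def shifts(self, condition: str) -> pd.DataFrame:
        """Wide per-residue table with ``shift_H``/``shift_N`` columns."""
        sub = self.table[self.table["condition"] == condition]
        wide = sub.pivot(index="residue_index", columns="atom", values="shift_ppm")
        wide = wide.rename(columns={"H": "shift_H", "N": "shift_N"})
        return wide.reindex(columns=["shift_H", "shift_N"])

    def residues(self) -> list[int]:
        return sorted(self.table["residue_index"].unique())


@dataclass
class StructureAnnotation:
    """Per-residue heavy-atom coordinates and a ligand/active-site reference point.

    ``ca``: residue -> Calpha coordinate (angstrom);
    ``side_chain``: residue -> (n_atoms, 3) side-chain heavy-atom coordinates;
    ``reference``: active-site reference point (e.g. bound-analogue centroid).
    """

    ca: Mapping[int, np.ndarray]
    side_chain: Mapping[int, np.ndarray]
    reference: np.ndarray
    secondary_structure: Mapping[int, str] = field(default_factory=dict)

    @classmethod
    def from_pdb(
        cls,
        path: str | Path,
        reference: np.ndarray | None = None,
        ligand_resname: str | None = None,
        chain: str | None = None,
    ) -> "StructureAnnotation":
        """Build an annotation from a PDB file (first model).

        The reference point is either given explicitly or taken as the
        centroid of heavy atoms of ``ligand_resname`` (HETATM residue).
        """
        from Bio.PDB import PDBParser

        parser = PDBParser(QUIET=True)
        model = next(parser.get_structure("annot", str(path)).get_models())
        backbone = {"N", "CA", "C", "O", "OXT"}
        ca: dict[int, np.ndarray] = {}
        side: dict[int, np.ndarray] = {}
        lig_atoms = []
        for ch in model:
            if chain is not None and ch.id != chain:
                continue
            for res in ch:
                het = res.id[0].strip()
                if het:  # heteroatom record
                    if ligand_resname is not None and res.resname.strip() == ligand_resname:
                        lig_atoms.extend(
                            a.coord for a in res if a.element != "H"
                        )
                    continue
                idx = res.id[1]
                sc = [
                    a.coord
                    for a in res
                    if a.element != "H" and a.get_name() not in backbone
                ]
                if "CA" in res:
                    ca[idx] = np.asarray(res["CA"].coord, float)
                if sc:
                    side[idx] = np.asarray(sc, float)
        if reference is None:
            if not lig_atoms:
                raise ValueError(
                    "no reference point: pass `reference` or a ligand_resname present in the PDB"
                )
            reference = np.mean(np.asarray(lig_atoms, float), axis=0)
        return cls(ca=ca, side_chain=side, reference=np.asarray(reference, float))


@dataclass
class CSPResult:
    """Per-residue CSP summary."""

    residue_index: int
    delta_avg: float  # ppm; NaN when unassigned
    z: float  # NaN when unassigned
    assigned: bool
    hotspot: bool
    set_label: str = "unclassified"

    def to_dict(self) -> dict:
        return {
            "residue_index": self.residue_index,
            "delta_avg": None if math.isnan(self.delta_avg) else self.delta_avg,
            "z": None if math.isnan(self.z) else self.z,
            "assigned": self.assigned,
            "hotspot": self.hotspot,
            "set_label": self.set_label,
        }


def delta_avg(dH: float, dN: float) -> float:
    """Weighted-average amide CSP (ppm) from 1H and 15N shift differences.

    Returns NaN when either input is missing; symmetric under sign flips.
    """
    dH = float(dH) if dH is not None else math.nan
    dN = float(dN) if dN is not None else math.nan
    if math.isnan(dH) or math.isnan(dN):
        return math.nan
    return math.sqrt(((NITROGEN_WEIGHT * dN) ** 2 + dH**2) / 2.0)


def compute_delta_avg(
    dataset: TitrationDataset, condition: str | None = None
) -> pd.Series:
    """Per-residue delta_avg between apo and a ligand condition.

    By default the endpoint (highest-ratio) condition is used; residues
    missing either the apo or the bound assignment come out as NaN.
    """
    condition = condition or dataset.endpoint
    if condition not in dataset.ligand_conditions:
        raise ValueError(f"unknown ligand condition {condition!r}")
    apo = dataset.shifts(APO)
    bound = dataset.shifts(condition)
    idx = sorted(set(apo.index) | set(bound.index))
    apo = apo.reindex(idx)
    bound = bound.reindex(idx)
    dH = bound["shift_H"] - apo["shift_H"]
    dN = bound["shift_N"] - apo["shift_N"]
    out = pd.Series(
        [delta_avg(h, n) for h, n in zip(dH, dN)], index=idx, name="delta_avg"
    )
    out.index.name = "residue_index"
    return out


def z_scores(delta_avgs: Mapping[int, float] | pd.Series, ddof: int = 0) -> pd.Series:
    """Standardize per-residue delta_avg values into Z-scores.

    Unassigned residues (NaN) are excluded from the mean/sigma and from the
    output.  ``ddof=0`` (population sigma) is the default standardization
    convention; pass ``ddof=1`` for the sample estimator.
    """
    s = pd.Series(delta_avgs, dtype=float).dropna()
    if len(s) < 2:
        raise ValueError("need at least 2 assigned residues to standardize")
    sigma = float(s.std(ddof=ddof))
    # guard against identical values whose mean subtraction leaves rounding dust
    tiny = 1e-12 * max(float(np.max(np.abs(s))), 1e-300)
    if sigma <= tiny or not math.isfinite(sigma):
        raise ValueError("degenerate perturbation distribution (sigma = 0)")
    z = (s - float(s.mean())) / sigma
    z.name = "z"
    return z


def call_hotspots(z: Mapping[int, float] | pd.Series, threshold: float = 1.0) -> set[int]:
    """Residues whose CSP Z-score meets the (inclusive) threshold."""
    s = pd.Series(z, dtype=float)
    return set(s.index[s >= threshold])


def classify_hotspots(
    residues: Iterable[int],
    annot: StructureAnnotation,
    r_active: float = 6.0,
    r_shell: float = 10.0,
) -> dict[int, str]:
    """Sort hotspot residues into active-site / shell / distal sets.

    A residue is *active-site* when any side-chain heavy atom lies within
    ``r_active`` of the reference point; otherwise *shell* when its Calpha
    lies within ``r_shell`` (side chain pointing away from the site, as for
    the active-site-wall strand residues); otherwise *distal*.  Residues
    with no coordinates are *unclassified*.
    """
    ref = np.asarray(annot.reference, float)
    out: dict[int, str] = {}
    for res in residues:
        sc = annot.side_chain.get(res)
        ca = annot.ca.get(res)
        if sc is None and ca is None:
            out[res] = "unclassified"
            continue
        if sc is not None and len(sc) > 0:
            d_sc = float(np.min(np.linalg.norm(np.asarray(sc, float) - ref, axis=1)))
            if d_sc <= r_active:
                out[res] = "active-site"
                continue
        if ca is not None:
            if float(np.linalg.norm(np.asarray(ca, float) - ref)) <= r_shell:
                out[res] = "shell"
                continue
            out[res] = "distal"
        else:
            out[res] = "unclassified"
    return out


def analyze_titration(
    dataset: TitrationDataset,
    threshold: float = 1.0,
    annot: StructureAnnotation | None = None,
    condition: str | None = None,
    r_active: float = 6.0,
    r_shell: float = 10.0,
) -> list[CSPResult]:
    """End-to-end CSP analysis: delta_avg -> Z -> hotspots -> structural sets."""
    davg = compute_delta_avg(dataset, condition=condition)
    z = z_scores(davg)
    hot = call_hotspots(z, threshold=threshold)
    labels = (
        classify_hotspots(hot, annot, r_active=r_active, r_shell=r_shell)
        if annot is not None
        else {}
    )
    results = []
    for res in davg.index:
        assigned = not math.isnan(davg[res])
        results.append(
            CSPResult(
                residue_index=int(res),
                delta_avg=float(davg[res]),
                z=float(z[res]) if assigned else math.nan,
                assigned=assigned,
                hotspot=res in hot,
                set_label=labels.get(res, "unclassified"),
            )
        )
    return results


def read_shift_table(path: str | Path) -> TitrationDataset:
    """Read a whitespace/tab-separated shift table (see module docstring)."""
    table = pd.read_csv(path, sep=r"\s+")
    return TitrationDataset(table)


def write_shift_table(dataset: TitrationDataset, path: str | Path) -> None:
    dataset.table.to_csv(path, sep="\t", index=False)


def write_results(results: list[CSPResult], path: str | Path) -> None:
    """Write per-residue results as TSV (``.tsv``) or JSON (anything else)."""
    path = Path(path)
    rows = [r.to_dict() for r in results]
    if path.suffix == ".tsv":
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        path.write_text(json.dumps(rows, indent=2) + "\n")
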