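"""Stability--activity Pareto-front analysis of enzyme variants.

A variant is nondominated when no other variant is at least as good on
every objective and strictly better on one (weak dominance: exact ties on
both objectives are retained, since experimental values carry error).  The
front over (denaturation temperature, activity) summarizes the absence or
presence of a stability--activity trade-off across a designed variant set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["VariantRecord", "pareto_front", "pareto_mask", "fold_range", "read_variant_table"]

VARIANT_COLUMNS = ["variant", "Tm_C", "kcat_s", "kcat_over_KM", "yield"]


@dataclass
class VariantRecord:
    variant_id: str
    Tm: float  # degC
    kcat: float | None = None  # 1/s
    kcat_over_KM: float | None = None  # 1/(M s)
    yield_mg_per_L: float | None = None

    def __post_init__(self):
        if not np.isfinite(self.Tm):
            raise ValueError("Tm must be finite")
        if self.kcat is None and self.kcat_over_KM is None:
            raise ValueError("at least one activity measure is required")


def pareto_mask(points: np.ndarray) -> np.ndarray:
    """Boolean mask of nondominated rows (all objectives maximized).

    Point i is dominated when some j is >= i on every column and > i on at
    least one; works for any number of objectives.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[0] == 0:
        raise ValueError("need a non-empty 2-D array of points")
    n = pts.shape[0]
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        ge = np.all(pts >= pts[i], axis=1)
        gt = np.any(pts > pts[i], axis=1)
        if np.any(ge & gt):
            mask[i] = False
    return mask


def pareto_front(points: Sequence[tuple[float, ...]]) -> list[tuple[float, ...]]:
    """Nondominated subset (both objectives maximized), sorted by the first
    objective for a stable presentation order."""
    pts = np.asarray(list(points), float)
    mask = pareto_mask(pts)
    front = [tuple(p) for p in pts[mask]]
    return sorted(front, key=lambda p: p[0])


def fold_range(activities: Sequence[float]) -> float:
    """max/min ratio of a positive activity list (the modulation range)."""
    arr = np.asarray(list(activities), float)
    if arr.size == 0:
        raise ValueError("empty activity list")
    if np.any(arr <= 0):
        raise ValueError("activities must be positive")
    return float(arr.max() / arr.min())


def read_variant_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"variant", "Tm_C"} - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    if not {"kcat_s", "kcat_over_KM"} & set(df.columns):
        raise ValueError("variant table needs kcat_s and/or kcat_over_KM")
    return df


def analyze_variants(df: pd.DataFrame) -> dict:
    """Front membership per (Tm, activity) objective pair plus fold ranges."""
    out: dict = {"variants": list(df["variant"])}
    for act in ("kcat_s", "kcat_over_KM"):
        if act not in df.columns:
            continue
        sub = df.dropna(subset=["Tm_C", act])
        mask = pareto_mask(sub[["Tm_C", act]].to_numpy(float))
        out[f"front_Tm_vs_{act}"] = list(sub.loc[mask, "variant"])
        vals = sub[act].to_numpy(float)
        if vals.size and np.all(vals > 0):
            out[f"fold_range_{act}"] = fold_range(vals)
    return out


def write_front_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
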