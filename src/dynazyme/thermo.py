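"""Transition-state-theory free energies and conformation--activity correlations.

The measured turnover number maps onto an apparent activation free energy
through the Eyring relation with unit transmission coefficient,

    dG_act = R T ln( (k_B T / h) / kcat ),

so a 10-fold gain in kcat lowers the barrier by R T ln 10 (~1.36 kcal/mol
at 298.15 K).  Pearson correlations between the substrate IN/OUT occupancy
fractions and these experimental barriers quantify how strongly the
productive-pose population tracks catalytic performance; because the
correlation is affine-invariant in ln kcat, the (unstated) prefactor
convention cannot change it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import constants, stats

__all__ = [
    "R_KCAL",
    "FreeEnergyRecord",
    "eyring_prefactor",
    "eyring_dg",
    "kcat_from_dg",
    "pearson",
    "correlate_fractions",
    "read_free_energy_table",
]

#: Gas constant in kcal/(mol K).
R_KCAL = constants.R / (constants.calorie * 1000.0)

DEFAULT_T = 298.15  # K; assays at 25 degC


@dataclass
class FreeEnergyRecord:
    variant_id: str
    kcat: float  # 1/s
    T: float = DEFAULT_T  # K
    pct_in: float | None = None
    pct_out: float | None = None
    dG_calc: float | None = None  # kcal/mol, external (e.g. EVB) estimate

    def __post_init__(self):
        if self.pct_in is not None and self.pct_out is not None:
            if not math.isclose(self.pct_in + self.pct_out, 100.0, abs_tol=1e-6):
                raise ValueError("pct_in + pct_out must equal 100")

    @property
    def dG_exp(self) -> float:
        return eyring_dg(self.kcat, self.T)


def eyring_prefactor(T: float = DEFAULT_T) -> float:
    """k_B T / h in 1/s."""
    return constants.k * T / constants.h


def eyring_dg(kcat: float, T: float = DEFAULT_T) -> float:
    """Apparent activation free energy (kcal/mol) from a rate constant."""
    if not (kcat > 0 and T > 0):
        raise ValueError("kcat and T must be positive")
    return R_KCAL * T * math.log(eyring_prefactor(T) / kcat)


def kcat_from_dg(dG: float, T: float = DEFAULT_T) -> float:
    """Inverse of :func:`eyring_dg`."""
    if not T > 0:
        raise ValueError("T must be positive")
    return eyring_prefactor(T) * math.exp(-dG / (R_KCAL * T))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient with strict input validation."""
    x = np.asarray(list(x), float)
    y = np.asarray(list(y), float)
    if x.size != y.size:
        raise ValueError("series lengths differ")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in an input series")
    return float(stats.pearsonr(x, y).statistic)


def correlate_fractions(
    records: Sequence[FreeEnergyRecord] | pd.DataFrame,
) -> tuple[float, float]:
    """(r_in, r_out): correlations of %IN and %OUT with experimental dG_act.

    Accepts records or a table with columns ``kcat_s, pct_in, pct_out`` and
    optionally ``T_K``.  Complementary fractions give r_in = -r_out
    exactly.
    """
    if isinstance(records, pd.DataFrame):
        records = [
            FreeEnergyRecord(
                variant_id=str(row.get("variant", i)),
                kcat=float(row["kcat_s"]),
                T=float(row.get("T_K", DEFAULT_T)),
                pct_in=float(row["pct_in"]),
                pct_out=float(row["pct_out"]),
            )
            for i, row in records.iterrows()
        ]
    complete = [r for r in records if r.pct_in is not None and r.pct_out is not None]
    if len(complete) < 3:
        raise ValueError("need at least 3 complete records")
    dG = [r.dG_exp for r in complete]
    r_in = pearson([r.pct_in for r in complete], dG)
    r_out = pearson([r.pct_out for r in complete], dG)
    return r_in, r_out


def read_free_energy_table(path: str | Path) -> list[FreeEnergyRecord]:
    """CSV ``variant,kcat_s,T_K,pct_in,pct_out,dG_calc_kcal`` (last column
    optional, e.g. transcribed external EVB estimates)."""
    df = pd.read_csv(path)
    missing = {"variant", "kcat_s"} - set(df.columns)
    if missing:
        raise ValueError(f"free-energy table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        def opt(col):
            if col in df.columns and pd.notna(row[col]):
                return float(row[col])
            return None

        out.append(
            FreeEnergyRecord(
                variant_id=str(row["variant"]),
                kcat=float(row["kcat_s"]),
                T=opt("T_K") or DEFAULT_T,
                pct_in=opt("pct_in"),
                pct_out=opt("pct_out"),
                dG_calc=opt("dG_calc_kcal"),
            )
        )
    return out
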