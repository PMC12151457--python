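"""Seeded synthetic-data generators for every pipeline input modality.

Each generator takes an explicit ground-truth dataclass carrying an integer
seed and returns the same in-memory containers (and on-disk formats) the
analysis modules consume, so the whole pipeline is testable without any
experimental download:

* fast-exchange CSP titrations with exact single-site 1:1 binding
  (quadratic solution, not the weak-binding approximation — ligand ratios
  up to ~2 equivalents are not in excess);
* Michaelis--Menten rate tables with a titratable-base pH dependence
  (optionally a pKa mixture) and multiplicative (CV) noise;
* two-state (IN/OUT) substrate pseudo-dihedral series from a stationary
  Markov chain, so autocorrelation is representable;
* state-dependent Bernoulli interaction fingerprints (apo vs holo).

All randomness flows through ``numpy.random.default_rng(seed)``; identical
ground truth + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .csp import TitrationDataset

__all__ = [
    "TitrationGroundTruth",
    "KineticGroundTruth",
    "TwoStateTrajGroundTruth",
    "FingerprintGroundTruth",
    "fraction_bound",
    "gen_titration_shifts",
    "gen_kinetic_data",
    "gen_two_state_angles",
    "gen_fingerprints",
    "angles_to_trajectory",
    "gen_angle_mixture",
]

_AA3 = (  # proline excluded: no amide cross-peak
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE "
    "LEU LYS MET PHE SER THR TRP TYR VAL"
).split()


# ---------------------------------------------------------------------------
# titration


@dataclass
class TitrationGroundTruth:
    """Planted truth for a fast-exchange CSP titration.

    ``delta_bound_H``/``delta_bound_N`` are the per-residue full-saturation
    shift changes (ppm).  ``ratios`` are ligand:protein molar ratios in
    strictly increasing order (default: the six-point series
    0.1, 0.14, 0.2, 0.4, 1.1, 2.1).
    """

    n_residues: int
    hotspot_residues: frozenset[int]
    delta_bound_H: np.ndarray
    delta_bound_N: np.ndarray
    Kd: float  # M
    protein_conc: float = 0.4e-3  # M
    ratios: Sequence[float] = (0.1, 0.14, 0.2, 0.4, 1.1, 2.1)
    noise_sd_H: float = 0.0  # ppm
    noise_sd_N: float = 0.0  # ppm
    unassigned_residues: frozenset[int] = frozenset()
    seed: int = 0

    def validate(self) -> None:
        ratios = np.asarray(self.ratios, float)
        if ratios.size == 0 or np.any(np.diff(ratios) <= 0):
            raise ValueError("ratios must be strictly increasing and non-empty")
        if not self.Kd > 0:
            raise ValueError("Kd must be positive")
        if not self.protein_conc > 0:
            raise ValueError("protein_conc must be positive")
        for arr in (self.delta_bound_H, self.delta_bound_N):
            if len(arr) != self.n_residues:
                raise ValueError("delta_bound arrays must have n_residues entries")
        bad = {r for r in self.hotspot_residues if not 1 <= r <= self.n_residues}
        if bad:
            raise ValueError(f"hotspot residues out of range: {sorted(bad)}")

    @classmethod
    def with_planted_hotspots(
        cls,
        n_residues: int = 190,
        n_hotspots: int = 10,
        background_ppm: float = 0.02,
        hotspot_scale: float = 5.0,
        Kd: float = 50e-6,
        noise_sd: float | None = None,
        seed: int = 0,
        **kwargs,
    ) -> "TitrationGroundTruth":
        """Plant ``n_hotspots`` residues with |bound-state shift change|
        ``hotspot_scale`` times the background magnitude.

        ``noise_sd`` defaults to a fifth of the background perturbation.
        """
        rng = np.random.default_rng(seed)
        residues = np.arange(1, n_residues + 1)
        hot = frozenset(
            int(r) for r in rng.choice(residues, size=n_hotspots, replace=False)
        )
        sign = rng.choice([-1.0, 1.0], size=n_residues)
        mag_H = rng.uniform(0.5, 1.5, size=n_residues) * background_ppm
        mag_N = rng.uniform(0.5, 1.5, size=n_residues) * background_ppm / 0.4
        for r in hot:
            mag_H[r - 1] *= hotspot_scale
            mag_N[r - 1] *= hotspot_scale
        if noise_sd is None:
            noise_sd = background_ppm / 5.0
        return cls(
            n_residues=n_residues,
            hotspot_residues=hot,
            delta_bound_H=sign * mag_H,
            delta_bound_N=sign * mag_N,
            Kd=Kd,
            noise_sd_H=noise_sd,
            noise_sd_N=noise_sd / 0.4,
            seed=seed,
            **kwargs,
        )


def fraction_bound(protein_conc: float, ligand_conc: float, Kd: float) -> float:
    """Bound protein fraction for single-site 1:1 binding (exact quadratic).

    Solves ``P*f**2 - (P + L + Kd)*f + L = 0`` for the root in [0, 1], with
    P/L the total protein/ligand concentrations.  ``Kd = 0`` is the
    stoichiometric limit ``min(1, L/P)``.
    """
    P, L = float(protein_conc), float(ligand_conc)
    if P <= 0:
        raise ValueError("protein concentration must be positive")
    if L < 0 or Kd < 0:
        raise ValueError("ligand concentration and Kd must be nonnegative")
    if Kd == 0:
        return min(1.0, L / P)
    b = P + L + Kd
    disc = b * b - 4.0 * P * L
    f = (b - np.sqrt(disc)) / (2.0 * P)
    return float(min(max(f, 0.0), 1.0))


def gen_titration_shifts(gt: TitrationGroundTruth) -> TitrationDataset:
    """Simulate apo + titration-series amide shifts under fast exchange.

    The observed shift at each ratio is the population-weighted average
    ``apo + f_bound * delta_bound`` plus Gaussian ppm noise.
    """
    gt.validate()
    rng = np.random.default_rng(gt.seed)
    n = gt.n_residues
    apo_H = rng.normal(8.3, 0.45, size=n)
    apo_N = rng.normal(119.0, 4.0, size=n)
    names = rng.choice(_AA3, size=n)
    rows = []
    keep = [r for r in range(1, n + 1) if r not in gt.unassigned_residues]

    def emit(condition, shifts_H, shifts_N):
        for r in keep:
            rows.append((r, names[r - 1], "H", shifts_H[r - 1], condition))
            rows.append((r, names[r - 1], "N", shifts_N[r - 1], condition))

    emit("apo", apo_H, apo_N)
    for ratio in gt.ratios:
        f = fraction_bound(gt.protein_conc, ratio * gt.protein_conc, gt.Kd)
        obs_H = apo_H + f * np.asarray(gt.delta_bound_H, float)
        obs_N = apo_N + f * np.asarray(gt.delta_bound_N, float)
        if gt.noise_sd_H > 0:
            obs_H = obs_H + rng.normal(0.0, gt.noise_sd_H, size=n)
        if gt.noise_sd_N > 0:
            obs_N = obs_N + rng.normal(0.0, gt.noise_sd_N, size=n)
        emit(str(ratio), obs_H, obs_N)
    table = pd.DataFrame(
        rows, columns=["residue_index", "residue_name", "atom", "shift_ppm", "condition"]
    )
    return TitrationDataset(table)


# ---------------------------------------------------------------------------
# kinetics


@dataclass
class KineticGroundTruth:
    """Planted truth for Michaelis--Menten rate tables with pH dependence.

    ``kcat(pH) = kcat0 * sum_i w_i * 10**(pH - pKa_i) / (1 + 10**(pH - pKa_i))``
    so a single-component list reduces to the one-base titration model.
    """

    kcat0: float = 1700.0  # 1/s, limiting turnover at high pH
    KM: float = 2e-3  # M
    pKa_list: Sequence[float] = (7.0,)
    weights: Sequence[float] = (1.0,)
    pH_grid: Sequence[float] = (6.0, 6.5, 7.0, 7.5, 8.0, 8.5)
    # serial-dilution design spanning ~0.1-10 x KM (geometric spacing)
    substrate_grid: Sequence[float] = tuple(np.geomspace(0.2e-3, 20e-3, 10))
    E0: float = 1e-8  # M
    noise_cv: float = 0.0
    n_replicates: int = 2  # independent preparations
    variant: str = "synthetic"
    seed: int = 0

    def validate(self) -> None:
        w = np.asarray(self.weights, float)
        if len(w) != len(self.pKa_list):
            raise ValueError("weights and pKa_list lengths differ")
        if not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must sum to 1")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if len(self.pH_grid) == 0 or len(self.substrate_grid) == 0:
            raise ValueError("pH and substrate grids must be non-empty")
        if np.any(np.asarray(self.substrate_grid, float) <= 0):
            raise ValueError("substrate concentrations must be positive")
        if not (self.kcat0 > 0 and self.KM > 0 and self.E0 > 0):
            raise ValueError("kcat0, KM and E0 must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def kcat_at(self, pH: np.ndarray | float) -> np.ndarray | float:
        """Turnover number at a given pH under the (mixture) titration model."""
        pH = np.asarray(pH, float)
        total = np.zeros_like(pH, dtype=float)
        for w, pka in zip(self.weights, self.pKa_list):
            x = 10.0 ** (pH - pka)
            total = total + w * x / (1.0 + x)
        out = self.kcat0 * total
        return float(out) if out.ndim == 0 else out


def gen_kinetic_data(gt: KineticGroundTruth) -> pd.DataFrame:
    """Rate table (columns ``variant,pH,substrate_M,E0_M,v_Ms,replicate``)."""
    gt.validate()
    rng = np.random.default_rng(gt.seed)
    rows = []
    for pH in gt.pH_grid:
        kcat = gt.kcat_at(pH)
        for rep in range(1, gt.n_replicates + 1):
            for S in gt.substrate_grid:
                v = gt.E0 * kcat * S / (gt.KM + S)
                if gt.noise_cv > 0:
                    v *= 1.0 + gt.noise_cv * rng.standard_normal()
                rows.append((gt.variant, pH, S, gt.E0, max(v, 0.0), rep))
    return pd.DataFrame(
        rows, columns=["variant", "pH", "substrate_M", "E0_M", "v_Ms", "replicate"]
    )


# ---------------------------------------------------------------------------
# two-state trajectories


@dataclass
class TwoStateTrajGroundTruth:
    """Planted truth for IN/OUT substrate-orientation dynamics.

    A two-state Markov chain with stationary IN probability ``f_in_target``
    and per-frame mixing rate ``transition_prob`` (1 = i.i.d. frames);
    IN angles live in (51, 180] degrees, OUT angles in [-180, 50].
    """

    f_in_target: float
    n_frames: int
    transition_prob: float = 1.0
    angle_jitter_sd: float = 10.0  # degrees
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.f_in_target <= 1.0:
            raise ValueError("f_in_target must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if not 0.0 < self.transition_prob <= 1.0:
            raise ValueError("transition_prob must lie in (0, 1]")


_IN_RANGE = (51.0, 180.0)
_OUT_RANGE = (-180.0, 50.0)


def gen_two_state_angles(
    gt: TwoStateTrajGroundTruth,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate per-frame state labels and pseudo-dihedral angles.

    Returns ``(labels, angles)`` with labels a boolean array (True = IN)
    and angles in degrees, consistent with the IN-iff-angle>50 rule.
    """
    gt.validate()
    rng = np.random.default_rng(gt.seed)
    f, c = gt.f_in_target, gt.transition_prob
    # transition probabilities chosen so the stationary IN fraction is f
    p_out_to_in = c * f
    p_in_to_out = c * (1.0 - f)
    labels = np.empty(gt.n_frames, dtype=bool)
    labels[0] = rng.random() < f
    u = rng.random(gt.n_frames)
    for i in range(1, gt.n_frames):
        if labels[i - 1]:
            labels[i] = u[i] >= p_in_to_out
        else:
            labels[i] = u[i] < p_out_to_in
    angles = np.empty(gt.n_frames, dtype=float)
    for state, (lo, hi) in ((True, _IN_RANGE), (False, _OUT_RANGE)):
        mask = labels == state
        k = int(mask.sum())
        if k == 0:
            continue
        base = rng.uniform(lo, hi, size=k)
        jit = rng.normal(0.0, gt.angle_jitter_sd, size=k) if gt.angle_jitter_sd > 0 else 0.0
        angles[mask] = np.clip(base + jit, lo, hi)
    return labels, angles


def angles_to_trajectory(angles: np.ndarray):
    """Embed a pseudo-dihedral series as 4-atom Cartesian frames.

    Atoms are ``(229, CA)``, ``(400, C1)``, ``(400, N1)``, ``(287, CA)``
    (two anchoring Calpha atoms plus two substrate atoms); the torsion over
    them reproduces the input angles exactly, which makes the result a
    convenient fixture for the trajectory readers and dihedral code.
    """
    from .conformers import Trajectory

    angles = np.asarray(angles, float)
    rad = np.deg2rad(angles)
    n = angles.size
    coords = np.empty((n, 4, 3), float)
    coords[:, 0] = (-0.5, 1.0, 0.0)
    coords[:, 1] = (0.0, 0.0, 0.0)
    coords[:, 2] = (1.0, 0.0, 0.0)
    coords[:, 3, 0] = 1.2
    coords[:, 3, 1] = np.cos(rad)
    coords[:, 3, 2] = np.sin(rad)
    topology = pd.DataFrame(
        {
            "residue_index": [229, 400, 400, 287],
            "residue_name": ["ASP", "SUB", "SUB", "VAL"],
            "atom_name": ["CA", "C1", "N1", "CA"],
        }
    )
    return Trajectory(topology=topology, coords=coords, frame_interval_ps=10.0)


def gen_angle_mixture(
    modes: Sequence[float],
    jitter_sd: float,
    n_frames: int,
    weights: Sequence[float] | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Angles (degrees, wrapped to (-180, 180]) from a von-Mises-like mixture.

    Used to emulate multi-modal side-chain rotamer distributions.
    """
    rng = np.random.default_rng(seed)
    modes = np.asarray(modes, float)
    if weights is None:
        weights = np.full(modes.size, 1.0 / modes.size)
    which = rng.choice(modes.size, size=n_frames, p=np.asarray(weights, float))
    ang = modes[which] + rng.normal(0.0, jitter_sd, size=n_frames)
    ang = np.mod(ang + 180.0, 360.0) - 180.0
    ang[ang == -180.0] = 180.0
    return ang


# ---------------------------------------------------------------------------
# interaction fingerprints


@dataclass
class FingerprintGroundTruth:
    """Planted truth for apo/holo Bernoulli interaction fingerprints."""

    n_interactions: int
    p_holo: np.ndarray
    p_apo: np.ndarray
    n_frames_per_state: int
    residue_map: Sequence[tuple[int, int]] = field(default_factory=list)
    interaction_types: Sequence[str] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        for p in (self.p_holo, self.p_apo):
            p = np.asarray(p, float)
            if len(p) != self.n_interactions:
                raise ValueError("presence-probability arrays must match n_interactions")
            if np.any((p < 0) | (p > 1)):
                raise ValueError("presence probabilities must lie in [0, 1]")
        if self.residue_map and len(self.residue_map) != self.n_interactions:
            raise ValueError("residue_map must cover every interaction")
        if self.n_frames_per_state < 1:
            raise ValueError("n_frames_per_state must be >= 1")

    @classmethod
    def with_planted_interaction(
        cls,
        n_null: int = 50,
        p_holo: float = 0.9,
        p_apo: float = 0.1,
        p_null: float = 0.6,
        n_frames_per_state: int = 10_000,
        seed: int = 0,
    ) -> "FingerprintGroundTruth":
        """One state-discriminating interaction among ``n_null`` null ones.

        Null interactions share the same presence probability in both
        ensembles, so only the planted contact carries ligand-state signal.
        """
        n = n_null + 1
        ph = np.full(n, p_null)
        pa = np.full(n, p_null)
        ph[0], pa[0] = p_holo, p_apo
        rng = np.random.default_rng(seed)
        residues = []
        used = {(1, 2)}
        residues.append((1, 2))  # the planted contact
        while len(residues) < n:
            pair = tuple(sorted(rng.integers(3, 3 + 2 * n, size=2)))
            if pair[0] != pair[1] and pair not in used:
                used.add(pair)
                residues.append(pair)
        return cls(
            n_interactions=n,
            p_holo=ph,
            p_apo=pa,
            n_frames_per_state=n_frames_per_state,
            residue_map=residues,
            interaction_types=["hbond"] * n,
            seed=seed,
        )


def gen_fingerprints(gt: FingerprintGroundTruth) -> tuple[np.ndarray, np.ndarray]:
    """Binary fingerprint matrix plus per-frame ensemble labels.

    Returns ``(matrix, labels)`` with matrix of shape
    ``(2 * n_frames_per_state, n_interactions)`` (holo block first) and
    labels an array of ``"holo"``/``"apo"`` strings.
    """
    gt.validate()
    rng = np.random.default_rng(gt.seed)
    m = gt.n_frames_per_state
    holo = rng.random((m, gt.n_interactions)) < np.asarray(gt.p_holo, float)
    apo = rng.random((m, gt.n_interactions)) < np.asarray(gt.p_apo, float)
    matrix = np.vstack([holo, apo])
    labels = np.array(["holo"] * m + ["apo"] * m)
    return matrix, labels


def fingerprints_to_table(
    gt: FingerprintGroundTruth, matrix: np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    """Long-format fingerprint table consumed by the networks module."""
    if not gt.residue_map:
        raise ValueError("ground truth carries no residue_map")
    types = list(gt.interaction_types) or ["hbond"] * gt.n_interactions
    frames = np.concatenate(
        [np.arange((labels == lab).sum()) for lab in ("holo", "apo")]
    )
    rows = []
    for j in range(gt.n_interactions):
        res_i, res_j = gt.residue_map[j]
        for k in range(matrix.shape[0]):
            rows.append(
                (f"int{j}", types[j], res_i, res_j, labels[k], frames[k], int(matrix[k, j]))
            )
    return pd.DataFrame(
        rows,
        columns=["interaction_id", "type", "res_i", "res_j", "ensemble", "frame", "present"],
    )
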