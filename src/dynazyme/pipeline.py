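"""Configuration-driven orchestration of the analysis stages.

A pipeline config (YAML/JSON mapping, see :class:`PipelineConfig`) toggles
stages and names their input files and numeric knobs.  Stages run in
dependency order (csp -> kinetics -> pareto; conformers -> thermo;
networks independent); a stage failure is recorded and isolated so later
independent stages still run.  The run report captures, per stage, the
SHA-256 digests of its inputs, the parameters applied, the outputs
written, and warnings -- every number in a report is traceable to the
config -- and is written atomically with a stable key order, so identical
config + seeds reproduce identical outputs apart from timing metadata.

External variant-design score tables (mutation lists plus predicted
stability scores from a design server) are ingested as plain CSV; the
design step itself is out of scope.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__, conformers, csp, kinetics, networks, pareto, thermo

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "make_demo_inputs"]

STAGE_ORDER = ["csp", "kinetics", "pareto", "conformers", "thermo", "networks"]

_REQUIRED_INPUT = {
    "csp": "shift_table",
    "kinetics": "rate_table",
    "pareto": "variant_table",
    "conformers": "trajectory",
    "thermo": "free_energy_table",
    "networks": "fingerprint_table",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    ``stages`` maps stage name -> stage mapping holding file paths and
    knobs; absent stages are skipped.  Knob defaults match the library
    defaults (Z threshold 1.0, IN/OUT boundary 50 deg, H-bond cutoff 3.5 A,
    occupancy threshold 0.5, KIF threshold 0.1, KIN cutoff 0.5).
    """

    stages: dict[str, dict[str, Any]]
    output_dir: Path
    seed: int = 0
    raw: dict = field(default_factory=dict)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        if "output_dir" not in mapping:
            raise ValueError("config requires an output_dir")
        stages = {k: dict(v or {}) for k, v in (mapping.get("stages") or {}).items()}
        unknown = set(stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        cfg = cls(
            stages=stages,
            output_dir=Path(mapping["output_dir"]),
            seed=int(mapping.get("seed", 0)),
            raw=mapping,
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for stage, spec in self.stages.items():
            key = _REQUIRED_INPUT[stage]
            if key not in spec:
                raise ValueError(f"stage {stage!r}: missing required input key {key!r}")
            path = Path(spec[key])
            if not path.exists():
                raise ValueError(f"stage {stage!r}: input file not found: {path}")
            for k, v in spec.items():
                if isinstance(v, str) and k.endswith(("_table", "_pdb", "trajectory", "_file")):
                    if not Path(v).exists():
                        raise ValueError(f"stage {stage!r}: input file not found: {v}")


def load_config(path: str | Path) -> PipelineConfig:
    text = Path(path).read_text()
    mapping = yaml.safe_load(text)
    return PipelineConfig.from_mapping(mapping)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_json(obj: Any, path: Path) -> None:
    """Atomic JSON write with sorted keys."""
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
            fh.write("\n")
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# ---------------------------------------------------------------------------
# stages


def _stage_csp(spec: dict, outdir: Path) -> dict:
    dataset = csp.read_shift_table(spec["shift_table"])
    annot = None
    if "structure_pdb" in spec:
        annot = csp.StructureAnnotation.from_pdb(
            spec["structure_pdb"],
            reference=np.asarray(spec["reference_point"], float)
            if "reference_point" in spec
            else None,
            ligand_resname=spec.get("ligand_resname"),
        )
    results = csp.analyze_titration(
        dataset,
        threshold=float(spec.get("z_threshold", 1.0)),
        annot=annot,
        r_active=float(spec.get("r_active", 6.0)),
        r_shell=float(spec.get("r_shell", 10.0)),
    )
    out = outdir / "csp_results.json"
    _write_json([r.to_dict() for r in results], out)
    hotspots = sorted(r.residue_index for r in results if r.hotspot)
    return {
        "outputs": [str(out)],
        "summary": {
            "n_assigned": sum(r.assigned for r in results),
            "n_hotspots": len(hotspots),
            "hotspots": hotspots,
        },
    }


def _stage_kinetics(spec: dict, outdir: Path) -> dict:
    table = kinetics.read_rate_table(spec["rate_table"])
    fits: dict = {}
    for (variant, pH), grp in table.groupby(["variant", "pH"]):
        fit = kinetics.fit_michaelis(grp)
        fits.setdefault(str(variant), {})[f"{pH:g}"] = fit.to_dict()
    profiles: dict = {}
    for variant, by_pH in fits.items():
        pHs = np.array([float(p) for p in by_pH])
        if pHs.size < 4:
            continue
        order = np.argsort(pHs)
        pHs = pHs[order]
        keys = np.array(list(by_pH))[order]
        prof = {}
        for param in ("kcat", "kcat_over_KM"):
            y = np.log10([by_pH[k][param] for k in keys])
            fit = kinetics.fit_single_pka(pHs, y)
            slope, slope_se = kinetics.loglinear_slope(pHs, y)
            prof[param] = {
                "single_pka_fit": fit.to_dict(),
                "loglinear_slope": slope,
                "loglinear_slope_se": slope_se,
            }
        profiles[variant] = prof
    out = outdir / "kinetics.json"
    _write_json({"michaelis_fits": fits, "ph_profiles": profiles}, out)
    return {"outputs": [str(out)], "summary": {"n_variant_pH_fits": sum(len(v) for v in fits.values())}}


def _stage_pareto(spec: dict, outdir: Path) -> dict:
    df = pareto.read_variant_table(spec["variant_table"])
    report = pareto.analyze_variants(df)
    out = outdir / "pareto.json"
    _write_json(report, out)
    return {"outputs": [str(out)], "summary": report}


def _stage_conformers(spec: dict, outdir: Path) -> dict:
    path = Path(spec["trajectory"])
    if path.suffix.lower() == ".pdb":
        traj = conformers.read_multimodel_pdb(path)
    else:
        traj = conformers.read_coordinate_table(path)
    atoms = [tuple(a) for a in spec.get(
        "dihedral_atoms", [(229, "CA"), (400, "C1"), (400, "N1"), (287, "CA")]
    )]
    dih = conformers.DihedralSpec(atoms=tuple((int(r), str(n)) for r, n in atoms), label="in_out")
    angles = conformers.dihedral_series(traj, dih)
    series = conformers.StateSeries.from_angles(
        angles, boundary=float(spec.get("in_out_boundary", conformers.IN_OUT_BOUNDARY))
    )
    pct_in, pct_out = conformers.state_fractions(series)
    summary: dict[str, Any] = {"pct_in": pct_in, "pct_out": pct_out, "n_frames": traj.n_frames}
    if "hbond" in spec:
        hb = spec["hbond"]
        occ, mean, sd = conformers.hbond_occupancy(
            traj,
            donor=tuple(hb["donor"]),
            acceptors=[tuple(a) for a in hb["acceptors"]],
            cutoff=float(hb.get("cutoff", 3.5)),
        )
        summary["hbond"] = {"occupancy": occ, "mean_distance": mean, "sd_distance": sd}
    out = outdir / "conformers.json"
    _write_json(summary, out)
    series_out = outdir / "state_series.tsv"
    pd.DataFrame(
        {"frame": np.arange(traj.n_frames), "angle_deg": series.angles,
         "state": np.where(series.labels, "IN", "OUT")}
    ).to_csv(series_out, sep="\t", index=False)
    return {"outputs": [str(out), str(series_out)], "summary": summary}


def _stage_thermo(spec: dict, outdir: Path) -> dict:
    records = thermo.read_free_energy_table(spec["free_energy_table"])
    r_in, r_out = thermo.correlate_fractions(records)
    per_variant = {
        r.variant_id: {"dG_exp_kcal": r.dG_exp, "pct_in": r.pct_in, "pct_out": r.pct_out}
        for r in records
    }
    summary = {"r_in": r_in, "r_out": r_out, "per_variant": per_variant}
    both = [r for r in records if r.dG_calc is not None]
    if len(both) >= 3:
        summary["r_calc_vs_exp"] = thermo.pearson(
            [r.dG_calc for r in both], [r.dG_exp for r in both]
        )
    out = outdir / "thermo.json"
    _write_json(summary, out)
    return {"outputs": [str(out)], "summary": summary}


def _stage_networks(spec: dict, outdir: Path) -> dict:
    records = networks.read_fingerprint_table(spec["fingerprint_table"])
    kif = networks.kif_scores(
        records,
        aggregation=spec.get("aggregation", "max"),
        threshold=float(spec.get("kif_threshold", 0.1)),
        min_occupancy=float(spec.get("min_occupancy", 0.5)),
    )
    summary: dict[str, Any] = {
        "per_residue_kif": kif.per_residue,
        "predicted_hotspots": sorted(kif.predicted_hotspots),
    }
    kin = None
    if "family_tables" in spec:
        fam_sets = []
        for p in spec["family_tables"]:
            fam = pd.read_csv(p, sep=r"\s+")
            fam_sets.append([(int(a), int(b)) for a, b in zip(fam["res_i"], fam["res_j"])])
        mapping = None
        if "mapping_table" in spec:
            mp = pd.read_csv(spec["mapping_table"], sep=r"\s+")
            mapping = []
            for k in range(len(fam_sets)):
                sub = mp[mp["family_structure"] == k]
                mapping.append(dict(zip(sub["residue"].astype(int), sub["reference_residue"].astype(int))))
        ref_pairs = {(rec.res_i, rec.res_j) for rec in records}
        kin = networks.kin_conservation(
            ref_pairs, fam_sets, mapping=mapping,
            conservation_cutoff=float(spec.get("kin_cutoff", 0.5)),
        )
        summary["per_residue_kin"] = kin.per_residue
    summary["candidates"] = sorted(
        networks.filter_hotspots(
            kif, kin,
            kif_min=float(spec.get("kif_threshold", 0.1)),
            kin_max=float(spec.get("kin_max", 0.1)),
        )
    )
    out = outdir / "networks.json"
    _write_json(summary, out)
    return {"outputs": [str(out)], "summary": summary}


_STAGE_FUNCS: dict[str, Callable[[dict, Path], dict]] = {
    "csp": _stage_csp,
    "kinetics": _stage_kinetics,
    "pareto": _stage_pareto,
    "conformers": _stage_conformers,
    "thermo": _stage_thermo,
    "networks": _stage_networks,
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute enabled stages and write ``report.json`` into the output dir."""
    config.validate()
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
    }
    t0 = time.monotonic()
    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        spec = config.stages[stage]
        digests = {
            k: _sha256(v)
            for k, v in spec.items()
            if isinstance(v, str) and Path(v).is_file()
        }
        entry: dict[str, Any] = {"parameters": spec, "inputs_sha256": digests}
        t_stage = time.monotonic()
        try:
            entry.update(_STAGE_FUNCS[stage](spec, outdir))
            entry["status"] = "ok"
        except Exception as err:  # isolate stage failures
            entry["status"] = "failed"
            entry["error"] = f"{type(err).__name__}: {err}"
        entry["wall_time_s"] = round(time.monotonic() - t_stage, 3)
        report["stages"][stage] = entry
    report["wall_time_s"] = round(time.monotonic() - t0, 3)
    _write_json(report, outdir / "report.json")
    return report


# ---------------------------------------------------------------------------
# demo inputs


def make_demo_inputs(directory: str | Path, seed: int = 0) -> PipelineConfig:
    """Generate a small all-synthetic input set plus a config covering every
    stage; returns the validated config (also written as ``config.yaml``)."""
    from . import synthetic

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    tgt = synthetic.TitrationGroundTruth.with_planted_hotspots(
        n_residues=60, n_hotspots=4, seed=seed
    )
    csp.write_shift_table(synthetic.gen_titration_shifts(tgt), directory / "shifts.tsv")

    kgt = synthetic.KineticGroundTruth(noise_cv=0.03, variant="V4-4", seed=seed + 1)
    kinetics.write_rate_table(synthetic.gen_kinetic_data(kgt), directory / "rates.csv")

    rng = np.random.default_rng(seed + 2)
    n_var = 12
    variants = pd.DataFrame(
        {
            "variant": [f"var{i}" for i in range(n_var)],
            "Tm_C": rng.uniform(70, 90, n_var).round(1),
            "kcat_s": rng.uniform(30, 1800, n_var).round(0),
            "kcat_over_KM": rng.uniform(1e4, 5e5, n_var).round(0),
            "yield": rng.uniform(5, 40, n_var).round(1),
        }
    )
    variants.to_csv(directory / "variants.csv", index=False)

    sgt = synthetic.TwoStateTrajGroundTruth(
        f_in_target=0.8, n_frames=2000, transition_prob=0.2, seed=seed + 3
    )
    _, angles = synthetic.gen_two_state_angles(sgt)
    traj = synthetic.angles_to_trajectory(angles)
    conformers.write_coordinate_table(traj, directory / "trajectory.tsv")

    fe = pd.DataFrame(
        {
            "variant": ["GNCA4-WT", "GNCA4-12", "V4", "V4-4"],
            "kcat_s": [10.0, 100.0, 600.0, 1700.0],
            "T_K": [298.15] * 4,
            "pct_in": [30.0, 56.0, 66.0, 80.0],
            "pct_out": [70.0, 44.0, 34.0, 20.0],
        }
    )
    fe.to_csv(directory / "free_energy.csv", index=False)

    fgt = synthetic.FingerprintGroundTruth.with_planted_interaction(
        n_null=20, n_frames_per_state=1500, seed=seed + 4
    )
    matrix, labels = synthetic.gen_fingerprints(fgt)
    synthetic.fingerprints_to_table(fgt, matrix, labels).to_csv(
        directory / "fingerprints.tsv", sep="\t", index=False
    )

    mapping = {
        "output_dir": str(directory / "out"),
        "seed": seed,
        "stages": {
            "csp": {"shift_table": str(directory / "shifts.tsv"), "z_threshold": 1.0},
            "kinetics": {"rate_table": str(directory / "rates.csv")},
            "pareto": {"variant_table": str(directory / "variants.csv")},
            "conformers": {"trajectory": str(directory / "trajectory.tsv")},
            "thermo": {"free_energy_table": str(directory / "free_energy.csv")},
            "networks": {"fingerprint_table": str(directory / "fingerprints.tsv")},
        },
    }
    (directory / "config.yaml").write_text(yaml.safe_dump(mapping, sort_keys=True))
    return PipelineConfig.from_mapping(mapping)
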