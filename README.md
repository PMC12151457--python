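# dynazyme

Analysis toolkit for **dynamics-guided enzyme optimization**: it connects
NMR-detected catalysis hotspots, steady-state kinetics, protein stability,
and simulation-derived conformational ensembles into one reproducible
pipeline. It is aimed at protein engineers and biophysicists who optimize
enzymes (the bundled defaults reflect a Kemp eliminase built on an
ancestral β-lactamase scaffold) and want the downstream analysis — not the
spectrometer, calorimeter, or MD engine — handled by tested code.

## What it computes

- **CSP hotspots** (`dynazyme.csp`). From an apo + titration series of
  amide shifts, the weighted perturbation
  Δδ_avg = √(((0.4·Δδ_N)² + Δδ_H²)/2) per residue, its experiment-wide
  Z-score Z = (Δδ_avg − μ)/σ, hotspot calls at Z ≥ 1, and a geometric
  grouping into active-site / shell / distal sets.
- **Kinetics** (`dynazyme.kinetics`). Initial rates from absorbance
  slopes (Beer–Lambert, ε = 15,800 M⁻¹cm⁻¹ default), Michaelis–Menten
  fits v/E₀ = k_cat[S]/(K_M+[S]) with curvature diagnostics, and
  pH-profile modelling with a single titratable catalytic base,
  log₁₀P = log₁₀P₀ + log₁₀(10^(pH−pKa)/(1+10^(pH−pKa))),
  plus a slope diagnostic and a pKa-mixture generalization for profiles a
  single pKa cannot describe.
- **Pareto fronts** (`dynazyme.pareto`). Nondominated variant sets in
  (Tm, activity) space and activity fold-ranges.
- **Conformer statistics** (`dynazyme.conformers`). Signed torsions from
  multi-model PDB or coordinate-table trajectories, substrate IN/OUT
  classification (boundary 50°), state fractions summing to exactly 100%,
  χ1/χ2 joint distributions with rotamer-mode counting, and H-bond
  occupancies (3.5 Å heavy-atom cutoff, closest-acceptor rule).
- **Interaction networks** (`dynazyme.networks`). Per-interaction mutual
  information (bits) between noncovalent-contact presence and ligand state
  (apo/holo), per-residue importance scores with a 0.1 hotspot threshold,
  evolutionary conservation fractions across a structure family with a 50%
  cutoff, and the high-importance/low-conservation engineering filter.
- **Thermodynamics** (`dynazyme.thermo`). Eyring activation free energies
  ΔG‡ = RT·ln((k_BT/h)/k_cat) and Pearson correlations between conformer
  fractions and barriers.
- **Synthetic data** (`dynazyme.synthetic`). Seeded generators for every
  input modality (fast-exchange titrations with exact 1:1 binding,
  Michaelis–Menten + pH rate tables, two-state Markov trajectories,
  Bernoulli fingerprints), so the whole pipeline runs end-to-end with no
  experimental data.

See `docs/methods.md` for models, assumptions, and numerical choices.

## Worked example

The four-variant optimization series (background through best variant)
with turnover numbers k_cat ≈ 10, 100, 600, 1700 s⁻¹ and productive-pose
(IN) populations 30, 56, 66, 80% from simulation:

```python
import pandas as pd
from dynazyme import thermo

variants = pd.DataFrame({
    "variant": ["GNCA4-WT", "GNCA4-12", "V4", "V4-4"],
    "kcat_s": [10.0, 100.0, 600.0, 1700.0],
    "pct_in": [30.0, 56.0, 66.0, 80.0],
    "pct_out": [70.0, 44.0, 34.0, 20.0],
})
for _, row in variants.iterrows():
    print(f"{row.variant:10s} kcat={row.kcat_s:7.0f} /s  "
          f"dG‡={thermo.eyring_dg(row.kcat_s):6.2f} kcal/mol")
r_in, r_out = thermo.correlate_fractions(variants)
print(f"r(%IN, dG‡) = {r_in:+.2f}   r(%OUT, dG‡) = {r_out:+.2f}")
```

prints

```
GNCA4-WT   kcat=     10 /s  dG‡= 16.09 kcal/mol
GNCA4-12   kcat=    100 /s  dG‡= 14.72 kcal/mol
V4         kcat=    600 /s  dG‡= 13.66 kcal/mol
V4-4       kcat=   1700 /s  dG‡= 13.05 kcal/mol
r(%IN, dG‡) = -0.99   r(%OUT, dG‡) = +0.99
```

— the 170-fold rate gain corresponds to a ~3 kcal/mol barrier drop, and
the fraction of time the substrate spends in its productive pose tracks
that barrier almost perfectly: optimization worked by conformational
selection, not by changing the chemistry.

Fitting a noisy synthetic Michaelis profile round-trips the planted
parameters:

```python
from dynazyme import kinetics, synthetic

gt = synthetic.KineticGroundTruth(kcat0=1700.0, KM=2e-3, pKa_list=(7.0,),
                                  pH_grid=(8.5,), noise_cv=0.05, seed=1)
fit = kinetics.fit_michaelis(synthetic.gen_kinetic_data(gt))
print(f"kcat = {fit.kcat:.0f} ± {fit.kcat_se:.0f} /s, "
      f"KM = {fit.KM*1e3:.2f} ± {fit.KM_se*1e3:.2f} mM")
# kcat = 1643 ± 17 /s, KM = 1.98 ± 0.07 mM
```

(the apparent k_cat at pH 8.5 is k_cat0·10^1.5/(1+10^1.5) ≈ 1647 s⁻¹ for a
catalytic base with pKa 7).

## Command line

`dynazyme` exposes thin subcommands over the library: `simulate`, `csp`,
`kinetics`, `ph-fit`, `pareto`, `conformers`, `kif`, `kin`, `correlate`,
`run` (full YAML-configured pipeline with a provenance report), and `demo`
(generate an all-synthetic input set and run every stage):

```sh
dynazyme demo /tmp/dynazyme-demo --seed 0
```

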