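# Methods

`dynazyme` implements the analysis chain used to optimize an enzyme by
targeting its conformational dynamics: NMR-detected catalysis hotspots,
steady-state kinetics with pH-dependence modelling, stability–activity
trade-off analysis, substrate-conformer statistics from simulation
trajectories, interaction-network importance/conservation scoring, and the
correlation of conformer populations with catalytic barriers. This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic-data generators do and do not emulate.

## Chemical-shift-perturbation hotspots (`dynazyme.csp`)

Binding of a transition-state analogue in fast exchange moves each amide
cross-peak by the population-weighted average of its free and bound
positions. The combined ¹H/¹⁵N perturbation per residue is

    Δδ_avg = sqrt(((0.4·Δδ_N)² + Δδ_H²) / 2)

with the conventional 0.4 weighting that compensates for the wider ¹⁵N
shift dispersion. Per experiment, Δδ_avg values are standardized into
Z-scores using the mean and **population** (n-divisor) standard deviation
over all assigned residues; `z_scores(..., ddof=1)` switches to the sample
estimator. Residues with Z ≥ 1 (inclusive) are hotspots. Choices worth
noting:

- Z is computed from the endpoint condition (highest ligand ratio, ~2-fold
  molar excess); intermediate ratios serve only to confirm gradual
  (fast-exchange) shifting.
- Missing assignments (prolines, overlapped/broadened peaks) propagate as
  missing and are excluded from μ and σ — never treated as zero CSP.
- Identical Δδ_avg for all residues is reported as a degenerate
  distribution (σ = 0) rather than producing infinite Z; the σ check uses a
  relative 1e-12 floor so that floating-point dust from identical values
  still raises.

Hotspots are optionally grouped geometrically relative to an active-site
reference point (bound-ligand centroid): *active-site* if any side-chain
heavy atom is within `r_active` (default 6 Å), else *shell* if the Cα is
within `r_shell` (default 10 Å) — capturing wall residues whose side chains
point away from the site — else *distal*. The cutoffs are conventions, and
configurable; the grouping in the underlying study is descriptive, not
quantitative, so this classifier is a proxy.

## Kinetics and pH profiles (`dynazyme.kinetics`)

Initial rates come from least-squares slopes of absorbance traces,
`v = (slope − blank)/(ε·l)` with ε = 15,800 M⁻¹cm⁻¹ by default (product
absorbance at 380 nm). Michaelis–Menten fits minimize unweighted squared
residuals of v/E₀ vs [S] (1/v² weighting available); initial guesses are
kcat ≈ 1.2·max(v/E₀) and KM from the half-max concentration, with a grid of
restarts on failure. Because kcat is only identified when the profile
curves, a fit whose KM ≥ 0.8 × max [S] sets `curvature_detected = False`,
in which case only kcat/KM (≈ the low-[S] slope) should be trusted.

The pH dependence of a catalytic parameter P controlled by one titratable
catalytic base is fitted in log space:

    log10 P(pH) = log10 P0 + log10( 10^(pH−pKa) / (1 + 10^(pH−pKa)) )

monotone increasing, plateauing at log10 P0 above the pKa and approaching
unit slope far below it — so the pKa is the "kink" pH. Fitting is done on
log10 P (matching how such profiles are presented and balancing relative
errors); a fitted pKa more than 3 units outside the observed pH window is
flagged poorly determined (e.g. a pure unit-slope line has no kink to
locate). `loglinear_slope` is the companion diagnostic: an observed slope
clearly below 1 with no plateau is inconsistent with a single pKa.

For that case `fit_pka_ensemble` fits a mixture,
P = Σᵢ wᵢ·P0·frac(pH − pKaᵢ) with simplex-constrained weights (softmax
parametrization, multi-start least squares). The mixture form is this
package's own generalization — motivated by a Michaelis complex populating
conformations whose buried catalytic base is pKa-perturbed to different
extents — and is tagged `model="ensemble"` in its output; AIC and RSS
support comparison against the nested single-pKa model.

## Pareto analysis (`dynazyme.pareto`)

Weak dominance, both objectives maximized: a variant is dropped only if
another is at least as good on both axes and strictly better on one; exact
ties are retained because measured Tm and kcat carry error. Front
membership is invariant under strictly monotone transforms of either axis,
and every excluded point is dominated by some front member (both asserted
in tests, the latter against a brute-force O(n²) oracle).

## Conformer statistics (`dynazyme.conformers`)

Torsions use the signed IUPAC atan2 convention, wrapped to (−180°, 180°]
with −180° mapped to +180°; collinear bond vectors raise rather than
returning an arbitrary angle. The substrate orientation pseudo-dihedral
(anchor Cα — substrate C — substrate N — anchor Cα) classifies frames IN
when the angle exceeds 50° and OUT otherwise. The nominal ranges
(IN 51–180°, OUT −180–50°) leave (50°, 51°) unassigned; a single boundary
at 50° closes the gap and is configurable. State fractions are frame
counts, with %OUT computed as 100 − %IN so the pair sums to exactly 100.

H-bond occupancy uses the heavy-atom donor–acceptor distance only (no
angle term), cutoff 3.5 Å, with the per-frame distance taken as the
minimum over candidate acceptors (side-chain rotation can exchange
chemically equivalent oxygens). Mean/SD distances are computed over bonded
frames only.

χ1/χ2 joint distributions are normalized 2-D histograms on (−180, 180]²
(default 36×36, i.e. 10° bins); metastable rotamer states are counted as
connected components of bins above 5% of the peak density. Connectivity
does not wrap across the ±180° seam, so a mode straddling it is counted
twice — acceptable for side-chain torsions whose rotamers sit near ±60°
and 180°-staggered positions, but worth remembering for seam-centred
distributions.

Trajectories are multi-model PDB (via Biopython) or plain per-frame
coordinate tables; binary MD formats are out of scope for the core so the
dependency footprint stays small.

## Interaction networks (`dynazyme.networks`)

Importance scoring compares noncovalent-interaction fingerprints between
liganded (holo) and unliganded (apo) ensembles. Interactions occupied
< 50% of frames in **both** ensembles are excluded (an AND rule; requiring
50% in each ensemble would delete exactly the state-discriminating
contacts of interest; 50% exactly is retained). Each surviving interaction
is scored by the plug-in mutual information (log base 2) of the 2×2 joint
between its presence series and the ensemble label over pooled frames. No
bias correction is applied; instead the null calibration is quantified
empirically — with identical apo/holo distributions and 10⁴ frames per
state the 99th percentile of per-interaction MI stays below 0.01 bits, so
the 0.1-bit hotspot threshold sits two orders of magnitude above the
estimator bias at the recommended frame counts. Per-residue scores
aggregate by max over the residue's interactions (one strong interaction
suffices; sum is available), and residues scoring > 0.1 are predicted
hotspots.

Geometric detection criteria (used when fingerprints are derived from
structures rather than supplied): H-bond, N/O–N/O heavy-atom pairs ≤ 3.5 Å;
salt bridge, charged side-chain group atoms of oppositely charged residues
≤ 4.0 Å; hydrophobic, side-chain C–C ≤ 4.5 Å between apolar residues
(A, V, L, I, M, F, W, P, Y). The 4.0/4.5 Å values and the apolar set are
common-practice conventions, config-exposed, not measured facts.

Conservation scoring counts the fraction of a homologous structure family
(mapped through a user-supplied residue correspondence; the package does
not compute alignments) forming each reference interaction; interactions
below 50% conservation drop out of the conserved network but remain
reported, and a residue inherits its maximum conservation. The engineering
filter selects residues with importance > 0.1 and conservation ≤ 0.1 —
dynamically coupled to ligand binding yet evolutionarily unconstrained.

## Activation free energies (`dynazyme.thermo`)

ΔG‡ = R·T·ln((k_B·T/h)/kcat), i.e. standard transition-state theory with
unit transmission coefficient, T = 298.15 K by default (25 °C assays).
The prefactor convention is immaterial for the correlation analysis:
Pearson r between a conformer fraction and ΔG‡ is affine-invariant in
ln kcat, which the tests assert explicitly. `correlate_fractions` requires
≥ 3 complete records and returns (r_in, r_out); with complementary
fractions r_in = −r_out to machine precision. For the four-variant
optimization series (kcat ≈ 10, 100, 600, 1700 s⁻¹; %OUT = 70, 44, 34, 20)
this yields r_in = −0.99, r_out = +0.99: the productive (IN) population
tracks the catalytic barrier almost perfectly across a 170-fold rate range.
The %IN/%OUT split of the background variant is quoted in two nearby forms
(69/31 vs 70/30) in the source material; both give −0.99 at two decimals,
and 70/30 is the default here.

## Synthetic data (`dynazyme.synthetic`)

The generators produce inputs with exactly the statistical structure each
stage assumes, with explicit integer seeds and no global random state
(identical ground truth + seed ⇒ byte-identical outputs):

- **Titrations** use the exact single-site 1:1 quadratic binding solution
  (not the weak-binding approximation — at ligand:protein ratios up to
  ~2.1 the ligand is not in excess), six-point ratio series
  0.1…2.1 by default, protein 0.4 mM, Gaussian ppm noise. Hotspots are
  planted with |Δδ_bound| five times background by default; the analogue's
  dissociation constant is not known from the study and is a free
  parameter (default 50 μM). Peak overlap/broadening is *not* emulated —
  unassignable residues are simply omitted.
- **Rate tables** follow v/E₀ = kcat(pH)·[S]/(KM+[S]) with kcat(pH) from
  the (optionally mixture) titration model and multiplicative (CV) noise.
  The default assay design is a geometric (serial-dilution) substrate
  series of 10 concentrations spanning ~0.1–10 × KM with duplicate
  preparations; this mirrors standard practice and makes KM identifiable
  (median recovery error ~3.5% at CV = 5%; a narrow linear single-replicate
  design roughly triples that).
- **Two-state trajectories** are Markov chains with stationary IN fraction
  `f_in_target` and tunable mixing (so autocorrelation can be
  stress-tested), angles drawn uniformly inside each state's range with
  clipped Gaussian jitter. `angles_to_trajectory` embeds a series as
  4-atom Cartesian frames whose pseudo-dihedral reproduces it exactly.
- **Fingerprints** are per-interaction Bernoulli draws with state-dependent
  presence probabilities.

Passing tests on these generators shows the estimators are correct under
the assumed models (fast exchange, Michaelis–Menten, stationary two-state
dynamics, conditionally independent interactions); it does not validate the
models against real spectra, traces, or force-field trajectories, and real
data add baseline drift, exchange broadening, correlated interactions, and
non-stationarity that the generators deliberately omit.

## Problem sizes and determinism

Test-suite and acceptance-script simulations use 10⁵ frames for fraction
recovery, 10⁴ frames/state × 51 interactions × 20 seeds for the MI null,
100 seeded kinetic datasets, and 190-residue titrations — sizes at which
every stochastic check has comfortable margin while the whole suite runs
in a few minutes on one CPU. All stochastic tests are seeded; the pipeline
report excludes timing metadata from its determinism guarantee and records
SHA-256 digests of every input so reruns are hash-comparable.

## Known limitations

- The structural hotspot classifier is a geometric proxy for a descriptive
  grouping; boundary residues can flip sets with the cutoffs.
- The ensemble-pKa mixture is one of several forms consistent with a
  conformationally heterogeneous Michaelis complex; its component count
  must be chosen by the user (AIC only compares supplied candidates).
- Interaction detection ignores hydrogens and angles; donor/acceptor roles
  are not distinguished for H-bonds.
- The MI estimator is uncorrected plug-in; below ~10³ frames/state its
  bias approaches the 0.1 hotspot threshold and results should not be
  trusted at such sizes.
- External design-server tables, external barrier calculations and Tm
  values are consumed as numbers; the package neither designs variants nor
  runs simulations.
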