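# Methods

`reactscreen` implements the downstream computations of a coumarin–Schiff-base
acetylcholinesterase-inhibitor screen: conceptual-DFT reactivity descriptors,
electrostatic-potential (ESP) surface analysis, MD-trajectory stability
metrics, MM/GBSA binding-energy assembly, and dose–response / SAR
summarization. The quantum-chemistry, docking and MD engines that produce the
raw inputs are out of scope; the package consumes their outputs (or seeded
synthetic stand-ins with planted ground truth) and computes everything after
that point.

## Conceptual-DFT descriptors

Global descriptors use the Koopmans-style finite-difference convention,
I = −E_HOMO and A = −E_LUMO (eV), with

- gap = I − A,
- chemical potential μ = −(I + A)/2 and electronegativity X = −μ,
- hardness η = (I − A)/2,
- softness S = 1/(2η),
- electrophilicity ω = μ²/(2η).

This convention set is internally consistent (X = −μ, 2ηS = 1, 2ηω = μ²) and
is the only one in which the anchor values I = 8.29 eV, A = 0.37 eV jointly
give X = 4.33, μ = −4.33, ω = 2.37 eV and S in the 0.126–0.14 eV⁻¹ range; the
alternative η = I − A convention contradicts the softness and
electrophilicity values and is not offered. Raw (unrounded) values are always
retained; 2-decimal rounding is a presentation concern.

Local reactivity uses the condensed Fukui functions over atom-aligned
electron populations q_k of the N, N−1 and N+1 electron states:
f⁻ = q(N) − q(N−1), f⁺ = q(N+1) − q(N), f⁰ = ½[q(N+1) − q(N−1)], dual
descriptor Δf = f⁺ − f⁻, philicity ω_k = ω·f_k, local softness s_k = S·f_k,
and the relative electrophilicity (f⁺/f⁻) / nucleophilicity (f⁻/f⁺) ratios.
Sites with |denominator| < 10⁻⁸ are flagged undefined rather than divided.
Populations (electrons) are the canonical input; natural-charge input is
accepted only with an explicit per-atom reference-electron column
(pop = ref − charge), because whether a population analysis reports
valence-only or all-electron counts cannot be guessed from the file.
Population sums must differ by exactly one electron between adjacent states;
the default tolerance is 10⁻³ e (typical population-analysis print
precision), configurable on the record.

## ESP surface and geometry comparison

The ESP is evaluated in the atomic-monopole approximation
V(r) = Σ_A q_A/|R_A − r| from supplied partial charges — the package has no
electron density, so isodensity-surface extrema from wavefunction-analysis
tools are qualitative references only, never comparison targets. The surface
is a deterministic Fibonacci-lattice dot surface on 1.2× Bondi spheres
(default 5 points/Å²), points strictly inside a neighbor sphere removed,
each surviving point owned by its generating atom; extrema are reported with
positions and owning atoms. kcal/mol values use the Coulomb constant
332.0637 kcal·Å·mol⁻¹·e⁻²; a.u. values use Bohr-scaled distances
(a₀ = 0.529177 Å). Dipoles are computed about the center of nuclear charge
(relevant for ions; identical to any origin for neutral systems) and
converted at 1 e·Å = 4.80320 D.

Internal coordinates are perceived with a covalent-radius criterion
(bond iff d ≤ r_cov(a) + r_cov(b) + 0.4 Å, Pyykkö single-bond radii),
angles over bonded triples, proper dihedrals over bonded quadruples with the
IUPAC sign convention (cross-checked against MDAnalysis during development).
Geometry comparison reports per-class mean absolute errors over the
intersection of direction-normalized coordinate keys; dihedral differences
use the minimal wrapped angular distance, and unmatched keys are counted,
never silently dropped.

## Trajectory metrics

- **Superposition/RMSD**: Kabsch optimal weighted rotation via SVD with
  reflection correction; degenerate selections (< 3 atoms or collinear) fall
  back to translation-only with a warning. RMSD series superpose each frame
  on a reference using an alignment selection and evaluate the RMSD over a
  measurement selection *without refitting*, so ligand-after-protein-fit
  series are expressible. The conventional 3.0 Å acceptability threshold
  yields a per-series stability verdict (on the series mean). No mass
  weighting in RMSD/RMSF (the common analysis-tool default).
- **RMSF**: per-atom fluctuation about the trajectory mean on an aligned
  trajectory; optional residue grouping averages member atoms.
- **Rg**: mass-weighted radius of gyration (physical definition).
- **SASA**: Shrake–Rupley with Bondi radii, 1.4 Å probe, 960 golden-spiral
  points per atom (all configurable), neighbor search via a k-d tree. As a
  finite point-sample estimate it is rotation-invariant only to the sampling
  resolution (≈ 0.1–0.5 % at 960 points), not machine precision.
- **Hydrogen bonds**: donor–acceptor heavy-atom distance ≤ rcut (3.0 Å) and
  D–H···A deviation from linearity ≤ angle cut (10°), i.e. ∠DHA ≥ 170° — the
  angle-cut semantics of common trajectory viewers; a 10° *absolute* D–H···A
  angle would be geometrically nonsensical. Donors default to N/O with at
  least one perceived bonded hydrogen (hydrogen-less donors are excluded
  with a warning); both cutoff comparisons are boundary-inclusive within
  10⁻⁹ so exactly-at-cutoff geometries classify as bonded.
- **Contact frequency**: a residue contacts the ligand in a frame iff any
  residue heavy atom is within 4.0 Å of any ligand heavy atom; frequency is
  contact frames over total frames. Heavy-atom-only counting is a choice the
  upstream tooling leaves unstated.

Series summaries use the sample (n−1) standard deviation.

## Binding-energy assembly

Per frame and per component, Δc = c_complex − c_receptor − c_ligand, and
ΔG_bind from the totals (sum of components when no total column is given);
snapshot statistics are mean, sample std and standard error. The
single-trajectory approximation (shared frames for the three entities) is
assumed; the assembly is agnostic to which components the table carries and
excludes any entropy term. The optional nonpolar term g_sa = γ·SASA + β uses
the conventional γ = 0.00542 kcal·mol⁻¹·Å⁻², β = 0.92 kcal·mol⁻¹, both
exposed. Complex comparison ranks by mean ΔG (most negative first) with a
per-component contribution table.

## Dose–response and SAR

The 4PL model in log₁₀-concentration form,
y = bottom + (top − bottom)/(1 + 10^((log₁₀IC50 − log₁₀c)·hill)), is fitted
by bounded least squares (0 ≤ bottom ≤ top ≤ 110 %, 0.1 ≤ hill ≤ 10) with
deterministic multistart: five log-spaced IC50 guesses across the tested
range × hill ∈ {0.5, 1, 2}, plus a data-driven half-response guess; the best
RSS wins. A mean-response range below 20 percentage points is rejected as
"no dose response". Standard errors come from the Jacobian-based residual
covariance; IC50 SE by the delta method. IC50 class comparisons use
geometric means (IC50s are log-distributed). Monoisotopic masses use the
most-abundant-isotope table (via rdkit) and reproduce HRMS "calcd." values
at 4 dp; such values are neutral monoisotopic masses even when labelled
[M+H]⁺, and an optional flag adds one proton mass (1.00728 amu).
Concentration conversion µM ↔ µg/mL requires a molecular weight. The oral
bioavailability flag uses the strict window 0 < Log P < 5.

## Synthetic-data generators

The generators emulate the *statistical structure* of each upstream engine,
nothing more: planted Fukui vectors (populations constructed so the
condensed differences equal the plant exactly), uniform random rigid
motions (quaternion) plus i.i.d. Gaussian coordinate noise for
trajectories, per-frame binding deltas N(μ, σ²) split across components in
fixed proportions, 4PL responses with multiplicative Gaussian noise, and a
donor–hydrogen–acceptor triple constructed at an exact distance and
deviation from linearity (root-found, asserted to 10⁻⁶ deg). One integer
seed plus a fixed per-generator stream tag feeds `numpy.random.default_rng`,
so adding a generator never perturbs another's draws and every output is
byte-reproducible. Default conditions follow the study scale: σ = 0.5 Å
noise on 200 atoms × 200 frames for trajectory validation, ΔG means of
−36.042/−23.645 kcal/mol over 100 frames, IC50s at 0.190–1.142 µM with 2 %
multiplicative noise and 3 replicates, 8 log-spaced concentrations spanning
±2 decades.

What passing tests on synthetic data do **not** show: recovery of any real
trajectory's RMSD values (real MD noise is correlated, not i.i.d.), real GB
component distributions (correlated across frames and components), or real
assay heteroscedasticity beyond the multiplicative model. They do show that
every assembly, estimator and classifier is correct on data whose truth is
known exactly.

## Numerical choices and limitations

- Element data (masses, atomic numbers) from rdkit's periodic table; Bondi
  vdW and Pyykkö covalent radii as small literature tables with rdkit
  fallback, then 2.0 Å with a warning.
- Descriptor ordering strings group values within a tolerance (default
  0.005) as ties, ties broken lexicographically for deterministic output.
- Parsers never silently drop records; malformed input errors name the line
  or frame.
- The pipeline runner isolates failures per compound and echoes every
  parameter used into a provenance block; re-running an identical
  configuration is byte-identical.
- Problem sizes in the analysis drivers (200×200 trajectories, 100-frame
  energy tables, 500-repeat fit validation) are chosen to make the
  statistical checks sharp at desk scale.
- No ΔSCF ionization energies, no electron densities, no GB solver, no MD
  integration, no enzyme-kinetics mechanism fitting, no Log P prediction.
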