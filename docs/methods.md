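# Methods

`umamidyn` implements the analysis layer of a dipeptide–taste-receptor
recognition study: construction and physicochemical screening of the complete
dipeptide database, recognition analytics over molecular-dynamics-style
trajectories, substrate-channel geometry, an empirical binding free-energy
score, and weak-interaction fields from a promolecular electron density.
This note records the models, their assumptions, the defaults, and the
numerical choices.

## Dipeptide database and screening

The database is the 400 ordered pairs of the 20 standard amino acids.  Per
record the package computes:

- **Molecular weight** — sum of free-amino-acid average masses minus one
  water (one peptide bond); masses from Biopython's `IUPACData`.
- **Net charge** at pH — Henderson–Hasselbalch over the free alpha-amino and
  alpha-carboxyl groups plus titratable side chains (D, E, H, C, Y, K, R):
  basic groups contribute `1/(1+10^(pH−pKa))`, acidic groups
  `−1/(1+10^(pKa−pH))`.  Dipeptides are modelled uncapped, as condensation
  products of free amino acids.
- **Isoelectric point** — the unique root of the net charge on (0, 14),
  found by bisection to 0.001 pH.  Uniqueness follows from strict
  monotonicity of every Henderson–Hasselbalch term; a dedicated test checks
  the bisection root against a 10⁻⁴-pH grid scan for all 400 sequences.
- **Hydrophobicity** — summed Kyte–Doolittle hydropathy.

**Default pKa table** (pH units): N-terminus 8.6, C-terminus 3.6, Asp 3.9,
Glu 4.1, His 6.5, Cys 8.5, Tyr 10.1, Lys 10.8, Arg 12.5.  This widely used
set reproduces the reference isoelectric point of Glu-Lys (6.41) and the
database-wide minimum net charge at pH 7 (−2.02, attained by Asp-Asp) to two
decimals.  The table is an argument everywhere it is used.  With this table
Asp-Gly titrates to pI 3.75.

**Hydropathy scale.**  Kyte–Doolittle, summed (not averaged).  Under this
scale the database extremes are Ile-Ile (+9.0) and Arg-Arg (−9.0).  Only the
sign convention (positive = hydrophobic) and relative orderings are
contracted; absolute values are scale-dependent, and other scales can be
passed in.

**Screening thresholds.**  Docking energy ≤ −6.5 kcal·mol⁻¹ (inputs are
compared at their 0.1 kcal·mol⁻¹ reporting precision) and umami probability
≥ 0.85.  Both scores are *imported* data — the package never runs docking or
umami prediction.  Records missing a score are excluded from that filter and
counted separately.

## Structures and trajectories

Structures are array-backed atom lists with element-derived van der Waals
radii (Bondi-style: H 1.20, C 1.70, N 1.55, O 1.52, S 1.80 Å) and optional
partial charges.  Multi-MODEL PDB files map to trajectories; parsing and
writing go through biotite, preceded by a validation pass that reports the
line number of a malformed record and the index of a MODEL whose atom count
disagrees with the first.

Superposition is unweighted least-squares (Kabsch, via
`scipy.spatial.transform.Rotation.align_vectors`), with
RMSD = √(Σδᵢ²/N) over the selection.  Tests compare it against an
independent brute-force quaternion-grid rotation search to 10⁻³ Å.
Pocket geometry boxes are measured along the principal axes of the
coordinate covariance, padded by per-atom vdW radii — a rotation-invariant
definition (the box frame of the original study is unstated).

Internal length unit is Å throughout; the clustering threshold is accepted
in nm, the unit it is conventionally quoted in (1 nm = 10 Å).

## Trajectory metrics

- **RMSD series** — per-frame Kabsch superposition onto a reference over a
  selection, then the RMSD formula over the same selection.
- **RMSF** — frames superposed to their running mean (two iterations), then
  RMSFᵢ = √⟨|rᵢ−⟨rᵢ⟩|²⟩, reported per residue over Cα atoms by default.
  The rigid-body fit absorbs six degrees of freedom, deflating RMSF by
  ≈√(1−2/N_atoms); for pre-aligned synthetic data the fit can be skipped.
  For isotropic Gaussian displacements of per-axis σ the expectation is
  σ√3, which tests verify within 3 % at 2000 frames.
- **Flexibility correlation** — Pearson R and ordinary-least-squares slope k
  of one RMSF profile on another over shared residues.
- **Clustering** — the pairwise criterion is C = 1 iff pairwise Cα RMSD
  after superposition ≤ threshold (default 0.5 nm).  The grouping algorithm
  is deterministic greedy leader clustering in frame order: a frame joins
  the first cluster whose *seed* frame is within the threshold, else founds
  a new cluster.  The criterion defines only pairwise membership, not the
  grouping; leader clustering was chosen for determinism and O(n·k) cost,
  and the seed-frame linkage is part of the contract (every member is within
  the threshold of its seed).  Representatives are minimum-potential-energy
  members, ties to the lowest frame index; without energies all frames tie
  and the first frame represents.
- **Snapshot accounting** — ⌊duration / (save_interval × timestep)⌋;
  200 ns at 5000 × 2 fs gives 20 000.

## Hydrogen bonds, contacts, SASA, pocket solvation

A hydrogen bond requires donor–acceptor distance < 3.5 Å *and*
acceptor–hydrogen–donor angle (vertex at the hydrogen) > 135°.  The distance
is donor-to-acceptor, exactly as the criteria are conventionally worded;
donors are polar heavy atoms (N/O/S) with a hydrogen within 1.25 Å,
acceptors all polar heavy atoms.  Occupancy is the fraction of frames a
donor–acceptor pair satisfies both criteria; tables are filtered at 45 %
by default.

Contact fingerprints list receptor residues with any heavy atom within
4.0 Å of a ligand heavy atom (the cutoff is a package default; the study
states none), labelled hydrogen-bonding when a cross H-bond fires,
hydrophobic when every contacting pair is C/S–C/S, polar otherwise.

SASA is Shrake–Rupley with a deterministic Fibonacci-sphere point set
(default 960 points, probe 1.4 Å).  Accuracy checks: isolated sphere versus
4π(r+p)² and overlapping equal spheres versus the spherical-cap closed form,
both within 1 %.  Pocket hydrophobicity is the SASA-weighted mean residue
hydropathy over the pocket selection — contracted for sign and ordering
only, since the original study's commercial routine is unpublished.  Pocket
waters are water oxygens within 5.0 Å of any pocket heavy atom, with a
convergence estimate over the final 25 % of frames.

## Channel profiling

HOLE-style: stations are laid every 0.25 Å along a user-supplied axis.  At
each station the sphere center is optimized within the perpendicular plane
to maximize min(center-to-atom distance − vdW radius), using the previous
station's center plus 16 seeded multi-starts (0.5–2 Å ring) refined by
Nelder–Mead; radii reaching 10 Å are flagged open-to-bulk.  A fixed axis
keeps the operation deterministic and testable (the original tool grows the
axis from a seed point); `suggest_axis` proposes endpoints from the first
principal axis of a selection.  The two nearest contact residues (smallest
center-to-surface distances, distinct residues) are recorded per station.
A plane-grid brute-force search (0.05 Å) is the test oracle; agreement is
within 0.1 Å on cylinder and V-shaped fixtures.

Channel acidity summarizes the unique titratable contact residues by their
model side-chain pKa (same values as the screening table); externally
computed per-residue pKas can be supplied instead.  Mean > 7 labels the
channel basic.  Full structure-based pKa prediction is out of scope.

## SIE binding free energy

ΔG_bind = α·(E_c + ΔG_R + E_vdw + γ·ΔMSA) + C, with the fitted defaults
α = 0.1048, D_in = 2.25, ρ = 1.1, γ = 0.0129 kcal·mol⁻¹·Å⁻², C = −2.89
kcal·mol⁻¹.  A variant applying α to the Coulomb term alone circulates in
some renderings of the functional form; it is exposed behind
`printed_bracketing=True`, but the default follows the convention the
coefficients were fitted under.  Terms:

- **E_c** — receptor–ligand Coulomb sum k·qᵢqⱼ/(D_in·rᵢⱼ),
  k = 332.0636 kcal·mol⁻¹·Å·e⁻².  Interpreted as the *inter*molecular
  interaction (a binding energy requires it), not a full-complex internal
  energy.
- **E_vdw** — 12-6 Lennard-Jones with Lorentz–Berthelot combination over a
  bundled per-element table (Amber-style generic values); per-atom
  parameters can be imported.
- **ΔG_R** — change in polar solvation on binding from a generalized-Born
  model: Hawkins–Cramer–Truhlar pairwise-descreening Born radii on ρ-scaled
  vdW radii, solvent dielectric 78.5.  The boundary-element solver used in
  the original study is replaced by this standard analytic continuum model;
  its single-ion limit is the exact Born formula (tested to 10⁻⁶) and it
  vanishes for far-separated neutral fragments.
- **ΔMSA** — surface-area change on binding, proxied by the zero-probe
  accessible surface over ρ-scaled radii; negative for any bound complex.

Ensemble scoring evaluates the selected frames (by default up to 100 frames
evenly over the second half of the trajectory, mirroring
equilibrated-production sampling at 1 ns intervals over a 100–200 ns run)
and reports mean ± SD with a per-frame component table.

## RDG / NCI fields

The electron density is promolecular: a superposition of spherically
averaged free-atom densities, the standard substitute for a quantum-chemical
density in NCI practice.  Atomic densities are built from Slater-type
orbitals with Slater's-rules screening exponents (H through Kr, Cr and Cu
exceptions included); each integrates exactly to the element's electron
count, is analytic and strictly positive.  This choice — rather than a
redistributed fit table — keeps every coefficient derivable from a published
rule set.

RDG = |∇ρ| / (2·(3π²)^{1/3}·ρ^{4/3}), with central-difference gradients in
atomic units (one-sided at boundaries, which are excluded from
classification); voxels with ρ < 10⁻⁸ a.u. are masked.  λ₂ is the middle
eigenvalue of the density Hessian.  Weak-interaction voxels (RDG < 0.5,
ρ < 0.05 a.u. — common NCI practice; the defaults are configurable) are
classified by sign(λ₂)·ρ: < −0.01 hydrogen bond, within ±0.01 van der
Waals, > +0.01 steric.  For an exponential density ρ = N·e^{−r/a} the RDG
closed form ρ^{−1/3}/(2(3π²)^{1/3}a) is matched within 2 % at 0.1 Å
spacing, and the RDG vanishes at the midpoint of a symmetric atom pair.
Grids export to Gaussian cube format (Bohr units, z-fastest ordering) with
a round-trip reader.

## Synthetic data

The generator module produces every input the pipeline consumes, with the
planted ground truth returned beside each object:

- **Dipeptides** — seeded distance-geometry embedding (RDKit ETKDG) over
  ideal bond lengths/angles, free termini, Gasteiger charges.  Geometry is
  idealized, not force-field-minimized: downstream stages use only
  topology, composition and approximate shape.
- **Trajectories** — reference plus independent isotropic Gaussian
  displacements (per-atom σ), optionally wrapped in random global
  rotations/translations to exercise superposition.  Gaussian noise (not
  correlated dynamics) suffices because only time-averaged statistics are
  analyzed; synthetic per-frame energies are seeded Gaussians so
  representative selection is deterministic.
- **Channels** — pseudo-atom rings whose inscribed-sphere radius at each
  ring equals the prescribed profile value.
- **H-bond trajectories** — a donor–H–acceptor triad bonded (2.9 Å, 180°)
  in exactly round(occupancy·n_frames) frames and broken (6 Å) otherwise,
  so planted occupancies are recovered *exactly*.
- **Score tables** — docking energies and umami probabilities with exact
  planted pass fractions against the −6.5 kcal·mol⁻¹ / 85 % thresholds and
  an optional planted overlap.

What passing tests show — and do not.  The generators emulate the
*statistical contracts* of real data (fluctuation amplitudes, occupancy
fractions, pore geometry, pass rates), not its physics: there are no force
fields, no solvent structure, no conformational kinetics.  Recovery of
planted parameters validates the estimators, not the ensembles they would
be applied to.

## Problem sizes and determinism

Test and pipeline problem sizes are chosen for seconds-scale runs: 2000
frames for RMSF law checks, ≤ 100-frame ensembles elsewhere, RDG grids of
≲ 10⁵ voxels at 0.1–0.25 Å spacing, channels of a few dozen stations.  All
randomness flows through explicit integer seeds (`numpy.random.default_rng`);
identical configuration and seed reproduce results bundles byte-for-byte.

## Known limitations

- The GB/SA reaction field and surface proxy are standard approximations;
  absolute SIE values for real complexes depend on charge/radius sets the
  user supplies.
- Promolecular densities have no charge transfer or polarization; NCI
  classes near strong ionic contacts should be read qualitatively.
- The channel profiler requires a user axis; strongly curved pores would
  need a piecewise axis.
- pKa summaries use model side-chain values; environment shifts require
  imported per-residue pKas.
- The hydropathy scale behind the published database extremes is not
  identifiable; only sign and ordering under the documented default scale
  are contracted.
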