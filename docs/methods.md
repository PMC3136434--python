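# Methods

`bindscan` post-processes conformational ensembles of a receptor–peptide
complex into binding free energies and per-residue energetics.  It never
generates the ensembles themselves: molecular-dynamics sampling and any
high-level (e.g. DFT) energies are inputs, produced elsewhere.  This
note records the models implemented, the numerical choices behind them,
what the synthetic toy complexes do and do not emulate, and the known
limitations.

## Units and conventions

Lengths in Å, energies in kcal/mol, charges in elementary charge units,
masses in amu, times in ps, entropies in cal/(mol·K); temperature
defaults to 300 K.  The Coulomb constant is fixed at
332.0637 kcal·Å·mol⁻¹·e⁻².  Lennard-Jones parameters use the r_min/ε
convention: per-atom radii are r_min/2 and combine arithmetically, well
depths geometrically (Lorentz–Berthelot).  Residue indices are 1-based
as in PDB files; the hairpin ligand's 15 positions are written 01–15.

## Single-trajectory MM-PBSA

The binding free energy is assembled per snapshot as

    ΔG_bind = ⟨ΔE_EL + ΔE_vdW + ΔG_PB + ΔG_SA⟩ − TΔS

with receptor and ligand coordinates extracted from the complex frame
(the single-trajectory convention), so intramolecular terms cancel
exactly and the gas-phase terms reduce to the receptor↔ligand cross
interaction, evaluated with infinite cutoffs and no periodicity.
Nonbonded exclusions (1-2, 1-3) therefore never enter the binding
energy; they are implemented only for the full-term cancellation
identity, where 1-4 pairs are unscaled.

Solvation differences G(complex) − G(receptor) − G(ligand) are computed
on shared coordinates and on one shared grid box (the complex's), which
cancels most of the grid self-energy.  Means are reported with block
standard errors (√N contiguous blocks by default) because snapshots are
autocorrelated.  A run is flagged converged when the running average of
the per-snapshot total moves by no more than a tolerance (default
1 kcal/mol) over a trailing window (default 12 ns).

## Poisson–Boltzmann solver

The polar term is the reaction-field energy: the grid electrostatic
energy with the solvent dielectric (default 80) outside the cavity minus
the same grid's energy with the solute dielectric (default 1)
everywhere.  Choices:

- Dielectric boundary: union of atom spheres at their cavity radii
  (default: the LJ r_min/2 radii).  No re-entrant molecular surface is
  constructed; the choice is isolated in `PBSettings`.
- Edge dielectrics: harmonic mean weighted by the *analytic* in-cavity
  fraction of each grid edge (edge–sphere intersection lengths, overlaps
  combined by a clipped sum).  The analytic fractions matter: midpoint
  or sampled fractions quantize the boundary position and make the
  discretization error oscillate with grid spacing instead of shrinking
  smoothly.
- Charges are spread trilinearly; the potential is interpolated back
  trilinearly and the energy is ½Σqφ.
- Boundary condition: solvent-screened analytic Coulomb potential of all
  charges on the box faces; default padding 6 Å beyond the cavity.
- Linear solver: diagonally preconditioned conjugate gradients to a
  1e-8 relative residual.
- Linearized salt screening (κ² term) is available but defaults to zero
  ionic strength, where the equation reduces to the Poisson equation.

On the Born ion (q = 1 e, cavity 2 Å, ε 1→80) the solver lands within
3.1%, 0.56% and 0.12% of the closed form at 1.0, 0.5 and 0.25 Å spacing
— monotone refinement, measured by the acceptance script.

The nonpolar term is γ·SASA + offset.  γ = 0.00542 kcal/(mol·Å²) and
offset = 0.92 kcal/mol are the conventional companions of this PB setup
and are configurable; they are defaults of this package, not values
taken from any particular study.  SASA uses deterministic Fibonacci
sphere sampling (960 points/atom by default; exact for an isolated
sphere) with probe radius 1.4 Å; exactly coincident spheres are
collapsed so duplicates carry no area.

## Normal-mode entropy

Snapshots are minimized under a differentiable MM model — conjugate
gradients to a loose gradient RMS (default 1e-2 kcal/(mol·Å)), then
Newton trust-region steps to the final tolerance (default 1e-4).  The
model combines harmonic bond terms (equilibria at the topology's
reference geometry), the nonbonded terms, an optional
generalized-Born-style polar term (Still pairwise form with fixed Born
radii = LJ radii, floored at 0.8 Å) and an optional intra-group harmonic
distance network (default cutoff 8 Å).  The network is a deliberate
modelling device: the coarse residues carry no angle or torsion terms,
and without it a chain topology has soft internal rotations whose
near-zero frequencies make harmonic entropies diverge.  Cross
receptor–ligand pairs are never restrained, so binding modes stay
physical.

The Hessian is built by central differences of the analytic gradient
(step 1e-4 Å), mass-weighted and diagonalized.  Modes below 1 cm⁻¹ are
removed as rigid-body modes; a warning is raised when their count
differs from the 3/5/6 expected for a point/linear/nonlinear solute.
Translational entropy is Sackur–Tetrode at a 1 atm standard state,
rotational is the classical rigid rotor (σ = 1), vibrational is the
quantum harmonic oscillator.  ΔS = S(complex) − S(receptor) − S(ligand)
is averaged over snapshots; snapshots that fail to minimize are skipped
with a logged count, and more than half skipped is an error.

## Alanine and glycine scanning

Mutants are built geometrically on existing snapshots, with no
re-minimization: an alanine mutant removes all side-chain atoms beyond
Cβ and places one hydrogen along the Cβ→Cγ unit vector at 1.09 Å
(configurable), carrying the alanine Hβ parameters from the parameter
table; a glycine mutant truncates at Cα the same way.  All non-mutated
coordinates are bit-identical between wild type and mutant.  ΔΔG =
ΔG_mut − ΔG_wt is averaged over frames and is enthalpic by default
(gas + PB + SA, entropy omitted as is conventional for post-processing
scans; it can be switched on).  In `auto` mode, positions whose wild
type is alanine receive the glycine mutation, all others the alanine
mutation; alanine-under-alanine entries are defined zero.  Alanine and
glycine scans are different observables and are reported separately,
never merged or compared numerically.

Truncating an ionized side chain changes the system's net charge and the
PB term is simply recomputed with the mutant charge set — no
neutralization correction.  This matches the truncate-and-recompute
protocol but is a known limitation for charged residues.

## QM-PBSA-style hybrid assembly

The hybrid free energy replaces the per-snapshot gas term with an
externally supplied high-level energy (matched by frame time) and
multiplies the MM polar solvation term by a weight derived from a
power-law fit |G_polar| = A·ε^b of polar solvation against the solute
dielectric, fitted by least squares in log–log space.  The weight is
(ε_target/ε_ref)^b; which dielectric the fit should be evaluated at is
genuinely underdetermined here, so it is a configuration point whose
identity default (ε_target = ε_ref) leaves the classical result
unchanged.  The entropy term stays classical.  With identity records and
unit weight the hybrid reduces to MM-PBSA exactly; a constant offset in
the records shifts ΔG by exactly that offset — both identities are
asserted in the tests.

Representative-snapshot selection augments a mandatory coarse-stride
subset with k extra frames chosen to minimize the discrepancy between
subset statistics and full-trajectory values; the statistics are the
mean and standard deviation of the per-frame enthalpic total plus each
named hydrogen bond's occupancy, combined as a sum of squared deviations
each normalized by the population standard deviation (equal weights,
configurable).  The search is exhaustive up to 5000 candidate subsets
and multi-start greedy (one start per pool frame) with swap refinement
beyond.  Note that the *optimal* objective is not monotone in k — a
small subset can match the population mean and spread essentially
exactly — but the (k+1)-optimum is never worse than the best
single-frame extension of the k-optimum, and that is the property the
tests assert.  A half-vs-full subset ΔG difference is reported as a
convergence diagnostic.

Force-error profiles are the per-atom mean over snapshots of
|F_high − F_MM|, with MM forces from the analytic gradient of the
configured energy model.

## Thermodynamic integration

A mutation is carried through three stages — decharge, soft-core vdW
transformation, recharge — and each stage's ΔG is the λ-integral of
⟨dV/dλ⟩ by Gauss–Legendre quadrature mapped to (0, 1), nine nodes by
default (exact through polynomial degree 17).  Node standard errors are
block-corrected and propagate through the weighted sum; stage SEs
combine in quadrature.  First-half/second-half node means are reported
as a convergence diagnostic.

The soft-core 12-6 interaction is separation-shifted:
V = c(λ)·4ε[σ¹²/(r⁶+Δ)² − σ⁶/(r⁶+Δ)] with Δ = α·λ_off^p·σ⁶, α = 0.5 and
p = 1 by default, where λ_off is the coupling-off fraction.  It is
finite at r = 0 for interior λ, reduces to plain LJ at the coupled
endpoint, and returns analytic dV/dλ (checked against finite
differences).

Because the alchemical MD engine is out of scope, the package samples
toy 1-D potentials with seeded Metropolis Monte-Carlo (10% of each chain
discarded as equilibration, step 0.5 Å): a harmonic stiffness change
(ΔG = (kT/2)·ln k₁/k₀), linear charging in a trap (ΔG = ±q²E²/2k) and
soft-core LJ appearance (ΔG from dense 1-D quadrature of both partition
functions — an oracle independent of the sampler).  The closed forms are
recovered within 3 combined SE at 2000 samples/node, and a null
transformation (identical end states) totals zero within 3 SE.

## Trajectory analytics

A hydrogen bond is counted in a frame when the donor–acceptor distance
is ≤ 3.5 Å and, if a hydrogen is specified, the donor–H–acceptor angle
is ≥ 120°; both thresholds are configurable, as the conventional
criterion is itself a convention.  Occupancy is the indicator mean over
frames, reported with per-block fractions.  Block averaging uses
contiguous equal blocks (remainder to the last) with SE =
std(block means)/√n_blocks.  Distance histograms default to 0.1 Å bins;
logarithmic counts mask empty bins with explicit NaN markers, never
zeros.  RMSD superposes selections with the closed-form SVD (Kabsch)
rotation including the determinant correction, and the monitoring
contract flags ensembles whose backbone trace exceeds a configured bound
(2.0 Å default; 2.5 Å is the documented alternative for comparisons
against an equilibrated rather than crystallographic reference).

## Synthetic toy complexes

The generator builds a coarse receptor groove (single-site residues on a
plane, ~3.5 Å spacing) binding a 15-residue hairpin whose residues carry
3–6 atoms (N, CA, C backbone plus a 1–2-atom side chain).  It emulates
exactly the statistical features the analysis relies on:

- a 4-residue hotspot (default positions 6–9: one bulky, two polar, one
  alanine) whose side chains sit in attractive LJ pockets carved into
  the groove, with brute-force pair-sum ground-truth interaction
  energies stored per residue;
- a +1/+2/+3 charge series, realized as +1 backbone sites against a
  fixed −3 receptor patch, so the whole series faces one and the same
  receptor and the electrostatic ranking is analytic;
- intermittent hydrogen bonds as two-state telegraph chains with exact
  stationary occupancy (default mean on-dwell 3 frames, configurable —
  long dwells inflate the occupancy estimator's variance far beyond the
  binomial bound the recovery checks assume);
- harmonic positional fluctuation about the reference pose (default
  σ = 0.08 Å).

Replacement hydrogens (ALA Hβ, GLY Hα2) are deliberately inert in the
toy parameter table (zero charge and well depth), which makes the
gas-phase scan ΔΔG *exactly* minus the removed side chain's interaction
energy.  The documented PB/SA allowance for the full-solvation scan
check is 0.75 kcal/mol: the side chains are neutral, so the perturbation
is the buried-area term plus the cavity-shape response of distant
charges (measured ≤ 0.11 kcal/mol on the default fixture).

What the toys do **not** emulate: real force-field chemistry (angles,
torsions, hydrogens), solvent structure, conformational transitions
beyond Gaussian jitter and telegraph toggling, realistic magnitudes of
EL/PB compensation, or actual peptide sequences.  Tests passing on these
fixtures validate the estimators' contracts and numerics — not the
biophysical accuracy of any force field or sampling protocol.

## Degenerate inputs and tie-breaks

Zero interatomic distances raise identified-pair errors in the pair
sums; a solute touching the PB grid raises an error naming the padding
remedy; empty species, empty λ-nodes, sign-mixed power-law samples and
out-of-range truncation windows all raise before any computation; frames
with identical values give zero standard errors rather than NaN;
coincident SASA spheres tie-break to the first atom.  All generator
outputs and both pipelines are bit-reproducible from (config, seed);
every report embeds its effective configuration and a schema version.

## Problem sizes

Default desk-scale sizes: toy complexes of ~90 atoms, PB grids of
40³–100³ nodes (0.25–1.0 Å spacing), ensembles of 2–1000 frames, TI with
9 nodes × 2000 Metropolis samples.  The scan over all 15 positions with
full PB/SA at 0.8 Å spacing completes in under two minutes on one core.
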