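# Methods

This note documents the models, numerical choices and limitations of
`confdesign`, in the order of the design pipeline.

## Structure model and superposition

Coordinates live in a Structure → Chain → Residue → AtomRecord hierarchy in
Å, with author (PDB) residue numbering canonical throughout; any offset
between crystal and reference sequence numbering is carried in an explicit
`numbering_map`, never applied silently.  PDB parsing and writing are backed
by gemmi; on top of its parse the reader collapses alternate locations
(default: keep the highest-occupancy conformer, ties broken by alphabetical
alt-loc identifier — a deterministic single-conformer model for design),
discards waters (flag to keep), and keeps HETATM cofactors such as PLP in a
separate ligand group.  mmCIF, symmetry expansion and anisotropic B-factors
are out of scope.

Superposition is the standard SVD (Kabsch) solution with reflection
correction, so the returned rotation always has determinant +1; mirrored
inputs yield a proper rotation with a nonzero residual rather than an
improper fit.  Degenerate inputs (<3 matched atoms, collinear sets) raise
rather than returning an ill-conditioned transform.

## Hinge geometry

Domain partitions (fixed / moving / hinge residue sets) are supplied by the
user or a YAML block; automatic domain decomposition is deliberately not
reimplemented, because downstream logic needs only the quantitative motion.
Both structures are superposed on fixed-domain Cα atoms; the residual
transform of the moving domain is decomposed into screw form.  The angle is
extracted as arccos((tr R − 1)/2) with the argument clamped to [−1, 1] for
numerical safety; angles below 10⁻⁴ degrees are reported as null motion
(the axis of a near-identity rotation is numerically meaningless).  The
axis is the unit eigenvector of R for eigenvalue 1, oriented so the
rotation about it is right-handed; the axis point solves
(I − R)p = t_perp in the least-squares sense; the screw translation is the
axis-parallel component of the residual translation.  Pure-rotation
fixtures recover zero screw translation to 1e-9 and the geometry is
invariant under any global rigid motion of both inputs.

## Ensemble generation

Backbone flexibility is modeled by perturb-and-minimize ensembles: each of
n members (default 50) perturbs every heavy atom by exactly ±m per
Cartesian axis (default m = 0.001 Å) with independent Rademacher signs —
so every heavy atom moves exactly m·√3 — and relaxes the result with a
bounded minimization.  The quoted ±m scheme is read as fixed magnitude with
random sign; uniform sampling in [−m, m] is available by substituting a
custom perturbation.  Member i draws its signs from seed `spec.seed + i`,
making ensembles bit-reproducible while keeping member streams independent.

The published procedure minimizes with a solvated all-atom force field;
that is out of scope here.  The bundled potential is a simplified
stand-in built from the same ingredients the design step uses: harmonic
restraints on all reference interatomic distances within 5 Å (bond-length/
angle surrogate, reference taken from the input geometry, k = 10
kcal/mol/Å²) plus the design 12-6 Lennard-Jones term on pairs between 5 and
8 Å.  Because the LJ tail shifts the minimum away from the input geometry
and roughens the landscape, perturbed members genuinely relax to nearby,
slightly different local minima (toy-scale runs give member–seed backbone
RMSDs of order 1 Å and pairwise diversities of order 0.01–0.1 Å).  The
published diversity values (≈0.3 Å at full protein scale under a different
force field) are not expected to be reproduced and are not asserted
anywhere.  Any object exposing `energy_gradient(flat_coords)` can be
plugged in instead.

"Truncated Newton for ≤100 iterations" is treated as a contract —
second-order-informed, monotone, deterministic, iteration-capped — and
satisfied by `scipy.optimize.minimize(method="Newton-CG")` (conjugate-
gradient inner loop, line-searched descent) with a steepest-descent
fallback if the quadratic model ever fails.  Energy never increases; a
structure already at a minimum is returned unchanged.

## Design energy function

Five pairwise terms, all continuous above a 10⁻³ Å clash floor, all capped
at +100 kcal/mol (clash cap) so matrices stay finite and bounded:

- **Lennard-Jones 12-6**: per-type radii scaled by 0.9, combined radius the
  arithmetic mean of the scaled radii, well depth the geometric mean;
  E(R₀) = −ε exactly, zero crossing at R₀·2^(−1/6).
- **Hydrogen bond**: hybrid 12-10, D₀[5(R₀/R)¹² − 6(R₀/R)¹⁰] with
  D₀ = 8.0 kcal/mol, R₀ = 2.8 Å, times an angular factor cos⁴θ_DHA with a
  hard cutoff below 90°.  No angular form is prescribed by the source
  energetics; cos⁴ is this package's choice.  Without explicit hydrogens an
  ideal linear geometry (factor 1) is assumed.
- **Coulomb**: 332.0637·q_iq_j/(ε(r)·r) with a distance-dependent
  dielectric ε(r) = 10·r by default (constant ε = 10 by configuration).
- **Solvation**: occlusion-based penalty, pairwise-decomposable —
  c_i·V_j·exp(−(r/λ)²) + c_j·V_i·exp(−(r/λ)²), λ = 3.5 Å — monotone
  non-decreasing as neighbors approach, zero for an isolated atom.
- **Secondary-structure propensity**: position-additive table lookup
  (residue type × helix/strand/other), the class assigned from template
  φ/ψ with coarse Ramachandran bins.

The original design software's parameter tables are not published.  The
bundled `data/forcefield.yaml` is a compact, versioned, self-consistent
stand-in (Dreiding-like LJ radii/depths, name-based charges and H-bond
typing, per-element solvation volumes).  Consequently **absolute energies
are not comparable to any published design energies**; every numeric check
on the design core is structural, relative, or arithmetic.

Matrices: singles are the summed terms between a built rotamer's side-chain
atoms and all template atoms outside the designed residues (own-residue
atoms excluded as bonded context) plus the propensity term; pairs are the
summed terms between rotamer atoms at distinct designed positions;
nonbonded cutoff 8 Å, no switching function.  The assignment energy
Σ singles + Σ pairs reproduces direct recomputation from coordinates to
1e-9, and matrices are invariant under global rigid motion.

## Rotamers and solvers

The reader accepts the 2002-style backbone-dependent library text format
(whitespace columns).  The true library is not bundled (size/licensing); a
small synthetic library covering all 17 side-chain-bearing designable types
at two backbone bins ships for tests and toy runs.  ±1σ expansion around χ1
and χ2 turns each base rotamer into 3^min(nχ,2) variants.  Proline is
excluded from the design alphabet (19 types); glycine and alanine are
rotamer-free.  Side chains are built by sequential torsion (NeRF)
construction with ideal internal coordinates, so re-measuring any χ from
built coordinates returns the input to 1e-6 degrees.

Three solvers share one contract (minimize singles + pairs, one choice per
position), with lexicographic tie-breaking everywhere for determinism:

- `brute_force_gmec`: exhaustive oracle, refuses >10⁶ assignments.
- `dee_prune`: Goldstein singles elimination iterated to a fixpoint;
  provably GMEC-preserving.
- `faster_optimize`: iterative batch relaxation from the singles minima
  followed by single-perturbation/relaxation sweeps accepted on strict
  improvement.  The pairs-perturbation variant of the published lineage is
  omitted — a documented completeness deviation; on random toy problems
  the implementation matches the exact optimum in ≥95% of instances and by
  construction can never beat it.  Sequence-constrained optimization
  restricts choices per position before solving (per-sequence optimization,
  matching a sequence-space sweep that optimizes rotamers for every
  sequence).

## Multistate scoring and library design

Per-state sequence energy is the Boltzmann-weighted average of per-member
optimized energies at T = 300 K with R = 1.9872×10⁻³ kcal/mol/K, computed
with a log-sum-exp shift so very favorable members cannot overflow; it is
bounded between the member minimum and mean.  ΔE = E_closed − E_open;
swapping state ensembles negates it exactly.  Ranking discards sequences
whose E_closed and/or E_open lies **above** the 75th percentile of its
column — "outside the percentile" is read as the unfavorable (high-energy)
tail, since the filter exists to stop unstable sequences from showing
artificially favorable ΔE — then sorts by ΔE (ascending for the closed
objective, descending for open).

CLEARSS's internal probability definition is not published.  The
implementation weights each amino acid at each position by a Boltzmann sum
over the records' ΔE at a selection temperature T_sel (default 1.0
kcal/mol, configurable) — a documented stand-in.  All size configurations
(n₁,…,n_k) with Πnᵢ inside target ± tolerance (default 20 ± 4) are
enumerated with pruning; each takes the top-nᵢ amino acids by weight per
position and is scored by the summed partition functions of its sets; ties
prefer the smaller library, then lexicographic sets.  The score is monotone
non-decreasing in the tolerance.

The pipeline builds matrices once per ensemble member with all candidate
amino acids present and restricts per sequence, so the sequence loop never
re-evaluates atom pairs.  Whether the percentile filter should be applied
per objective or globally is not specified by the source procedure; the
implementation applies it to whatever record set is passed in, which
reproduces either reading.  A full design run on toy fixtures is
byte-reproducible under a fixed seed.

## Two-state thermodynamics

Spectra are real-valued 1-D traces with a strictly monotone ppm axis.
Deconvolution fits two Lorentzians plus a constant baseline (linear
baseline by flag) by nonlinear least squares (lmfit), with widths and
amplitudes bounded positive; initial centers come from the two most
prominent local maxima, falling back to an axis split.  Peaks are returned
ordered by center descending.  Populations are **area** fractions
(area = π·amplitude·hwhm; note a ±50-hwhm window only captures
(2/π)arctan 50 ≈ 98.7% of a Lorentzian's area — tails matter).  The
closed-state peak is identified by configuration, default the more upfield
(lower-ppm) peak, and never inferred silently.  Keq = p_closed/p_open, so
all thermodynamics are in the direction of closing (G_closed − G_open).

van't Hoff fits run in ln Keq space, unweighted by default:
linear (ΔCp = 0, ≥3 temperatures) or nonlinear (≥4), Tref = 298 K,
uncertainties as 1σ from the fit covariance.  ΔG(T) = ΔHref + ΔCp(T−Tref)
− T[ΔSref + ΔCp·ln(T/Tref)] is algebraically identical to −RT·ln Keq of
the same model.  With seven temperatures and three parameters, coverage
statements use Student-t intervals (4 degrees of freedom); at 1%
multiplicative Keq noise the three parameters land inside their t-based
95% intervals in ≳92% of seeded replicates.  Full lineshape/exchange
modeling, referencing and phasing are out of scope; spectra are taken as
processed traces.

## Kinetics

Initial rates: the linear phase of an absorbance trace is detected by
expanding a prefix window until the next point deviates from the current
fit by more than 4× its RMSE (the curvature onset); the accepted window
must have R² ≥ 0.995 (configurable).  The slope divided by ε·path
(ε = 6220 M⁻¹cm⁻¹ for NADH at 340 nm) gives the rate; a flat trace is
linear with rate zero.  No definition of "linear phase" is prescribed by
the assay description; the residual-gated window is this package's choice
and recovers generator slopes to <0.1% on noiseless curved traces.

Michaelis–Menten and substrate-inhibition (v₀ = v_max[S]/(K_M + [S] +
[S]²/K_i)) fits use `scipy.optimize.curve_fit` with positivity bounds and
data-driven starts; k_cat = v_max/[E₀]; k_cat/K_M (M⁻¹s⁻¹) carries
first-order propagated uncertainty.  The substrate-inhibition model nests
Michaelis–Menten as K_i → ∞ and its rate maximum sits at √(K_M·K_i).  The
linear-regime estimator fits a through-origin slope to points with
[S] below a configured fraction of K_M.  Replicates are pooled, not
weighted, by default.  Selectivity is the ratio of efficiencies for two
donor substrates; selectivity(a,b)·selectivity(b,a) = 1 identically.

## Synthetic fixtures and what passing means

Generators are bit-deterministic under a seed and produce data in exactly
the formats the analysis modules read.  Toy structures use ideal-ized
backbone geometry on a helical curve (virtual Cα spacing 3.6 Å) with no
Ramachandran realism; hinge pairs apply an exact screw to the moving
domain, so geometry recovery is an identity check, not a robustness claim.
Spectra have exact Lorentzian lineshapes and Gaussian intensity noise —
no exchange broadening, baseline drift or phase error — and rate data have
multiplicative Gaussian noise at the stated level.  Passing tests
therefore demonstrate correctness of the implemented mathematics and
determinism of the pipeline on clean, well-specified inputs; they do not
demonstrate robustness to the artifacts of real spectra, real plates or
real crystal structures.

Problem sizes used by the test suite and the acceptance script (toy
structures of 8–14 residues, 2-member ensembles, 2 positions × 2–3 amino
acids, 100 random solver instances, 500 thermodynamic and 200 kinetic
noise replicates) were chosen as the smallest sizes at which every
contract is exercised end to end; all scale up by configuration.

## Known limitations

- Absolute design energies depend on the bundled stand-in parameter tables
  and match no published energy scale.
- The FASTER implementation omits pairs perturbation; on adversarial
  matrices its match rate to the exact optimum can drop below toy-problem
  levels.
- The ensemble potential has no solvent, no electrostatics and no bonded
  chemistry beyond distance restraints; ensemble diversities are
  qualitative.
- Automatic hinge detection is not provided; a wrong user partition gives a
  well-defined but meaningless screw.
- The CLEARSS weighting (Boltzmann over ΔE at T_sel) is a reconstruction of
  an unpublished definition; library compositions, though deterministic,
  may differ from the original tool's.
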