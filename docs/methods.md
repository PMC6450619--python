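# Methods

`cginverse` implements structure-based (bottom-up) coarse-graining for
implicit-solvent lipid models: an atomistic trajectory is mapped onto
beads, the mapped trajectory defines reference distribution functions, and
tabulated effective potentials are refined until a coarse-grained (CG)
simulation reproduces those distributions. This note records the model,
the numerical choices, and what the synthetic test systems do and do not
demonstrate.

## Mapping and CG topology

A mapping scheme partitions the atoms of one molecular species into beads.
Bead positions are mass-weighted group centres; because a group may
straddle a periodic boundary, each group is unwrapped around its first
atom by minimum image before averaging and the centre is wrapped back into
the box. Groups are small compared to any box of interest, so this
convention is unambiguous. Bead charges and masses are sums over the
member atoms, which conserves molecular mass and charge exactly.

Bonded terms are enumerated on the CG bond graph: bonds are its edges,
angles all simple paths of length two, torsions all simple paths of length
three. Interaction type names are canonicalised under reversal
(lexicographic minimum of the forward and reversed label tuples), which
deduplicates `N-P`/`P-N` and symmetric torsion traversals
deterministically. Every bead pair co-occurring in a bonded term (1-2,
1-3 and 1-4 neighbours) is excluded from non-bonded interactions. The CG
bond graph defaults to the image of the chemical bond graph under the
mapping, but a scheme may declare it explicitly: the 14-bead DOPE model
bonds the phosphate bead to *both* ester beads (giving the `CO-P-CO`
angle and `CO-P-CO-C3` torsion), a modelling convention that the literal
glycerol chemistry would not produce.

### The DOPE fixture

The bundled DOPE (dioleoylphosphatidylethanolamine) molecule is an
all-atom construction: C41 H78 N O8 P, 129 atoms, molar mass 744.05 g/mol,
with a complete chemical bond graph. It maps to 14 beads of six types —
N (ethanolamine), P (phosphate), two CO (ester + glycerol fragments), and
per oleoyl chain C3/C3/CdB/C3/C4, where CdB holds the double-bond carbons.
Enumeration yields 6 bond, 7 angle and 6 torsion types plus 21 non-bonded
type pairs. The 17 post-carbonyl chain carbons cannot split 3/3/3/3/4, so
the first chain bead carries four carbons (C2–C5); per-bead atom counts
are N 10, P 5, CO 6 and 8, and 12/9/7/9/13 along each chain. Atom partial
charges are fixture conventions constrained to plausible bead sums (+0.6 e
on N, −0.8 e on P, +0.1 e on each CO, neutral chains, zero total); they
are not a force field.

## Distribution functions

Bond, angle and torsion histograms are probability densities on uniform
grids (default 0.01 nm for distances, 2° for angles, 4° for torsions —
fine enough to resolve lipid torsion structure while keeping the inverse
problem ≲10³-dimensional). Torsions use the standard signed dihedral
convention; the sign is never folded, so chirally asymmetric torsion
distributions are representable. Non-bonded pair distributions are full
radial distribution functions g(r): shell-volume, frame and ideal-pair
normalised so an uncorrelated fluid gives exactly 1, which provides the
long-range tail check and makes the Boltzmann inversion of pair tables a
plain −kT ln g. Minimum-image conventions assume orthorhombic boxes
throughout; triclinic cells are out of scope.

For the inverse Monte Carlo machinery the *raw per-frame bin counts* are
retained alongside the densities. The cross-correlation matrix

    A_ag = ( <S_a><S_g> − <S_a S_g> ) / kB T

is the negative covariance of those counts over frames, estimated across
the concatenated bins of all interactions (bonded × non-bonded cross
blocks included). The same counts convention is used for the reference
and iteration sides of the update — mixing counts with densities would
silently rescale the Newton step. For the same reason the reference and
refinement systems must have matching composition (same molecule and
pair counts); refining a larger CG system against a smaller reference
requires rescaling the reference counts first.

## Potential refinement

Direct Boltzmann inversion provides the zeroth-order tables, dividing out
the measure Jacobian first: 4πr² for distances, sin ϑ for angles, nothing
for torsions (for pair tables the Jacobian already sits inside g(r)'s
normalisation). Bins with fewer than 10⁻⁶ of the peak population are
marked undefined and carry a finite placeholder (5 kT above the maximum
defined energy); boundary finalization later replaces them by
extrapolation. Pair tables are shifted to zero at the largest populated
distance, bonded tables to zero at their minimum — additive constants are
physically irrelevant but fixed conventions keep restarts reproducible.

Iterative Boltzmann inversion updates each table independently,
`dU = a kT ln(S_n / S_ref)`, skipping bins where either side is empty.
Inverse Monte Carlo solves `A dU = a (S_ref − S_n)` jointly across all
interactions with a truncated-SVD solve (singular values below 10⁻⁸ of
the largest are discarded): at finite sampling A is a noisy covariance
estimate whose small-eigenvalue directions would otherwise inject large
spurious updates. The damping factor a stabilises both updates; defaults
are a = 1 for IBI on bonded terms, a = 0.5 for non-bonded IBI and for
IMC steps (configurable — only 0 < a ≤ 1 is enforced).

Convergence is tracked by the total mean-square deviation
`delta = sum_I sum_a (S_ref − S_n)² / (l_a N_a)` over all interactions,
evaluated on densities so it is independent of sampling length.

The orchestrator runs an IBI phase then an IMC phase (the historical
20 + 20 schedule is the default), sampling each iteration with the
built-in canonical sampler. IMC iterations sample longer than IBI ones
(default 2×) because the correlation matrix needs more statistics than
the distributions alone. At the IBI→IMC boundary the configuration is
re-initialised from a random mixture (configurable); otherwise each
iteration warm-starts from the previous final configuration. The Coulomb
term of the Hamiltonian is part of the sampling model but is never
touched by either update: only the short-range tables are refined.
Default per-iteration sampling lengths are sized for desk-scale toy
systems (10⁴–10⁵ steps); production-scale refinement only changes those
numbers.

## Table post-processing

Raw inverted tables are smoothed by thin-plate-spline RBF interpolation
through the defined bins (the `smoothing` ridge parameter trades fidelity
for noise suppression; 0 interpolates exactly). Boundary finalization
then applies kind-specific rules:

* **bond/angle** — unsampled edges are continued by quadratics matched in
  value and slope to a local least-squares fit, with a curvature floor
  (200 kcal mol⁻¹ nm⁻², 10⁻³ kcal mol⁻¹ deg⁻²) so the walls confine;
* **pair** — the table is regridded to end exactly at the cutoff
  (default 2 nm); the unsampled core is continued by the same repulsive
  quadratic rule; the final 15 % of the range is replaced by a quintic
  matched in value, slope and curvature at the blend start and reaching
  zero value, force and curvature at the cutoff. The blend-start
  derivatives come from a one-sided least-squares quadratic over the
  trailing ten inner bins — one-sided so that finalization is bit-wise
  idempotent, least-squares so that single-bin histogram noise cannot
  steer the blend;
* **torsion** — periodic continuation; U and U′ are continuous across
  ±180° by construction.

Finalized tables carry an explicit force column (−dU/dx): the cubic
spline of the final grid values inside, the analytic quintic derivative
in the blend window, identically zero at the cutoff. Tables round-trip
bit-exactly through the internal text format and to ~10⁻¹⁰ through the
LAMMPS table dialect (`units real`: Å, kcal/mol; one keyword block per
interaction, `N <count>` header, indexed coordinate/energy/force rows).

## Canonical sampling

The sampler assembles the Hamiltonian from tabulated bonded terms,
tabulated short-range pair terms (zero beyond the cutoff, exclusions
honoured) and cutoff Coulomb `q_i q_j / (4πε₀ ε r)` with uniform relative
permittivity ε = 78 emulating aqueous screening. Tables are evaluated
through cubic splines, so forces are the exact negative gradient of the
energy (verified by central differences to 10⁻⁵ kcal mol⁻¹ nm⁻¹); below a
pair table's first grid point the potential continues linearly with the
boundary slope, a steep repulsive wall without spline extrapolation
artefacts. Long-range electrostatics beyond the cutoff is deliberately
omitted: desk-scale lipid systems here are near-neutral per bead and the
2 nm cutoff spans several screening lengths at ε = 78; a mesh-Ewald
treatment is a known limitation for strongly charged systems.

Dynamics is BAOAB Langevin with a 10 fs step and 0.5 ps friction time
constant at 303 K by default; bead masses are the mapped atomistic
masses. Initial configurations may be supplied, or drawn uniformly and
relaxed by L-BFGS energy minimization (out-of-table trial configurations
act as a barrier for the line search). A Metropolis single-particle mode
exists for exactness checks on tiny systems; off-table trial moves are
hard-wall rejections. Identical seeds give bit-identical trajectories.

Non-bonded pairs use a Verlet neighbour list (interaction radius + 0.4 nm
skin) rebuilt whenever any bead has moved more than half the skin since
the last build — a criterion that guarantees the list misses no
interacting pair, so energies and forces are identical to the full O(N²)
evaluation. The rebuild itself is a vectorised O(N²) pass; at the
≤ ~1500-bead scales this package targets it costs about one force
evaluation and amortises over ~50–100 steps, which is why a cell/bin
structure was not worth its complexity. Systems with fewer than 5000
candidate pairs skip the list.

Note that implicit-solvent CG dynamics is artificially accelerated
(no solvent friction on the configurational flow beyond the thermostat);
trajectories here serve configurational sampling, and no time rescaling
is applied or implied.

## Phase observables

* **z-density profile** — per-selection number densities along an axis,
  centred per frame on the circular mean of the selected beads' axial
  coordinates (a circular mean handles structures straddling the periodic
  boundary; plain centre of mass fails there).
* **bilayer thickness** — peak-to-peak distance of the head-group (N+P)
  profile with parabolic refinement of the two modes; fewer than two
  resolvable maxima raises a "no bilayer" error rather than returning a
  number.
* **2D cross-section histogram and cylinder spacing** — bead counts in
  the plane perpendicular to the cylinder axis (0.2 nm bins). An
  implicit-solvent cylinder projects as a hollow ring, so the histogram
  is Gaussian-blurred (σ = 0.8 nm, of the order of the head-ring radius)
  before peak detection, collapsing each ring to a single blob; maxima
  above the 80th percentile of nonzero bins and at least 2 nm apart are
  refined to sub-bin positions, and the spacing is their modal
  nearest-neighbour distance. Detection is intended for the *head-group*
  density, where the rings are clean; tail beads fill the interstices
  and can promote spurious maxima at lattice hollows.
* **cone-angle order parameters** — per lipid, the angle between the two
  vectors from the P bead to the CdB beads (mid-tail) and to the terminal
  C4 beads (tail end). Wide angles mark the splayed inverted-cone shape
  of hexagonal packing; narrow angles the cylindrical bilayer shape.
* **area per lipid** — `A_L = 2 × lateral box area / n_lipids` for a
  two-leaflet bilayer.

## Synthetic study systems

All test inputs are generated in code, deterministically per seed.

* **Toy fluids** sample a single-type fluid from a known analytic pair
  potential (truncated-shifted Lennard-Jones; ε = 0.3 kcal/mol,
  σ = 0.4 nm, cutoff 1.2 nm, 200 particles at 4.7 nm⁻³, 303 K by
  default). They are the ground truth for potential-recovery
  experiments: by the Henderson uniqueness argument the pair potential
  that reproduces g(r) is unique, so an IBI+IMC loop run against the
  fluid's own RDF must recover the generating table. The bundled
  experiment (5 IBI + 6 IMC iterations, 8 000/16 000-step iterations)
  recovers it to well within 0.1 kcal/mol wherever g(r) > 0.1.
* **Ideal bilayer / hexagonal constructions** place replicated 14-bead
  lipids in noiseless lamellar or inverted-hexagonal geometry (head
  beads exactly at ±thickness/2; cylinders on a periodic triangular
  lattice with heads at the core radius). A small alternating lateral
  zigzag keeps chain beads non-collinear so every torsion is defined.
  They validate the observables by round trip: construct at a known
  geometry, measure, compare.
* **Synthetic restraining tables** (`synthetic_bilayer_tables`) hold a
  constructed phase together under thermal motion: harmonic bonded
  restraints around the construction's own mean geometry plus a mildly
  cohesive Lennard-Jones (ε = 0.5 kcal/mol, σ = 0.42 nm) between all
  bead types. They are labelled synthetic deliberately — they are *not*
  an inverted potential set, and measurements on phases thermalised with
  them test the sampling + analysis pipeline, not the fidelity of any
  coarse-grained force field.

What passing these tests shows: the machinery — mapping, histogramming,
inversion algebra, sampling, table plumbing, observables — is correct on
systems where the right answer is known by construction. What it does
not show: that a model derived from a real atomistic lipid trajectory
reproduces real phase behaviour; that requires the atomistic reference
data and production-scale sampling outside this package's test scope.

## Degenerate inputs and tie-breaks

Empty distributions, single-frame correlation estimates, grids exceeding
half the box, bonds outside table ranges, missing bead roles and
non-bilayer profiles all raise typed errors naming the offending
interaction or index — silent clipping is avoided everywhere. Angle
forces clamp sin ϑ at 10⁻⁸ (the force prefactor vanishes at the same
rate, so the clamped expression stays finite and correct in the limit).
Torsion histograms fold φ = −180° onto +180° so the support is exactly
(−180°, 180°]. Where several equally tall density peaks exist, thickness
estimation takes the taller mode on each side of the centre.

## Known limitations

Orthorhombic boxes only; cutoff Coulomb (no Ewald/PME); NVT only (no
barostat — production phase diagrams at fixed density emulate the
implicit-solvent convention of setting water content through lipid
density); pure-Python force loops cap practical system sizes at a few
thousand beads; the IMC correlation matrix is dense, so total bin counts
much beyond ~10³ become expensive.
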