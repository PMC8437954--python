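# Methods

`dynhelix` models the mechanics of dynamin helical filaments — the
GTPase collars that constrict and sever membrane necks during
endocytosis — at three levels: the arithmetic of helical symmetry, a
continuum elastic energy for the stalk filament, and a coarse-grained
relaxation simulator coupling bead filaments to a Helfrich membrane
tube.  It also provides the rigid-body measurement operators (Kabsch
superposition, hinge angles, interface conservation) used to compare
filament conformers at atomic resolution.

## Helical geometry

A filament strand is a circular helix of radius *r* (axis to
centerline) and pitch *p* (axial advance per turn).  With the reduced
pitch *h = p/2π*, curvature and twist density are

    κ = r / (h² + r²),     τ = h / (h² + r²),

with the exact inverse r = κ/(κ²+τ²), h = τ/(κ²+τ²).  The conversion
is an algebraic bijection for r > 0, p ≥ 0; κ = 0 (a straight
filament, infinite radius) is rejected on inversion; p = 0 (planar
ring) is supported.  Discrete cryoEM symmetry (rise per subunit in Å,
twist per subunit in degrees, start number, cyclic order) converts to
the continuous picture via strand pitch = rise × 360/twist.  Internal
lengths are nm; Å enters only through symmetry rises and atomic
coordinates and is converted on input.  Handedness is a flag
(default right-handed) because deposited helical parameters do not fix
it; flipping it only mirrors azimuths.

## Stalk-filament elasticity

The filament is an elastic rod with a preferred (spontaneous) curvature
and twist:

    E(κ, τ) = α_κ (κ − κ0)² + α_τ (τ − τ0)²   [kJ/mol per nm]

Defaults: α_κ = 3000 nm·kJ/mol, α_τ = 2700 nm·kJ/mol, κ0 = 0.058 nm⁻¹,
τ0 = 0.041 nm⁻¹ (values derived in prior molecular-dynamics work on the
stalk tetramer).  Energies are reported per dimer by multiplying by the
5.6 nm of filament contour a dimer occupies.  A constant GG-dimer
interaction term g0 (kJ/mol/nm) can be added; it is the same for all
helical families and thus cancels in every comparison, so it defaults
to 0.

The quadratic form vanishes exactly at (κ0, τ0), i.e. at
r\* = κ0/(κ0²+τ0²) ≈ 11.50 nm and p\* = 2π τ0/(κ0²+τ0²) ≈ 51.1 nm: the
relaxed filament is a *large-pitch* helix.  A k-start helix at rung
spacing d has strand pitch k·d, so at the one-start rung spacing of
10 nm a two-start helix (strand pitch 20 nm) is closer to p\* than a
one-start (10 nm) at the same radius — this is the energetic argument
for the two-start, super-constricted state, and the energy gap grows
monotonically as the radius shrinks below ~18 nm.

Numerics: landscapes are direct vectorized grid evaluations (default
r ∈ [5, 25] nm, p ∈ [5, 80] nm, 400×400); the fixed-pitch minimization
over radius uses bounded scalar search (`scipy` Brent, xatol 1e-10)
and warns when the minimizer lands on a bound; the global minimum is
closed-form and is cross-checked against dense grid search in the test
suite.  The filament-radius → membrane-lumen-diameter mapping is a
single subtractive offset (default 11.5 nm), calibrated so the
13.5 nm two-start filament radius maps to the ≈4 nm super-constricted
lumen; it is a configuration constant, not a fitted quantity.

## Membrane tube

The membrane is a Helfrich sheet with bending stiffness χ (k_BT) and
tension γ (k_BT/nm²), defaults χ = 24, γ = 0.03.  The convention is
bending density (χ/2)(2H)², which for a cylinder of radius r gives the
per-length energy πχ/r + 2πγr, minimized at r_eq = √(χ/2γ) = 20 nm
(40 nm diameter) for the defaults; this convention is chosen precisely
because it reproduces that equilibrium diameter.  Non-cylindrical
axisymmetric profiles r(z) on a uniform periodic grid use the full
mean curvature 2H = 1/(r√(1+r′²)) − r″/(1+r′²)^{3/2} with central
differences (second-order; exact for constant profiles).  Membrane
energies stay in k_BT and convert to kJ/mol (×2.494, i.e. T = 300 K,
configurable — no temperature is otherwise implied) only when combined
with filament energies.

## Constriction simulator

One bead per dimer (target spacing 5.6 nm).  Discrete curvature at a
bead is the Menger curvature of three consecutive beads (exact inverse
circumradius); discrete twist density at a bond is the signed dihedral
between the flanking bond planes divided by the local mean bond
length.  At dimer spacing these estimators are within ~0.1% (κ) and
~3% (τ) of the continuous formulas for helices in the relevant
(r, p) range.  The total energy is

* filament: Σ α_κ(κ_i−κ0)²Δs + Σ α_τ(τ_b−τ0)²Δs,
* bonds: stiff harmonics (k_bond = 1000 kJ/mol/nm²) around the target
  spacing instead of hard constraints,
* membrane: the periodic profile energy in kJ/mol,
* coupling: a soft radial harmonic (k_c = 100 kJ/mol/nm²) between each
  bead's distance from the axis and the tube radius at the bead's
  (periodically wrapped) axial position, linearly interpolated.  The
  radial offset between the stalk centerline and the membrane surface
  defaults to 0 and is configurable.

Relaxation is *passive*, joint gradient descent on bead positions and
tube radii: central-difference gradients (step 1e-5 nm, evaluated as
one vectorized batch), Barzilai–Borwein step length with monotone
backtracking (factor 0.5, Armijo condition), so accepted-step energies
are non-increasing by construction and runs are deterministic.  The
BB step was preferred over a fixed-step descent because the bond
stiffness makes the problem ill-conditioned; plain steepest descent
crawls.  Termination: per-step energy drop below `tol` with the
gradient infinity norm below `grad_tol`, or `max_steps`.

The GTP-driven motor — the force cycle by which GG dimers drag
neighbouring rungs — is deliberately *not* modelled; the simulator
demonstrates only the downhill, curvature-driven part of constriction
(a free filament relaxes to (r\*, p\*); a bare tube to r_eq; a coupled
two-start system started at the 40 nm tube equilibrium pulls the tube
below 20 nm).  Active constriction endpoints (e.g. 8 nm inner diameter
on millisecond timescales) are out of scope.

Relaxed helix parameters are *measured* with the same discrete
estimators used in the energy (mean interior κ, τ inverted to (r, p)),
which makes the measurement rigid-motion invariant and cancels the
finite-spacing discretization bias.

Problem sizes used in the shipped tests and checks — 16–24 beads per
strand, 20–40 nm periodic tubes at 0.5–1.5 nm grid spacing, ≤40k
descent steps — were chosen as the smallest systems whose endpoints sit
within the quoted tolerances of the closed-form minima; endpoints, not
trajectories, are the claim.

## Structure comparison

Superposition is closed-form Kabsch (SVD with determinant correction,
so reflections are never returned; collinear selections are rejected).
Atom pairing is by (chain, residue number, insertion code, atom name),
Cα-only by default, with a residue-name consistency check so shifted
or shuffled numbering fails loudly instead of silently mispairing.
The hinge angle between two conformers is a two-stage protocol: align
on one domain (removing the global motion), then superpose the second
domain and report that rotation's angle (always in [0°, 180°]), axis
(sign chosen so the screw translation is ≥ 0) and screw translation.
The protocol is invariant under global rigid motions of either input.
Interface conservation between chain pairs: contacts are residue pairs
with any Cα–Cα distance ≤ cutoff (default 10 Å); the Jaccard index
compares contact sets (undefined → null when both are empty), and an
interface RMSD is computed over the union of contacting residues after
single-chain alignment.

Shipped dynamin 1 domain ranges (G domain 33–293; BSE 1–32, 294–320,
711–746; Stalk 321–499, 643–710; PH 500–642) are approximate working
defaults in author numbering — deposited entries do not come with an
authoritative range set, so measurements on real coordinates should be
expected to shift by a few degrees with the exact ranges, and the
ranges are a TOML config users can replace.

## Synthetic fixtures

Generators produce: pseudo-Cα helical lattices at given symmetry
(optionally noise-perturbed), two-domain hinge pairs with recorded
ground-truth rotation (random points in two 15 Å spheres 40 Å apart —
geometric decoys, not physical proteins), displaced bead filaments,
and sinusoidal tube profiles.  Every stochastic fixture requires a
seed and embeds its full generating specification in metadata;
regeneration from metadata is bit-identical.  Passing tests on these
fixtures demonstrate the *operators* (rotation recovery to 0.1°
noiseless and 1° at σ = 0.2 Å; interface bookkeeping), not robustness
to real experimental pathologies (missing residues, alternate
conformers beyond highest-occupancy selection, domain-boundary
ambiguity).

## Known limitations

* The elastic treatment assumes constant κ, τ along the filament
  (uniform helices), as appropriate for long symmetric assemblies.
* No entropic contribution to multi-start stability: the model predicts
  three- and four-start helices would be lower-energy still, which is
  not what is observed; the energy alone does not close that question.
* The membrane has no Gaussian-curvature or spontaneous-curvature
  terms and cannot fission; the simulator has no thermal noise.
* Coupling between filament and membrane is a phenomenological
  harmonic, not a lipid-level interaction.
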