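# Methods

`scaffoldlab` characterizes periodic bone-scaffold microstructures defined by
implicit equations: it generates a unit cell at a prescribed porosity,
measures its morphology, computes its effective elastic moduli by periodic
homogenization, computes its Darcy permeability from a Stokes flow solve,
and fits the scaling laws that relate all of these to porosity.  This note
records the models, the numerical choices, and what the validation
geometries do and do not establish.

## Geometry generation

Eight topologies are supported.  Five are triply periodic minimal surfaces
(TPMS) given by trigonometric nodal approximations `U(x, y, z)` — Diamond,
Gyroid, Schwarz P, Fischer-Koch S and F-RD — and three are strut lattices —
Cube (12 cell edges), FD-Cube (edges plus the 12 face diagonals) and Octa
(the 12 edges of the octahedron spanned by the cell-face centers).  The
solid phase is `{U - C >= 0}` for TPMS cells and `{D <= w}` for strut
lattices, where `D` is a periodic distance to the strut skeleton and `w` the
strut half-width.  One cell edge (default 2.5 mm) maps onto one period of
the nodal equations.

Strut-lattice conventions are ours, not the source study's (which generated
them interactively in a CAD tool without printing dimensions): square strut
cross-sections for Cube and FD-Cube, circular for Octa.  Quantitative
reproduction is therefore only claimed for the TPMS topologies; the strut
lattices participate in rankings and property sweeps.

Porosity is the void fraction of the bounding cube, estimated by sampling
the field at voxel centers (an unbiased phase-fraction estimator).  The
level-set constant (or half-width) for a target porosity is found by
bisection on the monotone porosity-parameter curve; the nodal field is
sampled once per resolution, so each bisection step is a threshold count.
Tolerance 1e-3 on porosity, 60 iterations maximum; for axis-aligned strut
lattices the voxel porosity is a step function (whole rows of voxels switch
at once), so the best parameter seen is returned and can sit ~1 voxel row
from the target.

## Morphology

The inner surface — the solid/void interface, excluding the outer cube
faces — is triangulated by marching cubes on the continuous field sampled
at the `(n+1)^3` cell nodes, and its area is summed over triangles.  Using
the smooth field rather than the binary occupancy avoids the staircase
overestimate of voxel-face counting; a voxelized sphere's area is recovered
to well under 1% at 128 voxels per edge.  S/V is that area divided by the
nominal cell volume (units 1/mm).  Quadratics in porosity are fitted by
ordinary least squares to five-point ladders.

### The study porosity window

The source study fitted every property-porosity relation on five porosity
levels per topology without printing them, and the fitted coefficients are
*not* insensitive to that window: the three-parameter stiffness law is
nearly degenerate (curves agreeing to ~2% pointwise can differ by ~25% in
the exponent), k(phi) is not exactly exponential, and S/V(phi) is not
exactly quadratic, so the window moves every fitted parameter.  The window
is nevertheless identifiable from the published outputs.  S/V(phi) is
exactly symmetric about 0.5 for the balanced TPMS (Diamond, Gyroid,
Schwarz P) — the phase-swap congruence maps the solid at porosity phi onto
the solid at 1 - phi with the same interface — so a ladder symmetric about
0.5 forces a fitted quadratic with a1 = -a2 and a peak at exactly 0.5,
while the published quadratics peak near 0.52; and the study's
manufactured scaffolds span porosities "between 50% and 80%".  The package
therefore uses `pipeline.STUDY_LADDER = (0.5, 0.575, 0.65, 0.725, 0.8)`
for every comparison against published fit coefficients; with that one
uniform ladder the published Gibson-Ashby parameters, shear-compression
slopes, permeability rates and S/V quadratics reproduce simultaneously
(several to within a few percent).  Two caveats remain: the Schwarz P
solid network pinches off near phi ~ 0.79, so the top of the window sits
in its degenerate regime — its fitted stiffness exponent is hypersensitive
there, its shear-compression relation loses linearity (R^2 ~ 0.97 versus
the published > 0.99), and its highest-porosity points drop below the
G = E diagonal (consistent with the published fit's negative intercept,
which itself crosses the diagonal at small E); and the Fischer-Koch S
quadratic coefficient remains ~15% shallower than published.  The general-purpose `StudyConfig` default
ladder stays at {0.3 ... 0.7} for full-range property sweeps.

## Elastic homogenization

Effective stiffness comes from the periodic cell problem: impose a
macroscopic strain `E`, solve for the periodic fluctuation that restores
equilibrium, and volume-average the stress.  The paper-protocol load cases
are two uniaxial strains and one shear (magnitudes irrelevant in linear
elasticity); under the cubic symmetry of all eight topologies these yield
C11, C12 and C44.  A "fast" mode drops the redundant second axial case, and
a "full" mode runs all six strains and returns the whole 6x6 matrix (used
for the laminate checks, which are not cubic).  A cubic-symmetry residual —
the spread among independent estimates of each constant — guards the
reduction; TPMS cells at moderate porosity stay well under 2%.

The solver is a Galerkin spectral (FFT) method on the voxel grid in Mandel
notation: stress is evaluated voxelwise from the two isotropic phases
(Ti-6Al-4V solid, E = 110 GPa, nu = 0.34; soft void filler, E = 1 MPa,
nu = 0.45, retained for fidelity to the study's models — it contributes
~1e-5 of the solid stiffness and keeps the operator definite), projected
onto compatible strain fields in Fourier space, and the resulting SPD
operator is inverted by conjugate gradients.  The gradient symbol is the
centered staggered (2x2x2-corner, "rotated") difference rather than the
continuous Fourier symbol: it eliminates interface ringing, and at the
1.1e5 phase contrast it converges in ~150 CG iterations where one-sided
differences need ~700.  Modes with vanishing gradient symbol (the mean and
Nyquist combinations) carry no compatible strain and are projected out.
Default relative residual 1e-8; the porosity-ladder pipelines use 1e-6,
which changes the moduli by well under 1e-4 relative.

Engineering moduli use the cubic closed forms
`E_e = (C11 - C12)(C11 + 2 C12)/(C11 + C12)` and `G_e = C44`, normalized by
the solid's Young's modulus (110 GPa) and shear modulus (41.04 GPa).  An
optional composite-voxel mode replaces surface-cut voxels by oriented
two-phase laminates (layered-medium averaging with the local interface
normal); it reproduces off-grid laminates exactly and is kept as a
cross-check, but it is slower to converge and less accurate than sharp
voxels for the cubic moduli of these cells, so sharp voxelization is the
default.

Shear bookkeeping caveat: the source study's printed shear relations imply
relative shear moduli above 1 and above the Voigt bound at low porosity,
which is impossible for `C44 / G_solid`; the factor of two indicates its
shear load case was bookkept as the tensor strain component, making its
reported shear moduli `2 C44 / G_solid`.  This package reports the physical
`G_e = C44` everywhere; comparisons against the study's printed
shear-compression slopes must double it (the acceptance layer does, and
says so).

Mesh convergence (`convergence_study`) has two modes.  "geometry" mode
re-voxelizes the implicit surface at each resolution, so the staircase
geometry perturbation (first-order in the voxel size, ~1.3% change between
64^3 and 96^3 for the Gyroid cell) rides on top of the solver error.
"mesh" mode freezes the geometry voxelized at a base resolution and refines
only the solution grid by integer factors — the analog of refining an FE
mesh on a fixed solid model, which is what the source study's convergence
rule describes.  For the study's convergence geometry (Gyroid at 50%
porosity, base 32^3) the per-refinement changes of the normalized moduli
are 0.81%, 0.51% and 0.08% across the 32-64-96-128 grids, so the
refine-until-<0.5% rule converges at the 96-to-128 step (at 51% porosity
the 64-to-96 change is already 0.49% — the rule's crossing point is
geometry-sensitive at the tenth-of-a-percent level).

## Permeability

At the protocol inlet velocity (0.1 mm/s of water through millimeter-scale
pores) the Reynolds number is ~1e-4, so the laminar flow solve is the
steady incompressible Stokes system.  It is discretized on a staggered
(MAC) grid over the void voxels of a tiled assembly: uniform normal inlet
velocity, zero outlet gauge pressure (with a zero-gradient velocity ghost),
no-slip on solid surfaces and the four lateral walls (mirror ghosts at the
half-voxel wall planes; a slip option provides symmetry planes for the
analytic checks).  Four fully open buffer layers are added before and after
the sample; the reported pressure drop is read between the sample's entry
and exit planes (layer means interpolated onto the planes), mirroring the
average-inlet-pressure protocol.  A connected-component percolation check
precedes the solve; void pockets disconnected from the inlet are removed,
and a non-percolating domain raises a blocked-domain error.  The symmetric
indefinite saddle-point system is solved by MINRES with a diagonal block
preconditioner (velocity: diag of the viscous block; pressure: h^3/mu mass
scaling) to a relative residual of 1e-9.

Darcy permeability is `k = Q mu L / (A dP)` with the superficial-velocity
convention (`A` is the full cross-section).  For comparisons against
fully-developed closed forms (plane channel, circular and square ducts) a
gradient-based pressure drop is provided — fitted to the interior layer
means — because the protocol drop includes entrance and contraction losses
that the textbook formulas exclude; the circular-channel permeability is
then recovered within ~2% at 64 voxels per edge.  The Kozeny-Carman
counterpart is `k* = phi^3 / (2 s^2)` with the specific surface `s` (1/m)
measured on the single-cell iso-surface.

Default flow domains are scaled to desk size: a 3^3 tiling at 16-24 voxels
per cell edge (the domain-size error of 3^3 vs 4^3 tilings is at the
percent level, consistent with the study's own 4^3-vs-5^3 check).  Absolute
permeabilities carry more discretization error than the morphology or
elasticity results — narrow throats at low porosity are a few voxels wide —
which flattens the fitted exponential porosity-rate at the coarsest
settings; the per-topology problem sizes used by the acceptance script are
recorded in its command-line defaults.

## Scaling laws

Relative compressive modulus versus relative density `rho = 1 - phi` is
fitted with the cellular-solids law `E* = C1 rho^n + E0` by unconstrained
nonlinear least squares with deterministic multi-starts over
`n0 in {1, 1.5, 2, 2.5}` (best residual wins).  The exponent classifies the
strut deformation mode: bending-dominated for `n >= 1.7`, stretching below
(published exponents for these topologies cluster below 1.5 and above 1.9,
so any cut between reproduces the published labels).  Beware that the
three-parameter family is ill-conditioned on five-point ladders: curves
agreeing to ~2% pointwise can differ by ~25% in `n` with compensating
`C1`/`E0` shifts, and the fitted parameters are sensitive to the porosity
window — fits from a [0.3, 0.7] ladder and from a higher-porosity window
extrapolate differently at the dense end, where the law itself breaks down
(`C1 + E0 < 1` forces `E* < 1` at full density).  The shear-compression
relation is an ordinary least-squares line of `G_s` on `E_c`.

## Validation fixtures

The analytic geometries (laminates, spheres, channels, full/empty cells)
carry closed forms: exact porosity and area; Voigt/Reuss and exact series
moduli for zero-Poisson laminates; Hagen-Poiseuille and square-duct
permeabilities under the superficial-velocity convention.  They validate
each solver stage independently of the TPMS pipeline.  What they do not
establish: accuracy on thin, curved, marginally-resolved features — that is
what the mesh-convergence studies and the published-value comparisons
probe — and any effect present in manufactured scaffolds (surface
roughness, partially melted powder, geometric deviation from the nominal
model), which the source study addressed by experiment and this package
does not model.

## Determinism

Nothing in the package draws random numbers: field evaluation, bisection,
CG/MINRES with fixed ordering, and least squares are all deterministic, so
rerunning any configuration reproduces every number exactly.  Seeds
accepted by the CLI and the acceptance script are recorded in manifests for
provenance only.
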