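# Methods

`tonosim` simulates non-contact tonometry (NCT) on an idealized
three-dimensional human eye at desk scale: a calibrated air pulse
deforms the cornea of a closed, pressurized globe, and Corvis-style
biomarkers are extracted from the computed deformation history.  This
note records the model, its assumptions, the numerical choices, and the
limits of what the synthetic test problems can show.

## Structural model

**Geometry.** The eye is an idealized quarter model of the anterior
half-globe: scleral outer radius 12 mm (wall 0.8 mm), corneal anterior
radius 7.8 mm (central thickness 0.55 mm), a limbal blend band of ±3°
around the cornea–sclera intersection circle (limbal radius 5.9 mm),
and, inside, a crystalline lens (nucleus + cortex, equatorial radius
4.5 mm, thickness 3.6 mm) suspended by a ciliary zonule membrane
attached at a polar angle of 38°, with a vitreous membrane lining the
posterior lens surface.  These dimensions are literature-typical
averages and are all configurable; none of the reported acceptance
quantities depends on them beyond their stated tolerances.  Coordinates:
`y` is the optical axis (apex at maximal `y`), `x` nasal-temporal, `z`
superior-inferior.  Symmetry conditions act on the `x = 0` and `z = 0`
planes; the equatorial cut `y = 0` carries a symmetry condition by
default (`u_y = 0`), which represents the mirrored full globe and, with
the two lateral planes, removes all rigid modes.  A clamped bottom is
available in the configuration.

**Meshing.** The corneo-scleral wall is swept from a two-block
butterfly surface grid (bilinear inner square plus a transition ring,
worst cell scaled Jacobian ≈ 0.86 in the parametric plane) joined to a
polar annulus whose rings are placed exactly on the part boundaries and
the zonule circle; the wall is extruded radially with 2–8 element
layers.  The lens is an independent butterfly-grid solid; it shares no
nodes with the wall and is connected only through the zonule membrane.
Minimum scaled hex Jacobian at the default geometry is ≈ 0.6.

**Materials.** Cornea and limbus are anisotropic nearly-incompressible
hyperelastic solids (Holzapfel–Gasser–Ogden):

Ψ = C10 (Ī₁ − 3) + k₁/(2k₂) Σᵢ₌₄,₆ [exp(k₂ (Īᵢ − 1)²) − 1] + U(J)

with two mutually orthogonal in-plane collagen families in the cornea
(projections of the global x and z axes onto the local tangent plane)
and one circumferential family in the limbus.  Fibre terms act only in
tension (Īᵢ > 1): during the puff the anterior surface goes into
compression and only the matrix carries it, which is essential to the
bending response.  Reference constants: C10 = 0.05 MPa, k₁ = 0.010 MPa,
k₂ = 100, ρ = 0.0011 g/mm³.  The sclera is the isotropic special case
(neo-Hookean, C10 = 0.8 MPa).  The volumetric term defaults to the
quadratic penalty U(J) = κ/2 (J − 1)² with κ = 10³·C10 per part; the
printed inverse-compressibility convention (1/κ)(J − 1)² is a
configuration switch — the two differ only in how κ is interpreted, and
κ is a penalty here either way.

Lens (nucleus E = 0.0003 MPa, cortex 0.35 MPa), zonule and vitreous
membrane (0.35 MPa) are Saint Venant–Kirchhoff (linear elastic, finite
rotation safe).  Their Poisson ratio defaults to ν = 0.4999: these are
hydrated, volume-conserving tissues, and with the very soft nucleus any
appreciable compressibility is unphysical — at ν = 0.47 the nucleus
bulk modulus (≈ 0.002 MPa) falls below the 15 mmHg IOP and the lens
collapses by more than a millimetre in an isolated-lens experiment.

**Humors.** The aqueous and vitreous are not meshed.  Each is an
enclosed cavity whose volume is evaluated by the divergence theorem
over an oriented facet list (the symmetry-plane caps pass through the
origin and contribute no flux); a single pressure per cavity acts as a
follower load that is the exact gradient of p·V.  Three modes: *inflow*
(a tracked target volume grows and the penalty p = K_c (V_t − V) sets
the pressure — the pressurization stage), *closed* (the volume is
conserved exactly via a Lagrange multiplier; the physiological state
during the puff, which is what makes the IOP rise), and *constant
pressure* (the open-system control).

## Discretization and solvers

Total-Lagrangian hex8 elements with selective reduced integration
(isochoric terms on the 2×2×2 Gauss rule, volumetric penalty at the
centroid) prevent volumetric locking at κ/μ ≈ 500; the lens solids use
full integration (they are soft and nearly unloaded deviatorically).
Zonule and vitreous membrane are 4-node total-Lagrangian membranes
(plane-stress StVK, thickness 0.05 mm); bending is negligible at that
thickness.  Because the lens floats on membranes, its nodes carry tiny
grounding springs (10⁻⁶ MPa·mm, configurable) that regularize the
otherwise singular static out-of-plane modes; the springs are ~10⁴
times softer than the membranes and do not measurably change any
reported quantity.

Dynamics: implicit Newmark (β = 0.3025, γ = 0.6, mildly dissipative;
configurable) with lumped mass and mass-weighted damping c·M·v,
c = 0.1 ms⁻¹ for all parts.  The dissipative pair is deliberate: the
thin wall carries high-frequency thickness-stretch modes far below the
working time step, and without algorithmic damping the closed-cavity
pressure rings unphysically.  The price is an energy-ledger residual of
order 10% of the external work at the working step (the energy removed
from those modes); with the energy-conserving pair (γ = 1/2, β = 1/4)
and a resolved step the ledger closes below 1%, which is how the audit
is verified.  The unit system is mm–g–ms–MPa.  Newton's
method solves each step monolithically with the cavity pressures as
bordered unknowns; globalization combines a residual-norm backtracking
line search (updates that grow the residual or invert elements are
halved before acceptance) with modified-Newton reuse of the sparse LU
factorization, refactorizing whenever the frozen tangent stops
contracting.  Failed steps are sub-stepped (dt halving, 4 levels).
Quasi-static solves use the same machinery without inertia and with
adaptive load cutback.

**Prestress.** The built geometry is the pressurized (imaged) state, so
the stress-free reference is recovered with the classical fixed point
X ← X − (x(X) − x_target), inflating each iterate to the target IOP;
convergence is declared when the maximum nodal mismatch drops below
10⁻³ mm (small against the corneal thickness) or after 20 iterations.
The update is applied to the corneo-scleral shell only by default: the
nearly-floating lens makes the map non-contractive, while its own
prestress deformation is irrelevant (it settles freely during
inflation).  Fibre directions are defined on the imaged geometry and
held fixed.  The defining round-trip property — re-inflating the
recovered reference reproduces the imaged geometry — is asserted in the
test suite.

## Air-jet surrogate

A resolved moving-mesh CFD of the pulse is out of scope; the surrogate
keeps the mechanism that matters — the pressure footprint depends on
the *deforming* shape — while replacing the flow solve with an
impingement model evaluated on the current surface each staggered
sub-iteration:

p(face) = g_c · q(v) · cos²θ · φ(r/r₀) − suction term

* q = ½ ρ_air v², ρ_air = 1.25·10⁻⁶ g/mm³ (q = 67.5 mmHg at 120 m/s);
* v(t): Gaussian inlet pulse, peak 120 mm/ms, 20 ms window (40–60 ms
  after 30 ms of inflation and 10 ms of rest), σ = period/6 with the
  baseline subtracted so the pulse is exactly zero outside the window;
* θ: angle between the face normal and the jet axis; r: distance from
  the instantaneous stagnation point (surface point closest to the
  nozzle axis, ties toward the apex);
* φ(x) = exp(−(r/w)²)(1 − x²)² with support radius r₀ = 5.5 mm and core
  width w = 2 nozzle radii (2.4 mm) — impingement footprints scale with
  the orifice;
* the suction term c_s·q acts on a Gaussian annulus (width 1 mm) around
  the curvature-reversal rim of the meridian profile, with an amplitude
  that ramps smoothly with the rim prominence (a discontinuous switch
  destabilizes the staggered coupling near the applanation instants).

The constants were calibrated once against the published impingement
anchors — apex peak pressure ≈ 2.25× the free-jet dynamic pressure
(g_c = 2.25), the 5.5 mm footprint, and the existence of a negative
pressure lobe at highest concavity (c_s = 0.8) — and are configuration
values, not fitting knobs of the structural model.  The coupling is
staggered and sub-iterated per time step until the interface
displacement update falls below 10⁻⁴ mm, with adaptive pressure
under-relaxation.

The free-jet centerline helper uses a potential core of five nozzle
diameters followed by 1/s decay — enough to reproduce the observed
near-constancy of the peak velocity over the 11 mm standoff; it plays
no role in the coupled load.

## Biomarkers

HC is the instant of maximal apex displacement; the deflection
amplitude (DA) is that displacement along the jet axis.  A1/A2 are the
first/last instants at which the central 3 mm of the mirrored 8 mm
meridian profile is flat (RMS deviation from its best-fit line below
2 µm); when the discretized profile never meets the RMS threshold the
zero crossing of the fitted central curvature is interpolated in time —
the same continuum condition, robust at coarse resolution.  The peak
distance (PD) is the horizontal distance between the two highest local
elevation maxima at HC, refined by parabolic interpolation (sub-grid
accuracy matters at desk-scale meshes).  Elevation maxima, not
curvature extrema, define the peaks.  An optional resampling to 140
frames over 33 ms emulates the instrument's camera.

## Study drivers

The sensitivity study is a 2⁵ full factorial over C10_c, k₁, k₂, C10_s
(±50% around the reference values) and IOP (8–22 mmHg), with contrast
main effects, selected two-way interactions, sums of squares, and a
Pearson matrix over the coded design and the responses.  Effects are
reported both raw and standardized (contrast / response SD), since the
normalization of published effect sizes varies.  A balanced 2⁵⁻²
fraction (8 runs) serves as the smoke subset.  The reduced-range study
repeats the machinery with IOP ∈ {12, 15} mmHg.  Batch rows that fail
are flagged and kept, never dropped.  The ablation driver reruns the
reference puff without lens, zonule and vitreous membrane (single
merged cavity) and reports relative biomarker differences.

## Problem sizes and tolerances

The package's reference scenario runs at deliberately coarse desk-scale
resolution, chosen near the coarsest discretization whose through-
thickness refinement changes the monitored apex displacement by less
than 1%: surface preset "ultra" (≈ 200 wall hexes per layer), three
layers through the wall, Δt = 0.25 ms (matching the instrument's 140
frames / 33 ms cadence), Newton relative tolerance 10⁻⁶.  The factorial
batch drops to two wall layers and a relaxed prestress tolerance
(5·10⁻³ mm) and records only through the concavity peak, since its
three biomarkers are all evaluated at HC and only their signs and
ordering are asserted.  The mesh
convergence driver repeats prestress + inflation + a moderate static
apex load (60 mmHg peak) over 3–6 wall layers.

## What the synthetic fixtures do and do not show

The fixture generators provide ground-truth data with known answers:
uniaxial stress–stretch curves sampled from the constitutive law itself
(so parameter recovery validates the fitter, not the law), profile
histories with constructed applanation instants and peak positions, and
factorial response tables from stated linear + interaction models.
Passing those tests demonstrates that the machinery is correct, not
that the physical model reproduces any particular eye: real corneas
have fibre dispersion, regional thickness variation and viscoelasticity
that the model deliberately omits, and real Corvis profiles carry
measurement noise far above the numerical error asserted here.

## Known limitations

* The air load is a calibrated surrogate, not a resolved flow: absolute
  apex pressures away from the calibration anchors (and any
  turbulence-driven confinement dynamics) are approximate, and the
  velocity field is not modelled at all.  In particular the confinement
  gain is constant, so the apex pressure follows the symmetric inlet
  pulse; the published asymmetry between the pressure maxima at first
  and second applanation — a consequence of concavity-driven confinement
  growth delaying the pressure peak — is not reproduced.
* Collagen fibre dispersion is ignored (two discrete families), as are
  viscoelasticity and patient-specific geometry.
* The quarter model with a mirrored equator cannot represent whole-eye
  translation or asymmetric deformation.
* Membrane elements carry no bending; the zonule is a uniform elastic
  ring rather than discrete fibre bundles.
* The published full-resolution effect-size magnitudes are not expected
  to be reproduced at desk scale; only their signs and ordering are
  asserted.
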