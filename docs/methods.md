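# Methods

## The alignment model

Cells are treated as collections of stress fibers that sample every spatial
direction and disassemble under compression (strain avoidance). For a
small-strain tensor ε and a unit direction *u*, the directional elongation
is the linearized fiber stretch

    e(u) = 1 + uᵀ ε u ,

with e < 1 meaning compression. Two strain states contribute:

- **Cyclic stretch.** The 1 Hz protocol is represented quasi-statically by
  its peak-amplitude field (stationary solves; inertia and viscoelasticity
  are irrelevant at these rates). The orienting effect of a cyclic cue
  comes from its *compressive* half-cycle, so `e_cyclic(u)` is evaluated on
  the negated peak tensor: a pure uniaxial stretch gives e_cyclic < 1 along
  the stretch axis and maximal elongation perpendicular to it. The positive
  sign convention would predict alignment parallel to stretch,
  contradicting the perpendicular alignment universally observed on
  stretched 2D substrates.
- **Self-condensation.** Cellular traction densifies the hydrogel (or the
  monolayer) from the moment of seeding. It is encoded as an isotropic
  stress-free eigenstrain −c·I over the cell-bearing region — the standard
  well-posed encoding of a direction-free homogeneous volumetric
  contraction; monolayers contract only in-plane (biaxial eigenstrain,
  components x and y). `e_self(u)` uses the resulting constrained strain
  field directly.

The cues combine through the polynomial addition law

    e_tot = ( e_cyclic^−n + e_self^−n )^(−1/n) ,   n = 4 .

Adding negative powers weights compression (e < 1) more heavily than
extension; the −1/n exponent restores length dimensions, so aligned cues
scale the result proportionally. The law is symmetric, homogeneous of
degree one, strictly increasing in each argument, bounded above by
min(e_cyclic, e_self), and tends to that minimum as n → ∞ (exactly
min·2^(−1/n) at equal arguments — 1.08 % below the minimum at n = 64,
which is the saturated worst case of the convergence bound).

The predicted orientation is the direction maximising e_tot over a 0.5°
axial grid, searched in the substrate (x–y) plane — all reported
orientations are in-plane image measurements — and folded to [0°, 90°]
from the stretch axis. A full-3D direction search is available behind
`CombinationParams(search_space="full_3d")`. Exactly flat profiles are
flagged "no preferred direction" instead of returning an arbitrary angle;
grid ties are broken toward the smaller folded angle and flagged.

Linearized elongation (1 + uᵀεu) is used instead of the finite-strain fiber
stretch √(1 + 2uᵀεu), consistent with the all-linear material model; the
difference is below 1 % up to 10 % fiber strain and below 2 % at the 15 %
protocol amplitude (the compressive side is the worst case).

## Geometry, materials, and meshes

The chamber is parametric (defaults: 20 × 10 × 10 mm, 0.1 / 5 mm sidewalls,
2 mm bottom wall) with a square-groove array — 350 × 350 µm cross-section
at 350 µm spacing — recessed into the floor, running along the stretch axis
or across it. The number of grooves follows from the available floor width
divided by the 700 µm pitch (the device leaves it unspecified; 7 fit the
default chamber). Materials are linear, homogeneous, isotropic: cells
E = 30 kPa, hydrogel E = 21 kPa (ν = 0.2), PDMS E = 0.98 MPa; Poisson
ratios nominally 0.5 are computed as 0.49, handled by selective reduced
integration of the volumetric stiffness so that near-incompressibility does
not lock the bilinear elements. Monolayers are modelled as a 10 µm film — a
typical monolayer height, configurable — following the substrate
topography.

Meshes are conforming tensor-product grids (quads in 2D, hexahedra in 3D)
with material breakpoints snapped onto grid lines, so region tags partition
elements exactly and mesh volume equals solid volume. Inside grooves the
element size is capped at 0.1 mm when refinement is requested. Export and
import go through Gmsh MSH 2.2 (tags round-trip) and legacy ASCII VTK.

## Reduced sections and boundary conditions

The orientation model needs only the groove-local strain state, so the
canonical campaigns run on 2D reductions of the chamber rather than the
full 3D solid (the 3D hexahedral element exists and is verified by the
same patch and free-contraction tests):

- **Stretch along grooves**: a transverse (y–z) cross-section spanning
  three groove pitches, driven by the known axial strain as a generalized
  plane-strain condition (the membrane transmits the applied strain
  essentially unchanged along a groove), lateral edges free so the
  membrane's transverse Poisson contraction develops, rigid-body modes
  pinned.
- **Stretch across grooves**: a longitudinal (x–z) plane-strain section
  through the full 20 mm groove profile, one end clamped (fully built-in),
  the other prescribed the axial end displacement derived from the applied
  strain and the modelled gauge length. The along-groove direction is
  closed with the membrane's transverse Poisson contraction −ν·ε. This
  section captures the bending of the asymmetric notched profile, which is
  what concentrates strain at the groove floors and in the hydrogel above
  them.
- **Hydrogel self-condensation**: the 350 × 350 µm gel cross-section alone,
  in plane strain along the groove axis (floor adhesion suppresses
  longitudinal contraction far from the chamber ends), with the floor
  bonded (the PDMS is ~47× stiffer than the gel, so the substrate is taken
  as rigid for this load), detachment springs on the lateral walls, and a
  free top surface.
- **Monolayer self-condensation**: the film on the full PDMS profile with
  in-plane biaxial eigenstrain; the substrate's stiffness decides how much
  strain the film achieves (almost none, which is the physics of the
  stretch-dominated 2D results).
- **Flat (ungrooved) scenarios**: layered sections; because a reduced
  section artificially distinguishes the in-plane axes (plane constraint
  along one, strip edges along the other) while the real unstructured
  chamber centre is in-plane symmetric under homogeneous contraction, the
  flat self-condensation tensor is isotropized in-plane. Static flat
  cultures then correctly report "no preferred direction".

The applied end displacement is always derived from the applied engineering
strain and the modelled gauge length (15 % for the alignment protocol, 36 %
for the transmission campaign); an absolute displacement can be prescribed
instead. Probes sit near the chamber centre on the groove midline: at
groove half-height for 3D seeding, at the film mid-plane for monolayers,
just below the surface when unseeded. Predictions use a single
representative probe; profiles can be averaged externally if desired.

## Calibration

Two quantities have no measured values and are calibrated once, before any
comparison, from stated physics:

- **Sidewall spring stiffness** (Robin coefficient, Pa/m). Extended culture
  partially detaches the gel from the groove walls. The stiffness is set by
  bracketed root finding so the cross-groove contraction at the groove
  centre reaches 50 % (configurable) of its fully detached value; the
  calibrated default is ≈ 8.9 × 10⁷ Pa/m. The limits are verified: k → 0
  reproduces the traction-free solution, k → ∞ the bonded one, and the
  contraction is monotone in k.
- **Contraction eigenstrain magnitude.** In the soft gel, cellular and
  applied strains are of similar magnitude, so c is rescaled (exactly, by
  linearity) until the peak in-plane self-elongation deficit at the probe
  equals the applied amplitude (0.15); the calibrated default is c ≈ 0.26.
  The *same* eigenstrain drives the monolayer scenarios, where the stiff
  substrate suppresses the realized strain — calibrating the 2D film strain
  itself to 0.15 would be inconsistent with a substrate the cells cannot
  deform. The sensitivity of the oblique prediction to c is reported as a
  monotone sweep (90° at c = 0 falling toward 0° as c dominates), within
  the range where directional shortening stays below 100 % (the linearized
  elongation is meaningless beyond).

## Synthetic data generators

- **Cell images** emulate stained elongated cells: ellipse profiles at
  axial angles drawn from a von Mises distribution on the doubled angle
  (concentration 0 = isotropic), uniform positions, additive Gaussian
  noise; deterministic per seed. They do *not* emulate cell-cell contact
  remodelling, intensity inhomogeneity, or out-of-focus light — recovery
  tests therefore validate the analysis chain, not segmentation robustness
  on real micrographs.
- **Beating videos** emulate periodic intensity pulsation (sinusoid or
  once-per-cycle Gaussian flash) at a set rate — 60 and 120 beats/min are
  used in tests, the unstimulated and stimulated culture rates — with a
  linear spatial phase lag and additive noise. They do not emulate motion
  artefacts, drift, or rate variability; frequency-recovery tests
  demonstrate the detector's accuracy (≤ 5 % error up to 20 % noise), not
  performance on arrhythmic cultures.

Orientation quantification uses the structure tensor (Gaussian gradient
scale 2 px) with pixels weighted by gradient energy where coherence exceeds
0.2; the analysis method for the experimental orientation histograms is not
otherwise specified, and the structure tensor is the standard, well-testable
choice. Both the circular mean angle (folded to [0°, 90°]) and the order
parameter |⟨e^{2iθ}⟩| are reported, since "degree of orientation" can mean
either. Area fractions threshold at Otsu's value when none is given.
Beating maps use 16 px blocks, peak prominence 0.2× the trace amplitude, a
0.25 s minimum inter-peak interval, the *median* inter-peak interval for
the frequency (robust to one missed beat), and the global mean trace as the
phase reference (a designated reference block is available and then has
phase exactly 0).

## Numerical choices

- Bilinear/trilinear elements, 2×2(×2) Gauss quadrature, volumetric term at
  the element centre (selective reduced integration); exact patch-test
  behaviour on the axis-aligned meshes is preserved and verified to
  machine precision.
- Sparse direct solve (`scipy.sparse.linalg.spsolve`); self-equilibrated
  load cases are pinned by minimal point constraints whose reactions
  vanish.
- Probing evaluates the shape-function gradients at the point's local
  coordinates (axis-aligned element lookup); strain fields are exact
  symmetric gradients of the discrete displacement.
- Discrete energy decreases monotonically under nested refinement
  (verified on three levels of the grooved section).
- Degenerate inputs are errors, not silent defaults: non-positive
  elongations, non-unit directions, probes outside the mesh, grooves that
  do not fit the chamber, under-sampled video specifications.

## Problem sizes

The canonical campaigns run on meshes of roughly 500–8 000 elements
(thousands to ~20 000 unknowns): the groove gel cross-section is 8 × 8
elements, the three-pitch transverse section ~1 000, and the full-length
grooved longitudinal section ~4 000. These sizes put every strain value in
the asymptotic range of the verification suite while keeping the whole
acceptance computation at a few seconds on one core; halving the element
size changes the four predicted angles by less than the 0.5° angle grid.

## Known limitations

- The reduced sections neglect out-of-plane bending of the transverse
  cross-section and treat the along-groove closure with a uniform Poisson
  estimate; full-chamber 3D solves would refine both at much higher cost.
- The 2D monolayer predictions are insensitive to the film's edge details
  by construction (stiff substrate); the model therefore predicts 90°
  rather than the slightly smaller observed/modelled values for grooved 2D
  substrates — the stretch-dominance conclusion is unaffected.
- The model predicts a single bulk angle per configuration; it does not
  resolve gradual transmural rotation, fiber dispersion, or any kinetics of
  reorientation, and strain avoidance is treated as the only alignment
  mechanism (no nanotopography, stiffness-gradient, or cell-cell coupling
  effects).
- Angles are folded to [0°, 90°]; the handedness of an oblique alignment
  (±θ) is not distinguished, matching how the experimental angles are
  reported.
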