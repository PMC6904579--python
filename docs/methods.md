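# Methods

## The model system

Chitons (Polyplacophora) carry, around their eight shell plates, a flexible
girdle covered by hundreds of small, almost purely aragonitic scales.  Each
dorsal girdle scale combines a diamond-footprint prismatic base, embedded in
soft tissue, with a hook-like dorsal cap that leans over the scale in front
of it.  The tessellated array is simultaneously protective (complete dorsal
coverage, jamming under concave bending) and flexible (free convex bending,
scale rotation in the soft regime).  This package implements a parametric
generative model of such scales, mesh-based morphometrics of the standard
descriptor set, tessellated armor assembly with printable output, and a
rigid-scale bending-contact analysis of the orientation-dependent
interlocking mechanism.

## Parametric scale model

### Parameters and markers

A scale is defined by **17 free parameters** positioning **20 geometric
markers** on three principal sections:

* **BASE** (4 parameters): diamond width `W`, length `L`, and two circular
  corner-fillet radii (front/back and side corners).  Markers: 4 diamond
  vertices + 4 fillet-arc midpoints.
* **YZ** (10 parameters): the sagittal silhouette.  Inclination `beta`
  (angle of the posterior basal edge above the base plane; the prismatic
  base leans *toward* the hook), inflection height `h1`, apex height `H`,
  imbrication `alpha`, hook reach (tip forward offset), tip height
  fraction, posterior inflection fraction, apex position fraction, and two
  bulge fractions shaping the hook underside (the cup) and the posterior
  crown.  Markers: posterior inflection, posterior mid, apex, crown, tip,
  underside, anterior inflection (7).  The two base corner positions are
  inherited from BASE.
* **XZ** (3 parameters): crown half-width profile — shoulder half-width and
  height fractions plus a roundness exponent.  Markers: 2 base corners
  (inherited from BASE), 2 shoulders, crown top (height inherited from YZ).

Angle convention: the hook axis (tip tangent) makes the angle
`theta = alpha + beta - 180` degrees with the base plane.  `alpha + beta <
180` therefore means the hook curls past horizontal and can overlap the
scale in front — the overlap-capability condition; parameter sets violating
it are rejected ("non-overlapping geometry").  The degenerate family
`alpha = 180, beta = 90` (no hook) is admitted explicitly and lofts to a
right prism by direct extrusion.

All curves are cubic interpolating splines, chord-length parameterized,
clamped where a tangent is part of the definition (basal edges leave at
`beta`; the outer hook surface arrives at the tip along the hook axis;
the apex tangent is horizontal).  Spline samples are cosine-clustered so
the fast tangent turns at clamped ends are resolved.

### Lofted solid

Pure spine-normal sectioning fails for strongly leaning scales: near the
flat base, planes normal to an oblique medial axis cut the base plane and
the section family degenerates.  The solid is therefore swept in three
zones whose section endpoints are anchored *on the boundary curves*:

1. **Prism zone** (`z < h1`): horizontal sections — exact cross-sections of
   the sheared prism.
2. **Elbow fan**: the posterior endpoint climbs from the inflection height
   along the posterior edge and crown to the apex while the anterior
   endpoint creeps up the first 15 % of the hook underside; sections fan
   smoothly around the anterior inflection.
3. **Flap zone**: sections span underside to outer hook surface, matched by
   normalized arc length from the tip, cosine-clustered toward the tip so
   the terminal tangent (and hence the measured `alpha`) is well resolved.
   The flap receives at least a quarter of the section budget.

Each section is the filleted BASE contour, affinely scaled to pass through
its two endpoints and the lateral half-width taken from the XZ profile.
The half-width is evaluated at the section *center height*, so the hook
keeps a broad cup rim rather than tapering to a point — matching the broad
overlapping caps of real scales and printed prototypes.  The mesh is capped
with the exact BASE contour below and collapses onto the hook tip above;
it is watertight by construction and validated (positive volume, no
degenerate faces).  The medial spine itself (base midpoint, prism medial
line, flap midcurve, hook tip) is exposed as `extract_spine`.

Defaults: 64 sections x 64 profile vertices.  Volume changes by < 0.2 %
when both are doubled (tested).  Optional micro-ornamentation (dorsal
ridges at 40 um spacing, posterior micro-bumps at 5 um) is available as a
vertex-displacement post-process and is off everywhere by default.

## Morphometrics

Measured from the closed mesh, mirroring how the descriptors are defined on
micro-CT geometry:

* `W`, `L`: extents of the basal slice of the footprint (the base diamond).
  The full bottom silhouette also contains the hook overhang and would
  overstate the *base* length of strongly imbricated scales.
* `H`: total height; `V`, centroid: divergence theorem on the closed mesh.
* `h1`: height where the anterior boundary of the sagittal (x = 0) section
  leaves the straight basal edge.  The onset is found from the smoothed
  discrete-curvature profile: noise floor from the basal part, first
  sustained rise, then the half-crossing of the local early-hook plateau
  (the unbiased onset estimate for a smoothed step).
* `beta`: total-least-squares line through the posterior basal edge of the
  sagittal section over heights 5–40 % of `H` (the basal straight region).
* `alpha`: interior angle at the inflection between the downward basal
  direction and the hook axis, where the hook axis is the arrival tangent
  of the *outer* hook surface at the tip (terminal chord of the sagittal
  section; sections cluster at the tip, making the chord a good tangent
  estimate).  The sagittal section is used instead of the projected
  silhouette because a cup-like hook's projected anterior boundary is its
  lateral rim envelope, which hides the hook axis.
* `A1`, `A2`: the transverse silhouette (projection along X) split by the
  vertical through the anteriormost point of the base footprint; `A1` is
  the overhang portion; `A_total = A1 + A2` and `H = h1 + h2` hold exactly
  by construction.
* Degenerate prisms (anterior edge with < 5 degrees total turning) report
  `h1 = H`, `alpha = 180` and the `degenerate` flag.  Doubly-curved scales
  (S-shaped flap) are detected from the integrated turning of the dorsal
  boundary above the basal region (> 45 degrees accumulated in *both*
  senses) and flagged `multi-inflection`; the first (lowest) inflection
  still defines `h1`.
* External meshes can be re-posed (`pose="auto"`): PCA of the base
  footprint aligns the long axis with Y, the apex side picks +Y, and the
  base drops to z = 0.  Residual alignment error is below ~2 % on the
  descriptor set.

Round-trip accuracy on the bundled presets (generate at defaults, then
measure): `alpha`, `beta` within 2 degrees; `W`, `L`, `H`, `h1` within 2 %.
Volume and silhouette areas agree with brute-force column-integration and
pixel-counting oracles to better than 1 % and 0.5 %.

## Species presets

Ten parameter sets are bundled, calibrated against the published descriptor
ranges for dorsal girdle scales of two families (per-species printed values
are not tabulated anywhere, so the presets target the reported windows, not
copied numbers): imbrication from ~90 degrees (*I. australis*,
*L. mertensii*) to ~130 degrees (*I. lentiginosus*); inclination from ~60
degrees (*I. australis*) down to ~15 degrees (*C. cumingsii*), higher in
the Ischnochitonidae than the Chitonidae; basal fraction `h1/H` near 0.5
for *C. cumingsii* and *I. contractus* and 0.3–0.4 elsewhere; volumes from
~0.004 mm^3 (*L. mertensii*) to ~0.1 mm^3 (*R. polita*); and
`alpha + beta < 180` for every species.  *L. mertensii* uses a negative
posterior bulge to produce the doubly-curved flap.  Each preset records its
expected descriptor windows; `SpeciesPreset.check` re-validates a measured
record against them, guarding against calibration drift.

A separate **prototype** parameter set reproduces the printed mechanical-
test panels: base length 10 mm, wall spacing 0.5 mm (d/L = 5 %), embedded
height 4.1 mm.  Those dimensions imply the printed scale had `h1/L = 0.41`
— a taller, simplified shape than the biological scale — so the prototype
preset is an *R. canariensis*-class hook with `h1/H = 0.5` and a broad
crown, calibrated so the scaled inflection height is exactly 4.1 mm.

## Armor assembly

Scale bases tile a diamond mosaic: lattice generators proportional to
`(W/2, +-L/2)` scaled by `1 + d/(2 r_e)` where `r_e` is the diamond's
center-to-edge distance, which makes the plan-view wall gap between
diagonal neighbors exactly the spacing `d` (the fillets only round corners
away from the contact zone).  Neighbor classes in the lattice graph:
`diagonal` (4 nearest), `column` (along the hook direction) and `row`
(across the width).

*Gradient* panels place scales on the intersections of two line pencils
(origin, axis, angular divergence, line spacing); with zero divergence the
construction reduces exactly to the uniform lattice.  Size factors are the
square root of the local cell area normalized by the largest cell, so scale
size decreases away from the pencil origins, as on the girdle from the
proximal to the distal margin.

*Curved* panels carry the lattice through a parametric host (plane,
cylinder, spherical cap, or a generic mesh via vertical ray casting); each
scale's +Z follows the local normal, its hook follows the v-parameter
tangent, and the size factor is `min(1, kappa_c / kappa_max)` with
`kappa_c` defaulting to `0.5/L`.

The substrate is a slab of thickness `h1` with one socket per base, built
constructively: top and bottom caps are the footprint rectangle minus the
socket polygons (triangulated by ear clipping with hole bridging), socket
walls follow the basal shear, and the whole mesh is watertight.  Its volume
equals the slab minus the embedded base volumes exactly.  For curved hosts
the flat slab-with-sockets is wrapped through the host mapping along local
normals.  Export: binary STL by default, one file for the rigid scales and
one for the flexible substrate, mirroring two-material printing.

On the uniform *R. canariensis* panel, the plan-view union of the scales
covers >= 99 % of the interior lattice cells — the complete dorsal coverage
seen on the animal.

## Bending kinematics

The substrate midsurface (z = h1/2) is wrapped isometrically onto a
cylinder of signed curvature `kappa` whose axis is perpendicular to the
loading direction; the loading direction makes the orientation angle `phi`
with the hook axis, so `phi = 0` bends along the hooks and `phi = 90`
across them.  Scales are rigid (the printed scale/substrate modulus ratio
is ~1000x) and are carried by the rigid frame of their own site; positive
`kappa` is the concave mode (scales inward, tops converging), negative the
convex mode.  The uniform-curvature cylinder replaces the experiment's
pinned post-buckled arc: curvature is the clean control variable, and the
experiment's center region dominates its response anyway.  Forces,
friction, and substrate shear are out of scope; only contact topology and
onset are claimed.

Contacts are detected between the *exposed* scale parts (above the
substrate surface; the embedded bases are separated by the matrix): an
edge joins any pair whose minimum surface distance falls below the
tolerance (default `0.05 d`), with witness points and the lattice neighbor
class attached.  Distances are exact vertex-to-surface queries on
subdivided meshes (bounded edge length makes KD-tree centroid pruning
reliable); bounding-box prescreening keeps the pair loop cheap.

The onset `kappa*` is the lower edge of the contact regime that persists
up to the curvature-domain limit (a half-tube wrap), found by bisection to
1e-4 /mm.  Transient riding contacts — at `phi = 0` each hook touches the
back of the scale diagonally ahead, then slides over it as bending
proceeds — do not count as interlocking; they are the kinematic image of
the experiment's soft regime.  On the 7x7 prototype panel this yields:

* `phi = 90`: sustained interlocking from `kappa* ~ 0.057 /mm`, first
  contact on diagonal neighbors, and past onset every interior scale
  touches exactly its four diagonal neighbors;
* `phi = 60`: sustained contact from `kappa* ~ 0.017 /mm` on a single
  diagonal family (two contacts per interior scale);
* `phi = 0`: no sustained interlocking inside the curvature domain — the
  most flexible orientation.

**Known limitation.** The published experiments find stiffening onset
*earliest* at 90 degrees and later at 60.  That ordering is not
reproducible by first sustained geometric contact under uniform-curvature
rigid kinematics: the diagonal gap that binds at 90 degrees closes faster
at 60 degrees by the projection factor
`(offset . e_b)(wall_normal . e_b)`, whose 60/90 ratio is ~2.1 for any
diamond aspect.  Distinguishing a sliding contact from a jamming one
requires contact forces and friction, which are outside this model's
scope; the orientation ordering test documents this and is expected to
fail on the 90-vs-60 comparison.

## Numerical choices

* Units are mm everywhere; no unit inference.
* All operations are deterministic; the only random element is the
  parameter-jitter fixture generator, seeded explicitly.
* Default resolutions: scale meshes 64x64; assembly templates 20–24 per
  axis (contact geometry converges well below that); onset bisection
  tolerance 1e-4 /mm; contact tolerance `0.05 d`.
* Test problem sizes: species round-trips at 48x48, bending tests on 5x5
  panels, the interlocking topology check on the 7x7 panel — sizes at
  which every reported quantity is stable to well within its tolerance.
* Degenerate inputs: empty meshes, open meshes, zero-area polygons, and
  over-curvature requests raise typed errors (`ParameterError`,
  `GeometryError`) that the CLI maps to exit codes 2 and 3.

## What the synthetic geometry does and does not show

All validation runs on generated geometry: presets are calibrated to
published *ranges*, not to per-specimen tables, and the prototype's exact
printed parametrization is unpublished.  Passing tests therefore
demonstrate that the generative model, the measurement pipeline, and the
assembly/bending kinematics are mutually consistent and reproduce the
published descriptor windows, prototype dimensions, overlap capability,
basal center-of-mass property, coverage, and contact topologies.  They do
not certify agreement with any individual micro-CT specimen, nor any
force-displacement behavior (finite elements, friction, and puncture
mechanics are explicitly out of scope).
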