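# Methods

`hipimpinge` is a geometric (rigid-body) model of impingement after total hip
arthroplasty (THA).  It answers one question: for a given implant, anatomy,
and surgical cup orientation, at what point during an activity of daily living
does something collide — prosthetic neck on liner rim, or bone on bone — and
where on the liner rim does prosthetic contact occur?  Sweeping the cup
orientation over a surgical range turns single answers into maps: per-activity
impingement matrices, a component-impingement frequency map, and
impingement-free zones.

The model is purely kinematic.  It contains no forces, no contact stresses,
no soft-tissue restraint, no wear or creep, and no head subluxation: the
femoral head centre stays fixed relative to the pelvis (concentric mode) or is
offset by the bearing clearance (contact mode).  These are the standard
assumptions of rigid-body impingement models; their main consequence is that
predicted range of motion is an upper bound, and the severity of rim contact
cannot be graded.

## Frames and joint kinematics

Pelvic frame (right hip): +X anterior, +Y superior, +Z lateral, origin at the
hip centre of rotation (COR); the anterior pelvic plane is the X-Y plane.  In
neutral stance the femoral frame coincides with the pelvic frame and the
femoral shaft points along -Y.

Hip motion is a Cardan sequence applied intrinsically:

1. flexion(+)/extension(-) about the medio-lateral axis Z,
2. adduction(+)/abduction(-) about the rotated anterior axis X',
3. internal(+)/external(-) rotation about the femoral shaft axis Y''.

The sequence is a fixed convention of this package (gait analysis uses
several; results at ADL-scale angles are insensitive to the choice, but the
convention must be stated and is).  Angle read-back inverts the composed
matrix in closed form; the round trip is exact to machine precision, far
inside the 0.01 degree verification bound the package asserts.  At
|adduction| = 90 degrees the extraction is degenerate (gimbal lock) and raises
an explicit error rather than resolving silently; no activity in scope
approaches it.

Cup orientation uses the radiographic convention: anteversion is the angle
between the cup opening axis and the coronal plane (positive anterior),
inclination the angle between inferior (-Y) and the coronal projection of the
axis (opening swinging laterally).  The axis map is closed-form invertible;
left hips mirror the lateral axis.

## Implant geometry

Components are parametric solids meshed as watertight triangle surfaces:
spherical head (default 36 mm), conical neck (apex at the head centre, default
half-angle 11 degrees, a generic taper stand-in), spherical-shell liner and
shell (56 mm shell, 4 mm wall, 0.1 mm radial bearing clearance).  The liner's
bearing surface spans polar angles [rim_opening_half_angle, 180 degrees] from
the opening axis, so 90 degrees is exactly hemispherical; the rim is a sharp
circle by default, with an optional chamfer parameter because rim detail
shifts contact angles by a few degrees.  The neck-shaft angle (default 135
degrees) fixes the neutral neck axis in the coronal plane.

The same parameters yield closed-form descriptors used as an independent
oracle, chiefly the oscillation half-angle: a cone of half-angle d inside a
liner with rim half-angle r first touches the rim circle when the angle
between neck axis and cup opening axis reaches r - d (80 degrees for the
default-like 10/90 case).  Mesh-based first contact must agree within 0.5
degrees at default density and converge under refinement; this is the
package's central self-check, because the two routes share no code.

## Surrogate anatomy

Bone meshes can be loaded from STL/PLY (mm assumed; a scale factor handles
metre-based files).  The built-in surrogates are deliberately schematic
compositions of analytic solids, not statistical shape models:

* pelvis — a thick spherical wall around the acetabular cavity (56 mm cavity
  at the COR, 5 mm wall, opening along a typical native direction of 45/20
  degrees), with the bony margin receding 15 degrees from the full
  hemispherical rim (real acetabular margins are not full hemispheres; a full
  rim collides with the osseous neck at ~84 degrees of flexion, far earlier
  than anatomy allows), plus two spherical prominences: AIIS at (28, 46, -4)
  mm radius 8, and ischium at (-22, -40, -6) mm radius 10;
* femur — the osseous neck as a 26 mm collar around the prosthetic neck
  (axial span 22-40 mm from the COR; the natural head is resected), joined to
  a 28 mm shaft capsule whose axis sits at the neck-shaft junction, giving the
  proximal femur its real lateral offset (a straight through-COR shaft
  artificially strikes the AIIS in deep flexion).

With these defaults, everyday activity ranges clear both prominences; deep
external rotation (beyond about -80 degrees) drives the posterior neck into
the ischium, enlarged collars do so earlier, and flexion beyond ~95-100
degrees brings the anterior osseous neck against the superior-anterior
acetabular margin.  What the surrogates do not emulate: real cortical
geometry, osteophytes, cam/pincer morphology, inter-subject variation.
Bone-bone results therefore demonstrate mechanism, not patient-specific
prediction — which is also why the package's acceptance surface for bone
events is qualitative.

## Placement

Cup placement aligns the liner/shell axis with the radiographic opening axis
at the COR; a `medialise` option displaces the cup centre along the
medial-superior bisector (the direction is configurable; the phrase is
ambiguous and the 45-degree bisector is the symmetric reading), emulating
deepened reaming.  The default is zero because the surrogate cavity is already
defined at the restored joint centre.  Reaming itself is implied by
construction (cavity diameter equals shell diameter); no boolean subtraction
is performed on the pelvis.

The stem is posed by the same Cardan sequence with anteversion as the
shaft-axis rotation; the default 15/6/6 degrees represents a stem implanted to
conform with the native neck, and the surrogate femur's collar is aligned with
the prosthetic neck for the same reason.  Head modes: concentric (head centre
= cup centre = COR) or contact (head translated by the radial clearance minus
a 1 um residual gap — the paper-scale sensitivity analysis found the two
nearly indistinguishable, and so does this model).

## Activity kinematics

The synthetic generator emulates the seven dislocation-prone ADLs plus level
walking as coupled three-axis motions: each axis rises from neutral to its
peak as a raised cosine with a per-axis phase offset (0 / 0.10 / 0.15 of the
cycle), so all three axes move simultaneously — the methodological point of
activity-based models versus single-axis sweeps.  Peaks (flexion/adduction/
rotation, degrees):

| label | peaks | character |
|-------|-------------|-----------|
| SSL   | 100 / 8 / 12  | sit-to-stand, low seat |
| SSN   | 92 / 10 / 18  | sit-to-stand, normal chair |
| XLG   | 82 / 22 / 22  | seated leg cross |
| TIE   | 105 / 14 / 14 | seated shoe tying |
| STOOP | 106 / 8 / 10  | standing bend to floor |
| PIVOT | -10 / -8 / -60 | standing trunk rotation |
| ROLL  | -20 / -12 / -55 | supine roll |
| WALK  | 30 / 7 / 8    | gait-scale reference |

These are configurable approximations chosen from gait-laboratory
plausibility ranges, not recorded subject data; users with measured
trajectories load them from CSV (`time,flexion,adduction,rotation`).  The
trajectories are monotone ramps to peak, which matches how first-contact
search consumes them; cyclic return phases would add nothing, since the first
super-threshold configuration occurs on the way in.  Default sampling is 49
points over the cycle; results are insensitive to sampling because contact is
refined by bisection (see below).

## Interference detection

Interference between two posed watertight solids is the volume of their
boolean intersection.  No mesh-boolean engine is used; the package integrates
the intersection directly from per-mesh signed-distance fields (SDFs):

1. each mesh gets, once, a regular SDF grid in its local frame (spacing =
   mesh density / 3, clamped to [0.15, 0.5] mm for implants, 0.7 mm for
   bones): voxel centres are classified inside/outside by scanline ray parity
   per connected component (so multi-part bones union correctly), a Euclidean
   distance transform supplies the far field, and voxels within two cells of
   the surface are replaced by exact point-to-triangle distances — the field
   is exact to the mesh where contact happens;
2. the overlap region of a posed pair is sampled hierarchically in the first
   solid's local frame: a coarse grid is culled using the 1-Lipschitz property
   of distance fields, surviving cells are refined 4x, and each fine sample
   contributes a first-order partial-volume weight clip(0.5 - s/h) where
   s = max(sdf_a, sdf_b);
3. positive-centre boundary cells are kept only if some cell corner is
   genuinely inside both solids — without this check the linear cut model
   fabricates volume inside thin conformal clearance gaps (head-in-liner,
   0.1 mm) where the max-field dips but never crosses zero.

Poses enter only through the relative transform between the two local frames,
so detection is exactly invariant under rigid motion of the whole scene.
Accuracy on closed forms: sphere-sphere lens volumes agree within ~1-3% down
to the 1 mm^3 level; contact angles agree with the oscillation-angle oracle
within ~0.1 degrees at default density.

Classification: component impingement is any femoral implant mesh against any
acetabular implant mesh above the volume threshold (default 1 mm^3,
configurable down to mesh resolution); bone impingement is femur against
pelvis.  The articulating head-liner couple is excluded by default: with the
head retained, its interference is identically zero and checking it costs the
most of any pair.  Component-bone contact is not a category of this model's
scenes (implant vs opposite-side bone pairs are not checked); the event
taxonomy still carries `component_and_bone` for events where both categories
first appear within one bisection bracket.

## First impingement and rim localisation

A trajectory is scanned in time order at its samples; the first detecting
sample is bracketed against its predecessor and bisected — each joint axis
interpolated linearly in time — until the largest-moving axis changes by at
most the tolerance (default 0.1 degrees) across the bracket.  The event is
evaluated at the detecting end of the final bracket, i.e. the first known
super-threshold configuration; this makes results reproducible and
insensitive to trajectory sampling.  Detection already present at the first
sample is reported as trajectory fraction 0 with an explicit warning.

For component events the contact patch is the weighted set of intersection
samples between femoral and acetabular implant meshes; its centroid is
projected into the rim plane and reported as an azimuth measured clockwise
from the projection of pelvic superior, viewed from lateral (right hip):
superior 0, anterior 90, inferior 180, posterior 270 degrees.  Reported
matrices bucket the azimuth to 5 degrees; events keep the exact value.  When
the cup axis is parallel to superior (inclination 0 with zero anteversion) the
azimuth origin is undefined; the scale is then anchored at anterior = 90.

The 1 mm^3 threshold means the detected configuration lies slightly beyond
tangency (the intersection must grow to threshold); for the default geometry
this is a few tenths of a degree.  Oracle-equivalence tests therefore lower
the threshold to 0.02 mm^3, which the threshold's configurability exists for.

## Sweep, frequency map, safe zone

`run_sweep` evaluates every (cup-orientation cell, activity) pair over a grid
(default inclination 30-70, anteversion 0-50, 5-degree steps; 99 cells),
re-placing only the acetabular components per cell so all meshes and SDFs are
shared.  Cells are independent and the pipeline has no stochastic step:
results are deterministic and order-free, and identical configurations
produce byte-identical CSVs.

The frequency map counts, per cell, activities whose event is component
impingement (component-and-bone counts as component; bone-only does not).
`safe_zone` thresholds that count and also reports the intersection with the
Lewinnek window (inclination 30-50, anteversion 5-25).  With the default
battery and geometry the maps reproduce the directional structure expected of
THA impingement: flexion-dominant activities impinge antero-superiorly
(azimuths ~45-80 degrees) at low anteversion, with incidence falling as
anteversion and inclination rise; extension/external-rotation activities
impinge postero-inferiorly (~230-240 degrees) at high anteversion with the
opposite trend; walking never impinges; and the component-impingement-free
band runs from roughly (inclination 30, anteversion 35-40) to (inclination
70, anteversion 10-15) — as inclination increases, less anteversion is needed
to stay free.

## Numerical choices and problem sizes

* Mesh density 1.5 mm target edge (implants): ~5k-13k triangles per
  component; SDF spacing 0.5 mm with an exact near band.  Halving density
  moves oracle contact angles by under 0.2 degrees.
* Volume threshold 1 mm^3; bisection tolerance 0.1 degrees; trajectory
  sampling 49 points.
* The full default battery (8 activities x 99 cells) runs in a few minutes on
  one core; single events take well under a second after the one-off SDF
  builds (~15 s per scene's mesh set).
* Ties: if component and bone interference both first exceed threshold within
  the final bisection bracket, the event is `component_and_bone`.
* Degenerate inputs are rejected with the violated constraint named
  (non-finite angles, non-watertight meshes in strict contexts, bumps
  intersecting the cavity, unsorted grids, and so on); non-watertight loaded
  meshes are accepted with a warning and give lower-bound volumes.

## Known limitations

* Single fixed Cardan convention; no pelvic-tilt re-referencing of cup
  angles, no anatomic/operative anteversion conventions.
* Rigid bodies only: no stress, deformation, subluxation, or soft tissue.
* The surrogate anatomy is schematic; bone-bone predictions show mechanism,
  not patient anatomy.  Exact reproduction of any specific CT-derived
  anatomy's matrices is out of scope.
* The synthetic activity peaks are representative, not measured; quantitative
  cell-by-cell maps will differ for measured kinematics, which is why
  acceptance properties are directional/structural rather than cell-exact.
* Interference volumes inherit SDF accuracy (~0.01 mm near surfaces);
  designed clearances below that (the 1 um contact-mode gap) can register
  spurious volumes of order 0.1 mm^3, well under the detection threshold.
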