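# Methods

`pedispine` generates solid-state (watertight, closed triangulated) models of
pediatric lumbar vertebrae, intervertebral discs and assembled lumbar spines
for five age groups — newborn, infant (0–1 y), toddler (1–3 y), middle
childhood (3–7 y) and preadolescent (8–12 y) — from a packaged table of mean
osteometric dimensions (5 groups × 5 levels × 7 body measurements, mm) and a
five-tissue linear-elastic material registry. This note records the model,
its parameters, the numerical machinery and the design choices made where
the published construction leaves freedom.

## Coordinate and unit conventions

Millimetres throughout; right-handed frames with +z cranial, +y anterior,
+x anatomical left. Each vertebra is built in a frame whose origin lies on
the vertical axis of the vertebral foramen at the plane of the body's
inferior surface, then shifted so the origin coincides with the inferior
body-surface centroid of the *group's L3 reference body*. Using one shift
per age group (rather than per level) keeps all levels of a group exactly
coaxial at the facet joints; the per-level inferior centroid deviates from
the origin by well under 1 mm.

## Vertebral body

The body is a loft generated from the printed dimensions alone:

* **Frontal width profile** `w(z)`: cosine blend IVBW → MVBW → SVBW over the
  posterior height, with zero slope at both faces and at mid-height. When
  MVBW is smaller than both endplate widths the profile automatically
  produces the "waist" of the older groups; the blend also makes the
  mid-height width exactly MVBW, so slicing at 50% of the posterior height
  recovers the printed value.
* **Sagittal depth profile** `d(z)`: cosine blend IVBL → SVBL.
* **Silhouette**: a closed outline composed of an anterior elliptical arc,
  posterolateral quadratic-bezier flanks and a posterior concave recess that
  follows the vertebral-foramen boundary (see below). Per-group shape
  parameters move the widest station and flatten the flanks, producing the
  oval newborn body and the disc-/cylinder-sector bodies of older groups.
* **Endplate inclination**: the superior surface ramps linearly in y between
  the posterior height (PVBH) at the posterior extreme and the anterior
  height (AVBH) at the anterior extreme; the inferior surface is flat.
* **Endplate reliefs**: central fossae are spherical-cap depressions (depth
  0.05 × PVBH, radius 0.55 of the inscribed endplate radius — not printed,
  configurable). Groups 3–5 carry rim notches (12 scallops, 0.3 mm deep,
  in bands hugging both rims). The preadolescent ring-apophysis "step" is a
  recessed band just below/above the endplate rims (inset 0.08 × PVBH over a
  0.10 × PVBH band). The step is realised *below* the rim rather than as a
  rebate *of* the rim because the packaged dimensions are overall extents:
  cutting the rim margin itself would make the generated solids contradict
  the very table they are built from. All rim modulations fade out at the
  four cardinal columns (anterior apex, lateral extremes) so the printed
  extents are preserved exactly.

Both the exact loft mesh and an implicit signed field are generated from the
same scale functions, so the body can enter boolean operations at any point.

## Arch parameters and the vertebral foramen

The construction consumes pedicle, process and foramen measurements that the
dimension table does not print. They default to fixed fractions of printed
dimensions (all overridable):

| parameter | default | of |
|---|---|---|
| pedicle height | 0.55 | PVBH |
| pedicle width | 0.20 | MVBW |
| arch plate thickness | 0.12 | MVBW |
| transverse process length | 0.45 | MVBW |
| spinous process length | 0.50 | SVBL |
| articular process length | 0.35 | PVBH |
| foramen frontal diameter | 0.60 | MVBW |
| foramen sagittal diameter | 0.80 | IVBL |
| fillet radius | 0.10 | min(pedicle width, plate thickness) |

These fractions are stand-ins for untabulated arch osteometry; they preserve
cross-age scaling and keep the build reproducible from packaged data alone.

The foramen boundary is a radial function ρ(φ) around the canal axis that
blends an ellipse (on the frontal/sagittal diameters) with a rounded
posterior-apex triangle; the blend weight grows with age (0, 0.15, 0.25,
0.45, 0.50 for groups 1–5), giving the circular newborn foramen and the
near-triangular middle-childhood foramen. The arch is an extruded annular
ring on that boundary (radial thickness = plate thickness, bulged to the
pedicle width near the body), and the body's posterior recess follows the
same boundary, so ring + recess frame the canal without any boolean cut.

## Posterior elements and the facet joints

Transverse processes and the spinous process are truncated-pyramid
parallelepipeds; the transverse-process root is anchored just lateral of the
foramen's widest extent so the canal is never encroached. The spinous
process is absent in the newborn model, rudimentary in groups 2–3, slants
15° downward in group 4 ("subtly downward-slanting"; no angle is printed)
and is strictly horizontal in group 5. A shallow notch is cut on the arch's
posterior inferior edge as the spinous-process foundation.

The facet joints are modelled as vertical pins (inferior articular
processes, radius 0.30 × pedicle width) descending into U-channel cutouts of
the superior articular processes below. Both sit at a posterolateral angular
station (100° from the anterior foramen axis, where lumbar facets lie); the
process footprints are rectangles aligned with the arch ring (radial ×
tangential), so they hug the ring band and never reach over the vertebral
canal or the body. The cutout diameter is **solved, not defaulted**:
bisection on the *measured* minimum surface distance between a pin stacked
at the group's reference segment height and the notch below, targeting a
0.40 mm articular gap (tolerance 0.02 mm), inside the 0.5 mm joint-gap
bound. Facet stations and radii are derived once per age group from its L3
record so that adjacent levels articulate coaxially; under the default
lordosis the assembled gaps stay positive and within the bound.

## Age-group component architecture

* Group 1 — six components: body, two semi-arch bones (each the fused union
  of its half-ring, transverse process, pin and notched process), plus two
  pedicle synchondroses and one posterior midline synchondrosis, built as
  annular-sector cartilage layers (thickness 0.15 × pedicle width) that fill
  the gaps between bones exactly, leaving a 0.02 mm assembly clearance so
  components touch (< 0.05 mm) without boolean overlap.
* Groups 2–3 — four components: body, one fused arch, two pedicle
  synchondroses. A config flag restores the midline synchondrosis at L5 of
  group 2 (the stated ossification exception); it is off by default so the
  four-component architecture holds at every level.
* Groups 4–5 — one fused bone: union of body and all posterior elements,
  then edge smoothing.

## Intervertebral discs

The disc envelope reuses the body-outline machinery (including the posterior
recess, so the canal stays open) at the footprint given by the mean of the
lower vertebra's superior width/length and the upper vertebra's inferior
width/length (L5/S1 uses the L5 inferior dimensions; the sacrum is not
tabulated). Two clearance bites are subtracted around the facet stations
where the articular pins and processes cross the disc space.

The sagittal wedge is 7° by default, opening anteriorly (the direction is
not stated; anterior-taller is the lordosis-consistent choice). Disc height
is `ratio × mean(adjacent PVBH)` with ratios 1.0, 0.8, 0.6, 0.4, 0.3 for
groups 1–5 — the newborn value is the stated body-matching height, the later
ratios are package defaults realising the qualitative "shorter" →
"relatively small" gradient. The height is attached to the tall (anterior)
edge, which is both the printed example value and the disc's stacking
contribution in a straight spine.

The internal cavity is an inset copy of the envelope (one volume spanning
the anterior chamber and posterior recess); its wall scale is solved by
bisection until the cavity holds 50% ± 0.5% of the envelope volume. The
nucleus pulposus is built separately as the cavity offset inward by a
uniform 0.05 mm clearance and inserted; annulus (envelope minus cavity,
realised as an exact two-shell mesh) and nucleus are therefore disjoint by
construction.

## Spine assembly

Eleven elements (L1…L5, five discs, S1 superior endplate — a flat plate of
thickness 0.30 × L5 PVBH on the L5/S1 footprint, labeled cortical bone) are
stacked caudally to cranially. Total lordosis defaults to 0°, 0°, 15°, 25°,
30° for groups 1–5 (absence is stated for the first two groups, visibility
from the toddler group on; the magnitudes are package defaults), distributed
equally over the five segments as rotations about the frontal axis at the
disc planes, half to the disc and half to the vertebra above.

Because wedged endplates and wedged discs are not congruent, each element is
seated by a surface-contact solve: its bearing surface is rasterised against
the element below on a 0.3 mm grid in the local frame and slid along the
stacking axis until the clearance equals 0.03 mm. With endplate slopes under
10° the rasterisation error is well below the clearance, so elements are in
contact (< 0.1 mm) and never interpenetrate. Articular pins are excluded
from the contact solve (they engage the facet channels); interpenetration is
verified afterwards on the signed fields.

## Solid kernel numerics

* **Booleans** are implicit CSG: every primitive carries an exact signed
  field (sign-exact everywhere, Euclidean near the surface); min/max
  composition; triangulation by marching cubes on a grid of pitch
  MVBW/96 (clamped to 0.12–0.45 mm), offset by an irrational fraction of the
  pitch so flat faces never coincide with grid planes. Meshing is lazy: a
  chain of booleans samples the composed field once.
* **Fillet** (step-11 smoothing) is Humphrey filtering (α = 0.02, β = 0.5)
  after edge-length-bounded subdivision — shrink-resistant and nearly
  idempotent — with a volume-drift guard at 15%. A filleted solid keeps its
  pre-smoothing field as a conservative outer bound for diagnostics, but
  must not re-enter booleans.
* **Minimum distance** is exact point-to-triangle distance from a
  deterministic dense surface refinement of each operand to the other's
  triangles, KD-tree pruned; the sampling-side error is bounded by
  (edge length)²/(8 × curvature radius), far below 0.02 mm at these scales.
* **Volumes** are divergence-theorem signed sums over the triangulation;
  a Monte-Carlo inside-test oracle cross-checks them in the test suite.
* Discretisation defaults: 64 facets per revolution, 48 loft rings, 130
  outline columns. At these settings the marching-cubes volume error of a
  boolean result is ≈ 0.1% at vertebra scale; the body loft is exact at its
  vertices, so the table round-trip errors are at the 0.01 mm level.

## Measurement protocol (validation)

Measurements invert the construction without reading construction internals
back from the solids: endplate faces are detected by face normal (within 35°
of vertical); widths are frontal extents of those faces (IVBW/SVBW) or of
the mid-height section (MVBW, sliced at 50% of posterior height); lengths
are sagittal extents of the endplate faces in the mid-sagittal strip;
heights are vertical extents of the strip in the anterior half (AVBH) and at
the posterior recess wall (PVBH). Tolerance is max(0.2 mm, 2%) per entry.
For the fused groups the emitted component is a single solid, so these
measurements run on the model's recorded pre-fusion body. Foramen shape is
assessed by circularity 4πA/P² of the canal cross-section sliced through the
arch, after a 0.05 mm morphological closing that seals the synchondrosis
clearances.

`full_validation(group)` builds all five vertebrae, five discs and the
spine of a group and concatenates every report (dimension round-trips,
component counts, watertightness, wedge/cavity/containment, spine
composition, contact gaps, interpenetration, facet gaps).

## What the generator does and does not emulate

The models are idealised parametric solids built from mean dimensions of a
57-specimen osteometric series: they reproduce mean sizes, age-dependent
component architecture, foramen shape trends, process development, disc
proportions and lordosis onset. They do not reproduce individual anatomy,
cortical/trabecular internal structure, real endplate curvature, facet
orientation angles, or ligamentous/muscular soft tissue; passing validation
means the construction is internally consistent with its own dimension
table, not that the solids match any particular specimen. They are suitable
for education, comparative biomechanics and FEA preprocessing — not for
patient-specific surgical planning.

## Known limitations

* Mesh booleans (not exact CAD B-reps): sub-0.1 mm surface detail of fused
  unions is grid-limited, and repeated boolean chains accumulate ~0.1%
  volume error per meshing.
* The arch/process fraction table is a reasoned stand-in for untabulated
  source osteometry; absolute posterior-element dimensions are therefore
  package conventions, though they scale correctly with age.
* Step-4 "inclines" are realised on the body endplates only; the arch
  pedicles keep square posterior edges until the smoothing step.
* The contact solve seats elements with a small uniform clearance instead of
  congruent-surface mating; interface micro-gaps of up to ~0.1 mm remain by
  design so that no element pair interpenetrates.
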