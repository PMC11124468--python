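# pedispine

Parametric solid-state 3D models of **pediatric lumbar vertebrae,
intervertebral discs and assembled lumbar spines**, for five age groups from
newborn to preadolescent.

Pediatric spines are structurally different from adult ones — vertebrae
begin as separate ossification centres joined by cartilaginous
synchondroses, the vertebral foramen changes from circular to triangular,
processes develop gradually, disc heights shrink relative to the bodies, and
lumbar lordosis only appears with upright posture. `pedispine` encodes these
changes as a fully parametric construction driven by a packaged table of
mean osteometric dimensions (5 age groups × levels L1–L5 × 7 measurements:
AVBH/PVBH anterior/posterior body heights, SVBL/IVBL superior/inferior
sagittal lengths, SVBW/MVBW/IVBW superior/middle/inferior frontal widths,
all in mm). Every generated solid is a watertight triangulated boundary
labeled with a tissue and its linear-elastic properties (Young's modulus
*E*, Poisson ratio *ν*), ready for export to FEA pipelines, 3D printing or
VR/AR teaching material.

The construction, in brief: the vertebral body is a loft whose frontal
radius follows a cosine blend IVBW → MVBW → SVBW (giving the preadolescent
"waist" when MVBW is smallest) stretched sagittally by IVBL → SVBL, with
endplates inclined between PVBH and AVBH and relieved by central fossae; the
posterior arch is an annular ring on the foramen boundary ρ(φ) — an
ellipse-to-triangle blend that ages the canal shape — carrying
truncated-pyramid transverse and spinous processes and facet joints whose
cutout diameter is *solved* so the articular gap stays within 0.5 mm. Age
groups differ in component architecture: 6 components in the newborn
(3 bone + 3 cartilage), 4 in infants/toddlers, a single fused bone from
middle childhood. Discs are 7°-wedged annuli whose internal cavity is solved
to hold 50% of the disc volume, with a separately built nucleus pulposus
inserted at 0.05 mm clearance. Spines stack 5 vertebrae, 5 discs and the S1
superior endplate along an equally distributed lordosis arc (0° before
upright posture, up to 30° in preadolescents).

Users who need different conventions (arch fractions, disc ratios, lordosis,
resolutions) can override every default through a JSON config with the
schema of `pedispine.config.BuildConfig`.

## Worked example

```python
from pedispine import build_vertebra, build_disc, measure_vertebra, check_disc

vert = build_vertebra(1, "L3")           # newborn L3
print([c.anatomical_name for c in vert.components])
rep = measure_vertebra(vert)
for name in ("MVBW", "AVBH", "SVBW"):
    e = rep[name]
    print(f"{name}: measured {e.measured:.2f} mm (table {e.expected} mm) pass={e.passed}")

disc = build_disc(1, "L3/4")
drep = check_disc(disc)
print(f"disc height: {disc.height_anterior:.2f} mm")
print(f"wedge angle: {drep['wedge angle'].measured:.2f} deg")
print(f"cavity fraction: {drep['cavity volume fraction'].measured:.3f}")
```

prints

```
['body', 'right semi-arch', 'left semi-arch', 'right pedicle cartilage', 'left pedicle cartilage', 'midline cartilage']
MVBW: measured 15.20 mm (table 15.2 mm) pass=True
AVBH: measured 7.20 mm (table 7.2 mm) pass=True
SVBW: measured 14.60 mm (table 14.6 mm) pass=True
disc height: 7.25 mm
wedge angle: 7.00 deg
cavity fraction: 0.496
```

The six components are the newborn architecture (body and two semi-arches in
bone, joined by two pedicle synchondroses and the posterior midline
synchondrosis); the re-measured body dimensions reproduce the packaged table
to within max(0.2 mm, 2%); the disc shows the 7° sagittal wedge, the
body-matching newborn disc height (mean adjacent PVBH = 7.25 mm) and the
~50% nucleus cavity.

## Command line

```sh
pedispine dims --group 1 --level L3          # print a table record
pedispine materials                          # tissue registry (E, nu)
pedispine build-vertebra --group 4 --level L2 --out out/v42 --format stl
pedispine build-spine --group 5 --out out/spine5
pedispine validate --group 1 --json report.json
```

Exports write one mesh file per component (binary/ASCII STL, OBJ or PLY)
plus `manifest.json` carrying each component's tissue, *E* (MPa) and *ν* —
the bundle a finite-element preprocessor needs.

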