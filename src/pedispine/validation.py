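"""Morphometric validation: re-measure generated solids against the packaged
dimension table and the geometric construction constraints.

The measurement protocol inverts the construction:

* frontal widths are the frontal extents of the inferior/superior endplate
  faces (IVBW/SVBW) and of the mid-height cross-section (MVBW, sliced at 50%
  of the posterior body height);
* sagittal lengths are the sagittal extents of the endplate faces inside the
  mid-sagittal strip (IVBL/SVBL);
* body heights are the vertical extents of the mid-sagittal strip in the
  anterior half (AVBH) and at the posterior recess wall (PVBH).

For the fused age groups (4-5) the emitted component is a single solid, so
the body measurements are taken on the model's recorded body solid.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .config import BuildConfig, default_config
from .osteometry import VertebralLevel, get_age_group, get_dimensions
from . import solid_kernel as sk
from .solid_kernel import MinDistanceResult, TriSurfaceSolid
from .vertebra import VertebraModel, build_vertebra
from .disc import DiscModel, build_disc, DISC_PAIRS
from .spine import SpineModel, assemble_spine, spine_report

__all__ = [
    "MeasurementEntry",
    "MeasurementReport",
    "measure_body_dimensions",
    "measure_vertebra",
    "measure_foramen",
    "check_facet_gap",
    "check_disc",
    "full_validation",
]

#: expected component counts per age group (default architecture)
EXPECTED_COMPONENTS = {1: 6, 2: 4, 3: 4, 4: 1, 5: 1}


@dataclass
class MeasurementEntry:
    name: str
    measured: float
    unit: str = "mm"
    expected: Optional[float] = None
    tolerance: Optional[float] = None

    @property
    def passed(self) -> bool:
        if self.expected is None:
            return True
        return abs(self.measured - self.expected) <= (self.tolerance or 0.0)


@dataclass
class MeasurementReport:
    title: str
    entries: List[MeasurementEntry] = field(default_factory=list)

    def add(self, name, measured, unit="mm", expected=None, tolerance=None):
        self.entries.append(MeasurementEntry(name, float(measured), unit, expected, tolerance))

    def extend(self, other: "MeasurementReport") -> None:
        for e in other.entries:
            self.entries.append(
                MeasurementEntry(f"{other.title}: {e.name}", e.measured, e.unit, e.expected, e.tolerance)
            )

    @property
    def overall_pass(self) -> bool:
        return all(e.passed for e in self.entries)

    def failed(self) -> List[MeasurementEntry]:
        return [e for e in self.entries if not e.passed]

    def __getitem__(self, name: str) -> MeasurementEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "title": self.title,
            "overall_pass": self.overall_pass,
            "entries": [
                {
                    "name": e.name,
                    "measured": e.measured,
                    "unit": e.unit,
                    "expected": e.expected,
                    "tolerance": e.tolerance,
                    "pass": e.passed,
                }
                for e in self.entries
            ],
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_text(self) -> str:
        lines = [f"== {self.title} ({'PASS' if self.overall_pass else 'FAIL'}) =="]
        for e in self.entries:
            exp = "" if e.expected is None else f" expected {e.expected:g} +/- {e.tolerance:g}"
            flag = "" if e.passed else "  <-- FAIL"
            lines.append(f"  {e.name}: {e.measured:.3f} {e.unit}{exp}{flag}")
        return "\n".join(lines)


def _tol(value: float) -> float:
    return max(0.2, 0.02 * value)


def measure_body_dimensions(body: TriSurfaceSolid, pvbh_station: float) -> dict:
    """Measure the seven body dimensions on a body solid.

    ``pvbh_station`` sets the slicing stations (50% of the posterior height
    for MVBW); all other measurements are station-free.
    """
    m = body.mesh
    v = m.vertices
    fn = m.face_normals
    fc = m.triangles_center
    zmax = v[:, 2].max()
    cos35 = math.cos(math.radians(35))
    top = (fn[:, 2] > cos35) & (fc[:, 2] > 0.5 * zmax)
    bot = (fn[:, 2] < -cos35) & (fc[:, 2] < 0.5 * zmax)
    tv = m.triangles[top].reshape(-1, 3)
    bv = m.triangles[bot].reshape(-1, 3)
    out = {}
    out["SVBW"] = tv[:, 0].max() - tv[:, 0].min()
    out["IVBW"] = bv[:, 0].max() - bv[:, 0].min()
    ts = tv[np.abs(tv[:, 0] - np.median(v[:, 0])) < 1.0]
    bs = bv[np.abs(bv[:, 0] - np.median(v[:, 0])) < 1.0]
    out["SVBL"] = ts[:, 1].max() - ts[:, 1].min()
    out["IVBL"] = bs[:, 1].max() - bs[:, 1].min()
    sec = m.section(plane_origin=(0, 0, pvbh_station / 2.0), plane_normal=(0, 0, 1))
    pts = np.vstack([np.asarray(d) for d in sec.discrete])
    out["MVBW"] = pts[:, 0].max() - pts[:, 0].min()
    strip = v[np.abs(v[:, 0] - np.median(v[:, 0])) < 0.4]
    ymid = 0.5 * (strip[:, 1].min() + strip[:, 1].max())
    ant = strip[strip[:, 1] >= ymid]
    out["AVBH"] = ant[:, 2].max() - ant[:, 2].min()
    post = strip[strip[:, 1] <= strip[:, 1].min() + 0.8]
    out["PVBH"] = post[:, 2].max() - post[:, 2].min()
    return {k: float(val) for k, val in out.items()}


def measure_vertebra(model: VertebraModel) -> MeasurementReport:
    """Re-measure one vertebra model against its packaged dimension record."""
    rep = MeasurementReport(f"vertebra group {model.group.index} {model.level.value}")
    dims = model.dims
    measured = measure_body_dimensions(model.body_solid, dims.PVBH)
    for name, value in measured.items():
        expected = getattr(dims, name)
        rep.add(name, value, "mm", expected, _tol(expected))
    expected_n = EXPECTED_COMPONENTS[model.group.index]
    rep.add("component count", len(model.components), "", expected_n, 0)
    for comp in model.components:
        rep.add(f"{comp.anatomical_name} watertight", float(comp.solid.is_watertight), "", 1.0, 0)
        rep.add(f"{comp.anatomical_name} volume", comp.solid.volume, "mm^3")
    return rep


def measure_foramen(model: VertebraModel) -> MeasurementEntry:
    """Circularity (4 pi A / P^2) of the vertebral foramen cross-section,
    sliced through the arch at 45% of the posterior body height."""
    from shapely.geometry import Polygon

    z = 0.45 * model.dims.PVBH
    region = sk.section_polygons(model.solids(), z)
    region = region.buffer(0.05).buffer(-0.05)  # seal synchondrosis micro-gaps
    polys = [region] if region.geom_type == "Polygon" else list(region.geoms)
    rings = [i for p in polys for i in p.interiors]
    if not rings:
        return MeasurementEntry("foramen circularity", 0.0, "")
    hole = max((Polygon(r) for r in rings), key=lambda p: p.area).simplify(0.05)
    circ = 4.0 * math.pi * hole.area / hole.exterior.length ** 2
    return MeasurementEntry("foramen circularity", circ, "")


def check_facet_gap(
    upper: VertebraModel,
    lower: VertebraModel,
    pose: np.ndarray,
) -> MinDistanceResult:
    """Minimum distance between the inferior articular surfaces of ``upper``
    (placed at ``pose`` relative to ``lower``) and the superior articular
    surfaces of ``lower``; overlapping surfaces report 0 with the flag set."""
    best = MinDistanceResult(np.inf, False)
    for pin in upper.facet_inferior:
        moved = pin.transformed(pose)
        for notch in lower.facet_superior:
            r = sk.min_distance(moved, notch)
            if r.overlapping:
                return r
            if r.distance < best.distance:
                best = r
    return best


def check_disc(model: DiscModel, config: Optional[BuildConfig] = None) -> MeasurementReport:
    """Wedge angle (plane-fit dihedral), cavity volume fraction, nucleus
    containment and planarity of the disc's bearing faces."""
    config = config or default_config()
    rep = MeasurementReport(f"disc group {model.group.index} {model.pair}")
    ann = model.annulus.solid
    outer = max(ann.mesh.split(only_watertight=True), key=lambda p: p.volume)
    fn, fa = outer.face_normals, outer.area_faces
    cos30 = math.cos(math.radians(30))
    for label, mask in (("superior", fn[:, 2] > cos30), ("inferior", fn[:, 2] < -cos30)):
        if not mask.any():
            rep.add(f"{label} face found", 0.0, "", 1.0, 0)
            return rep
    ntop = (fn[fn[:, 2] > cos30] * fa[fn[:, 2] > cos30, None]).sum(axis=0)
    nbot = (fn[fn[:, 2] < -cos30] * fa[fn[:, 2] < -cos30, None]).sum(axis=0)
    ntop /= np.linalg.norm(ntop)
    nbot /= np.linalg.norm(nbot)
    angle = math.degrees(math.acos(np.clip(np.dot(ntop, -nbot), -1, 1)))
    rep.add("wedge angle", angle, "deg", model.wedge_angle, 0.5)

    # planarity: worst residual of the top face vertices against its plane
    topverts = outer.triangles[fn[:, 2] > cos30].reshape(-1, 3)
    d = topverts @ ntop
    rep.add("superior face planarity", float(d.max() - d.min()), "mm", 0.0, 0.05)

    frac = 1.0 - ann.volume / model.envelope.volume
    rep.add("cavity volume fraction", frac, "", config.disc.cavity_fraction, 0.05)

    # nucleus containment: fraction of nucleus sample points outside the cavity
    nuc = model.nucleus.solid
    lo, hi = nuc.bounds
    pitch = max(float(min(hi - lo)) / 8.0, 0.25)
    axes = [np.arange(lo[k] + pitch / 2, hi[k], pitch) for k in range(3)]
    g = np.meshgrid(*axes, indexing="ij")
    pts = np.column_stack([x.ravel() for x in g])
    in_nuc = nuc.sdf(pts) < 0
    if in_nuc.any():
        p = pts[in_nuc]
        in_cavity = (model.envelope.sdf(p) < 0) & (ann.sdf(p) > 0)
        escape = 1.0 - in_cavity.mean()
    else:  # pragma: no cover - nucleus always has interior samples
        escape = 1.0
    rep.add("nucleus outside cavity (fraction)", escape, "", 0.0, 0.001)
    for comp in (model.annulus, model.nucleus):
        rep.add(f"{comp.anatomical_name} watertight", float(comp.solid.is_watertight), "", 1.0, 0)
    return rep


def full_validation(group: "int", config: Optional[BuildConfig] = None) -> MeasurementReport:
    """Build and validate all five vertebrae, five discs and the assembled
    spine of one age group; concatenates every report."""
    config = config or default_config()
    grp = get_age_group(group)
    rep = MeasurementReport(f"group {grp.index} ({grp.label})")
    for level in VertebralLevel:
        model = build_vertebra(grp, level, config)
        rep.extend(measure_vertebra(model))
    for pair in DISC_PAIRS:
        rep.extend(check_disc(build_disc(grp, pair, config), config))
    spine = assemble_spine(grp, config)
    sr = spine_report(spine)
    rep.add("spine vertebra count", len(spine.vertebrae()), "", 5, 0)
    rep.add("spine disc count", len(spine.discs()), "", 5, 0)
    rep.add("spine endplate count", sum(e.kind == "endplate" for e in spine.elements), "", 1, 0)
    for gap in sr["contact_gaps"]:
        rep.add(f"contact gap {gap['interface']}", gap["gap"], "mm", 0.05, 0.05)
    for pen in sr["interpenetration"]:
        rep.add(f"interpenetration {pen['interface']}", pen["fraction"], "", 0.0, 0.001)
    ordered = spine.elements[::-1]
    verts = [e for e in ordered if e.kind == "vertebra"]
    for lower_el, upper_el in zip(verts[:-1], verts[1:]):
        pose = np.linalg.inv(lower_el.pose) @ upper_el.pose
        gap = check_facet_gap(upper_el.payload, lower_el.payload, pose)
        rep.add(
            f"facet gap {lower_el.name}-{upper_el.name}", gap.distance, "mm", 0.25, 0.25
        )
    return rep
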