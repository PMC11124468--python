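"""Intervertebral disc construction.

A disc is built in three steps mirroring the vertebral workflow: a wedge-
shaped outer envelope is generated by the same rotational/loft machinery as
the vertebral body (7 degree sagittal wedge by default, opening anteriorly,
consistent with lumbar lordosis), an internal cavity for the nucleus
pulposus is carved so that it holds the configured fraction of the disc
volume (50% by default, solved by bisection on the cavity wall scale), and
the nucleus pulposus is created separately and inserted into the cavity with
a small uniform clearance.

The disc footprint is derived from the endplates it sits between: the mean
of the lower vertebra's superior width/length and the upper vertebra's
inferior width/length.  Its height follows the age group's disc-to-body
height ratio (newborn discs match the bodies; the ratio falls with age).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import trimesh

from .config import BuildConfig, default_config
from .osteometry import (
    AgeGroup,
    VertebralLevel,
    get_age_group,
    get_dimensions,
    get_material,
)
from . import solid_kernel as sk
from .solid_kernel import GeometryError, TriSurfaceSolid
from .vertebra import BodyGeometry, LabeledComponent, _arch_for, group_origin_shift

__all__ = ["DiscModel", "DISC_PAIRS", "parse_pair", "disc_height", "build_disc", "wedge_prism"]

DISC_PAIRS = ("L1/2", "L2/3", "L3/4", "L4/5", "L5/S1")


@dataclass
class DiscModel:
    group: AgeGroup
    pair: str
    annulus: LabeledComponent
    nucleus: LabeledComponent
    wedge_angle: float
    height_posterior: float
    height_anterior: float
    cavity_fraction: float
    envelope: TriSurfaceSolid
    footprint: Tuple[float, float]  # (width, depth)

    def solids(self):
        return [self.annulus.solid, self.nucleus.solid]


def parse_pair(pair: str) -> Tuple[VertebralLevel, Optional[VertebralLevel]]:
    """'L3/4' -> (L3, L4); 'L5/S1' -> (L5, None) (S1 is untabulated)."""
    key = pair.strip().upper().replace(" ", "")
    if key not in DISC_PAIRS:
        raise ValueError(f"unknown disc level pair {pair!r}; expected one of {DISC_PAIRS}")
    upper = VertebralLevel(key.split("/")[0])
    lower = None if key == "L5/S1" else VertebralLevel("L" + key.split("/")[1])
    return upper, lower


def disc_height(
    group: "int | AgeGroup", pair: str, config: Optional[BuildConfig] = None
) -> float:
    """Disc height (mm): group ratio x mean adjacent posterior body height.

    With the anteriorly-opening wedge this is the height of the disc's tall
    (anterior) edge, which is also its stacking height in a straight spine.
    """
    config = config or default_config()
    group = get_age_group(group)
    upper, lower = parse_pair(pair)
    pu = get_dimensions(group, upper).PVBH
    pl = get_dimensions(group, lower).PVBH if lower is not None else pu
    return config.disc.height_ratio[group.index] * 0.5 * (pu + pl)


def wedge_prism(
    outline: np.ndarray,
    ztop_fn,
    name: str = "wedge prism",
) -> TriSurfaceSolid:
    """Prism on ``outline`` with a flat base at z=0 and top at ``ztop_fn(y)``."""
    poly = outline if sk.polygon_area(outline) > 0 else outline[::-1]
    n = len(poly)
    bottom = np.column_stack([poly, np.zeros(n)])
    top = np.column_stack([poly, ztop_fn(poly[:, 1])])
    if (top[:, 2] <= 1e-9).any():
        raise GeometryError("wedge top plane intersects the base within the footprint")
    caps = sk.earclip(poly)
    verts = np.vstack([bottom, top])
    faces = []
    for i in range(n):
        j = (i + 1) % n
        faces.append((i, j, n + j))
        faces.append((i, n + j, n + i))
    faces.extend((a, c, b) for a, b, c in caps)
    faces.extend((n + a, n + b, n + c) for a, b, c in caps)

    def sdf(points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        d2 = sk.polygon_sdf(p[:, :2], poly)
        dz = np.maximum(-p[:, 2], p[:, 2] - ztop_fn(p[:, 1]))
        return np.maximum(d2, dz)

    return TriSurfaceSolid.from_mesh(verts, np.asarray(faces), sdf=sdf, name=name)


def _scaled_outline(outline: np.ndarray, scale: float) -> np.ndarray:
    c = outline.mean(axis=0)
    return c + scale * (outline - c)


def disc_solids(
    outline: np.ndarray,
    height_anterior: float,
    wedge_angle: float,
    config: Optional[BuildConfig] = None,
) -> tuple:
    """Build (envelope, annulus, nucleus, cavity_fraction) for a footprint.

    The cavity is an inset copy of the envelope (anterior chamber plus
    posterior recess in one volume); its wall scale is solved by bisection
    until the cavity holds the configured fraction of the envelope volume.
    The nucleus is the cavity offset inward by the configured clearance.
    """
    from shapely.geometry import Polygon

    config = config or default_config()
    dc = config.disc
    y_ant = outline[:, 1].max()
    slope = math.tan(math.radians(wedge_angle))

    def ztop(y):
        return height_anterior - slope * (y_ant - np.asarray(y, dtype=float))

    envelope = wedge_prism(outline, ztop, name="disc envelope")
    v_env = envelope.volume
    margin = 0.12 * height_anterior

    def cavity_at(scale: float) -> TriSurfaceSolid:
        inner = _scaled_outline(outline, scale)

        def ztop_in(y):
            return ztop(y) - margin

        cav = wedge_prism(inner, ztop_in, name="nucleus cavity")
        return cav.translated((0, 0, margin))

    def fraction(scale: float) -> tuple:
        cav = cavity_at(scale)
        return cav.volume / v_env, cav

    lo, hi = 0.25, 0.97
    f_lo, _ = fraction(lo)
    f_hi, _ = fraction(hi)
    if not (f_lo < dc.cavity_fraction < f_hi):
        raise GeometryError(
            "requested cavity fraction is not reachable for this footprint"
        )
    cav = None
    s_solved = 0.5 * (lo + hi)
    for _ in range(48):
        s_solved = 0.5 * (lo + hi)
        f, cav = fraction(s_solved)
        if abs(f - dc.cavity_fraction) <= dc.cavity_fraction_tolerance:
            break
        if f < dc.cavity_fraction:
            lo = s_solved
        else:
            hi = s_solved
    cav_frac = cav.volume / v_env

    # annulus = envelope minus cavity: the exact two-shell mesh
    shell_in = cav.mesh.copy()
    shell_in.invert()
    ann_mesh = trimesh.util.concatenate([envelope.mesh.copy(), shell_in])
    env_sdf, cav_sdf = envelope.sdf, cav.sdf

    def ann_sdf(points):
        return np.maximum(env_sdf(points), -cav_sdf(points))

    annulus = TriSurfaceSolid(_mesh=ann_mesh, sdf=ann_sdf, name="annulus fibrosus")

    cl = dc.nucleus_clearance
    cav_poly = Polygon(_scaled_outline(outline, s_solved)).buffer(-cl, join_style=2)
    nuc_outline = np.asarray(cav_poly.exterior.coords)[:-1]

    def ztop_nuc(y):
        return ztop(y) - margin - cl - (margin + cl)

    nucleus = wedge_prism(nuc_outline, ztop_nuc, name="nucleus pulposus")
    nucleus = nucleus.translated((0, 0, margin + cl))
    return envelope, annulus, nucleus, cav_frac


def build_disc(
    group: "int | AgeGroup",
    pair: str,
    config: Optional[BuildConfig] = None,
    wedge_angle: Optional[float] = None,
) -> DiscModel:
    """Build one intervertebral disc for an age group and level pair."""
    config = config or default_config()
    group = get_age_group(group)
    upper, lower = parse_pair(pair)
    du = get_dimensions(group, upper)
    if lower is not None:
        dl = get_dimensions(group, lower)
        w = 0.5 * (du.IVBW + dl.SVBW)
        d = 0.5 * (du.IVBL + dl.SVBL)
        if w > max(du.IVBW, dl.SVBW) or d > max(du.IVBL, dl.SVBL):
            raise GeometryError("disc footprint exceeds both adjacent endplates")
    else:
        w, d = du.IVBW, du.IVBL

    # footprint outline: the body silhouette machinery of the group (with the
    # posterior recess, so the disc never blocks the vertebral canal), minus
    # clearance bites around the facet stations where the articular processes
    # and pins of the adjacent vertebrae pass through the disc space
    from shapely.geometry import Polygon, box as shapely_box

    from .vertebra import _facet_solids, facet_spec

    l3 = get_dimensions(group, VertebralLevel.L3)
    geom = BodyGeometry(l3, group, _arch_for(l3, group, config), config)
    outline = geom._outline(d, w)
    shift = group_origin_shift(group, config)
    outline = outline + shift[:2]
    spec = facet_spec(group, config)
    margin = 0.4
    poly = Polygon(outline)
    for side in (+1, -1):
        pin, prism = _facet_solids(spec, side, config)
        for s in (pin, prism):
            (x0, y0, _), (x1, y1, _) = s.bounds
            poly = poly.difference(
                shapely_box(x0 + shift[0] - margin, y0 + shift[1] - margin,
                            x1 + shift[0] + margin, y1 + shift[1] + margin)
            )
    if poly.geom_type != "Polygon":
        poly = max(poly.geoms, key=lambda p: p.area)
    outline = np.asarray(poly.exterior.coords)[:-1]
    if sk.polygon_area(outline) < 0:
        outline = outline[::-1]

    h_ant = disc_height(group, pair, config)
    angle = config.disc.wedge_angle_deg if wedge_angle is None else float(wedge_angle)
    envelope, annulus, nucleus, cav_frac = disc_solids(outline, h_ant, angle, config)
    y_span = outline[:, 1].max() - outline[:, 1].min()
    h_post = h_ant - math.tan(math.radians(angle)) * y_span
    return DiscModel(
        group=group,
        pair=pair.strip().upper().replace(" ", ""),
        annulus=LabeledComponent(annulus, get_material("annulus fibrosus"), "annulus fibrosus"),
        nucleus=LabeledComponent(nucleus, get_material("nucleus pulposus"), "nucleus pulposus"),
        wedge_angle=angle,
        height_posterior=h_post,
        height_anterior=h_ant,
        cavity_fraction=cav_frac,
        envelope=envelope,
        footprint=(w, d),
    )
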