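"""Deterministic kernel test fixtures with closed-form areas and volumes."""

from __future__ import annotations

import math

import numpy as np

from .solid_kernel import PlanarProfile, TriSurfaceSolid, box, extrude_polygon

__all__ = ["fixture_profiles"]


def fixture_profiles() -> dict:
    """Profiles and primitive solids with documented exact measures.

    Keys -> (object, exact measure):

    * ``unit_square``: 1x1 profile, area 1.
    * ``circle_r2``: radius-2 polygon (64 segments); area of the smooth
      circle is 4*pi, the inscribed polygon (n/2)*sin(2*pi/n)*r^2.
    * ``l_profile``: L-shaped hexagon, area 3.
    * ``annulus_rect``: rectangle r in [1, 2], z in [0, 2] for revolution;
      the full revolution has volume pi*(2^2-1^2)*2 = 6*pi.
    * ``nested_boxes``: (outer unit cube, co-centred cube of edge 0.5);
      difference volume 1 - 0.125 = 0.875.
    * ``l_prism``: the L profile extruded to height 1, volume 3.
    """
    ang = np.linspace(0.0, 2.0 * math.pi, 64, endpoint=False)
    circle = np.column_stack([2.0 * np.cos(ang), 2.0 * np.sin(ang)])
    lshape = np.array([[0, 0], [2, 0], [2, 1], [1, 1], [1, 2], [0, 2]], dtype=float)
    return {
        "unit_square": (
            PlanarProfile(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)),
            1.0,
        ),
        "circle_r2": (PlanarProfile(circle), 4.0 * math.pi),
        "l_profile": (PlanarProfile(lshape), 3.0),
        "annulus_rect": (
            PlanarProfile(np.array([[1, 0], [2, 0], [2, 2], [1, 2]], dtype=float)),
            6.0 * math.pi,
        ),
        "nested_boxes": ((box(1, 1, 1), box(0.5, 0.5, 0.5)), 0.875),
        "l_prism": (extrude_polygon(lshape, 0.0, 1.0), 3.0),
    }
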