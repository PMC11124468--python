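"""Build configuration: every package default in one documented namespace.

All geometric defaults that the construction needs but the dimension table
does not print live here, grouped by the stage that consumes them.  A config
can be loaded from JSON (same schema as ``BuildConfig.model_dump()``), and
every builder accepts an optional config, falling back to the defaults.

All lengths are in mm, all angles in degrees; fields named ``*_fraction``
are dimensionless multipliers of a printed body dimension of the vertebra
being built (documented per field).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

from pydantic import BaseModel, Field

__all__ = ["BuildConfig", "KernelConfig", "BodyConfig", "ArchConfig",
           "DiscConfig", "SpineConfig", "default_config", "load_config"]


class KernelConfig(BaseModel):
    """Mesh-resolution knobs for the solid kernel."""

    model_config = dict(frozen=True)

    #: facets per full revolution on curved faces (chord error well under
    #: 0.05 mm at vertebral-body radii)
    segments: int = Field(default=64, ge=12)
    #: marching-cubes cells across one MVBW for CSG results; the grid pitch
    #: for a vertebra is MVBW / csg_resolution, clamped below
    csg_resolution: int = Field(default=96, ge=24)
    min_pitch: float = Field(default=0.12, gt=0)
    max_pitch: float = Field(default=0.45, gt=0)
    #: rings along the body height and points around the body outline
    body_rings: int = Field(default=48, ge=8)
    outline_points: int = Field(default=48, ge=16)


class BodyConfig(BaseModel):
    """Vertebral-body shaping defaults (endplate reliefs, age styling)."""

    model_config = dict(frozen=True)

    #: central endplate fossa: spherical-cap cutout depth as fraction of PVBH
    fossa_depth_fraction: float = Field(default=0.05, ge=0)
    #: fossa radius as fraction of min(SVBW, SVBL)/2
    fossa_radius_fraction: float = Field(default=0.55, gt=0, lt=1)
    #: preadolescent ring-apophysis "step": recess band just below/above the
    #: endplate rims; radial inset and band height as fractions of PVBH
    step_depth_fraction: float = Field(default=0.08, ge=0)
    step_band_fraction: float = Field(default=0.10, gt=0)
    step_rim_fraction: float = Field(default=0.06, gt=0)
    #: endplate rim notches (groups 3-5): count and depth (mm); placed so the
    #: extreme width/depth stations are untouched
    notch_count: int = Field(default=12, ge=0)
    notch_depth: float = Field(default=0.3, ge=0)
    #: fraction of body height occupied by each notched band at the rims
    notch_band_fraction: float = Field(default=0.15, gt=0, lt=0.5)


class ArchConfig(BaseModel):
    """Posterior-element defaults; arch linear measurements come from
    :func:`pedispine.osteometry.derive_arch_parameters` (overridable here)."""

    model_config = dict(frozen=True)

    #: per-field overrides forwarded to derive_arch_parameters
    overrides: Dict[str, float] = Field(default_factory=dict)
    #: synchondrosis (cartilage layer) thickness as fraction of pedicle width
    cartilage_thickness_fraction: float = Field(default=0.15, gt=0)
    #: assembly clearance left between cartilage and bone faces (mm); keeps
    #: components in contact (< 0.05 mm) without boolean overlap
    contact_clearance: float = Field(default=0.02, gt=0)
    #: half-angle of the body's posterior recess span (deg from anterior axis
    #: of the foramen)
    recess_half_angle: float = Field(default=55.0, gt=10, lt=85)
    #: facet joint: target articular gap (mm; the joint-surface bound is
    #: 0.5 mm) and bisection tolerance
    facet_gap_target: float = Field(default=0.40, gt=0, le=0.5)
    facet_gap_tolerance: float = Field(default=0.02, gt=0)
    #: facet pin radius as fraction of pedicle width
    facet_pin_fraction: float = Field(default=0.30, gt=0)
    #: foramen shape morph toward a rounded triangle, per age group
    #: (0 = elliptic, 1 = triangular)
    foramen_triangularity: Dict[int, float] = Field(
        default_factory=lambda: {1: 0.0, 2: 0.15, 3: 0.25, 4: 0.45, 5: 0.50}
    )
    #: spinous process styling per group: length multiplier and pitch below
    #: the horizontal (deg); groups 1-3 carry only a rudiment or nothing
    spinous_length_factor: Dict[int, float] = Field(
        default_factory=lambda: {1: 0.0, 2: 0.25, 3: 0.35, 4: 1.0, 5: 1.0}
    )
    spinous_slant_deg: Dict[int, float] = Field(
        default_factory=lambda: {1: 0.0, 2: 0.0, 3: 0.0, 4: 15.0, 5: 0.0}
    )
    #: infant exception: keep the midline synchondrosis at L5 in group 2
    group2_l5_midline_cartilage: bool = False


class DiscConfig(BaseModel):
    """Intervertebral-disc defaults."""

    model_config = dict(frozen=True)

    #: sagittal wedge angle between the planar superior and inferior faces
    wedge_angle_deg: float = Field(default=7.0, ge=0, lt=30)
    #: target fraction of disc volume occupied by the nucleus cavity,
    #: solved by bisection on the cavity wall scale
    cavity_fraction: float = Field(default=0.50, gt=0.1, lt=0.9)
    cavity_fraction_tolerance: float = Field(default=0.005, gt=0)
    #: uniform annulus-to-nucleus clearance (mm), <= 0.1
    nucleus_clearance: float = Field(default=0.05, gt=0, le=0.1)
    #: disc height as a ratio of the mean adjacent posterior body height;
    #: group 1 matches the bodies, later groups shrink relative to them
    height_ratio: Dict[int, float] = Field(
        default_factory=lambda: {1: 1.0, 2: 0.8, 3: 0.6, 4: 0.4, 5: 0.3}
    )


class SpineConfig(BaseModel):
    """Whole-spine assembly defaults."""

    model_config = dict(frozen=True)

    #: total lumbar lordosis per group (deg), distributed equally across the
    #: five motion segments; absent before upright posture, visible from the
    #: toddler group on
    lordosis_deg: Dict[int, float] = Field(
        default_factory=lambda: {1: 0.0, 2: 0.0, 3: 15.0, 4: 25.0, 5: 30.0}
    )
    #: stacking clearance left at each interface (mm); keeps adjacent
    #: elements in contact (< 0.1 mm) without interpenetration
    contact_clearance: float = Field(default=0.03, gt=0, lt=0.1)
    #: S1 superior endplate plate thickness as fraction of L5 PVBH
    s1_thickness_fraction: float = Field(default=0.30, gt=0)


class BuildConfig(BaseModel):
    """Root configuration namespace."""

    model_config = dict(frozen=True)

    kernel: KernelConfig = Field(default_factory=KernelConfig)
    body: BodyConfig = Field(default_factory=BodyConfig)
    arch: ArchConfig = Field(default_factory=ArchConfig)
    disc: DiscConfig = Field(default_factory=DiscConfig)
    spine: SpineConfig = Field(default_factory=SpineConfig)

    def cache_key(self) -> str:
        return self.model_dump_json()


_DEFAULT = BuildConfig()


def default_config() -> BuildConfig:
    return _DEFAULT


def load_config(path: "str | Path") -> BuildConfig:
    """Load a configuration from a JSON file (schema-validated)."""
    with open(path) as fh:
        return BuildConfig.model_validate(json.load(fh))
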