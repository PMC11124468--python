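"""Osteometric dimension tables, material registry and derived arch parameters.

The package ships two small tables as package data:

* ``dimensions.json`` -- mean linear dimensions (mm) of pediatric lumbar
  vertebral bodies for five age groups (newborn through preadolescent) at
  levels L1..L5, seven measurements per body (three heights are not
  independent: AVBH/PVBH are the anterior/posterior body heights, SVBL/IVBL
  the superior/inferior sagittal lengths, SVBW/MVBW/IVBW the superior/middle/
  inferior frontal widths).
* ``materials.json`` -- linear-elastic properties (Young's modulus ``E`` in
  MPa, Poisson's ratio ``nu``) for the five tissues used to label model
  components.

The arch and process measurements that the construction consumes (pedicle
height/width, process lengths, foramen diameters, ...) are not part of the
published body-dimension table.  They are derived here as documented fixed
fractions of the printed body dimensions (:data:`ARCH_FRACTIONS`), so the
whole build is reproducible from the packaged tables alone while scaling
naturally across age groups.  Every derived value can be overridden per field.
"""

from __future__ import annotations

import json
from enum import Enum
from functools import lru_cache
from importlib import resources
from typing import Mapping, Optional

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "AgeGroup",
    "VertebralLevel",
    "VertebralDimensions",
    "DerivedArchParameters",
    "TissueMaterial",
    "ARCH_FRACTIONS",
    "LEVELS",
    "age_groups",
    "get_age_group",
    "get_dimensions",
    "get_material",
    "material_registry",
    "derive_arch_parameters",
    "load_dimension_table",
]


class OsteometryLookupError(KeyError):
    """Raised when a group/level/tissue key does not resolve."""


class VertebralLevel(str, Enum):
    """Lumbar vertebral level."""

    L1 = "L1"
    L2 = "L2"
    L3 = "L3"
    L4 = "L4"
    L5 = "L5"

    @classmethod
    def coerce(cls, value: "VertebralLevel | str") -> "VertebralLevel":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            raise OsteometryLookupError(
                f"unknown vertebral level {value!r}; expected one of "
                f"{[lvl.value for lvl in cls]}"
            ) from None


LEVELS = list(VertebralLevel)


class AgeGroup(BaseModel):
    """One of the five modeled age groups."""

    model_config = dict(frozen=True)

    index: int = Field(ge=1, le=5)
    label: str
    specimen_count: int = Field(gt=0)


class VertebralDimensions(BaseModel):
    """The seven printed osteometric measurements of one vertebral body (mm)."""

    model_config = dict(frozen=True)

    AVBH: float = Field(gt=0, lt=50)
    PVBH: float = Field(gt=0, lt=50)
    SVBL: float = Field(gt=0, lt=50)
    IVBL: float = Field(gt=0, lt=50)
    SVBW: float = Field(gt=0, lt=50)
    MVBW: float = Field(gt=0, lt=50)
    IVBW: float = Field(gt=0, lt=50)

    @model_validator(mode="after")
    def _widths_exceed_lengths(self) -> "VertebralDimensions":
        if min(self.SVBW, self.MVBW, self.IVBW) <= max(self.SVBL, self.IVBL):
            raise ValueError(
                "frontal widths (SVBW, MVBW, IVBW) must exceed sagittal "
                "lengths (SVBL, IVBL) for a lumbar vertebral body"
            )
        return self


class DerivedArchParameters(BaseModel):
    """Arch/process measurements consumed by the posterior-element build.

    All lengths in mm.  ``facet_cutout_diameter`` here is only an analytic
    seed; the vertebra builder refines it by bisection against the measured
    facet gap (target clearance well under the 0.5 mm joint-gap bound).
    """

    model_config = dict(frozen=True)

    pedicle_height: float = Field(gt=0)
    pedicle_width: float = Field(gt=0)
    arch_plate_thickness: float = Field(gt=0)
    transverse_process_length: float = Field(gt=0)
    spinous_process_length: float = Field(gt=0)
    articular_process_length: float = Field(gt=0)
    foramen_frontal_diameter: float = Field(gt=0)
    foramen_sagittal_diameter: float = Field(gt=0)
    facet_cutout_diameter: float = Field(gt=0)
    fillet_radius: float = Field(gt=0)


_TISSUES = (
    "cortical bone",
    "trabecular bone",
    "cartilage",
    "nucleus pulposus",
    "annulus fibrosus",
)


class TissueMaterial(BaseModel):
    """Linear-elastic material attached to a labeled component."""

    model_config = dict(frozen=True)

    tissue: str
    youngs_modulus_E: float = Field(gt=0)
    poisson_ratio_nu: float = Field(ge=0, lt=0.5)


#: Documented default fractions mapping printed body dimensions to the
#: unprinted arch/process measurements.  Each entry is
#: ``field -> (fraction, source dimension)``.  These are package defaults
#: (stand-ins for the authors' untabulated arch osteometry) and every one can
#: be overridden through :func:`derive_arch_parameters` or the build config.
ARCH_FRACTIONS: Mapping[str, tuple[float, str]] = {
    "pedicle_height": (0.55, "PVBH"),
    "pedicle_width": (0.20, "MVBW"),
    "arch_plate_thickness": (0.12, "MVBW"),
    "transverse_process_length": (0.45, "MVBW"),
    "spinous_process_length": (0.50, "SVBL"),
    "articular_process_length": (0.35, "PVBH"),
    "foramen_frontal_diameter": (0.60, "MVBW"),
    "foramen_sagittal_diameter": (0.80, "IVBL"),
}

#: Facet pin (inferior articular cylinder) radius as a fraction of pedicle
#: width, and the analytic seed clearance (mm) used before bisection.
FACET_PIN_FRACTION = 0.30
FACET_SEED_CLEARANCE = 0.40

#: Fillet radius fraction of the smallest of pedicle width / plate thickness.
FILLET_FRACTION = 0.10


def _read_json(name: str) -> dict:
    with resources.files("pedispine.data").joinpath(name).open("r") as fh:
        return json.load(fh)


@lru_cache(maxsize=1)
def load_dimension_table() -> dict:
    """Raw packaged dimension table (parsed JSON, cached)."""
    return _read_json("dimensions.json")


@lru_cache(maxsize=1)
def _groups() -> dict[int, dict]:
    return {g["index"]: g for g in load_dimension_table()["groups"]}


@lru_cache(maxsize=1)
def age_groups() -> tuple[AgeGroup, ...]:
    """All five packaged age groups, in index order."""
    return tuple(
        AgeGroup(
            index=g["index"],
            label=g["label"],
            specimen_count=g["specimen_count"],
        )
        for g in load_dimension_table()["groups"]
    )


def get_age_group(index: "int | AgeGroup") -> AgeGroup:
    if isinstance(index, AgeGroup):
        return index
    for group in age_groups():
        if group.index == index:
            return group
    raise OsteometryLookupError(
        f"unknown age group {index!r}; expected an integer 1..5"
    )


def get_dimensions(
    group: "int | AgeGroup", level: "VertebralLevel | str"
) -> VertebralDimensions:
    """Look up the packaged mean dimensions for one (age group, level) pair."""
    grp = get_age_group(group)
    lvl = VertebralLevel.coerce(level)
    record = _groups()[grp.index]["levels"][lvl.value]
    return VertebralDimensions(**record)


@lru_cache(maxsize=1)
def material_registry() -> dict[str, TissueMaterial]:
    data = _read_json("materials.json")
    registry = {m["tissue"]: TissueMaterial(**m) for m in data["materials"]}
    assert tuple(registry) == _TISSUES
    return registry


def get_material(tissue: str) -> TissueMaterial:
    """Look up a tissue material by (case-insensitive) name."""
    key = str(tissue).strip().lower()
    registry = material_registry()
    if key not in registry:
        raise OsteometryLookupError(
            f"unknown tissue {tissue!r}; valid names: {sorted(registry)}"
        )
    return registry[key]


def derive_arch_parameters(
    dims: VertebralDimensions,
    group: "int | AgeGroup",
    overrides: Optional[Mapping[str, float]] = None,
) -> DerivedArchParameters:
    """Derive the unprinted arch/process measurements from printed dims.

    Every field defaults to a fixed fraction of one printed dimension
    (:data:`ARCH_FRACTIONS`); ``overrides`` replaces individual fields
    verbatim.  Deterministic; the age group is accepted for symmetry with the
    builders (the default fractions are age-invariant, which preserves the
    cross-age scaling of the printed table).
    """
    get_age_group(group)  # validate
    values: dict[str, float] = {
        field: fraction * getattr(dims, source)
        for field, (fraction, source) in ARCH_FRACTIONS.items()
    }
    pin_radius = FACET_PIN_FRACTION * values["pedicle_width"]
    values["facet_cutout_diameter"] = 2.0 * (pin_radius + FACET_SEED_CLEARANCE)
    values["fillet_radius"] = FILLET_FRACTION * min(
        values["pedicle_width"], values["arch_plate_thickness"]
    )
    if overrides:
        for key, value in overrides.items():
            if key not in values:
                raise ValueError(
                    f"unknown arch parameter {key!r}; valid fields: "
                    f"{sorted(values)}"
                )
            if not value > 0:
                raise ValueError(f"arch parameter {key!r} must be > 0, got {value}")
            values[key] = float(value)
    return DerivedArchParameters(**values)
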