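"""Mesh export with tissue/material manifests for downstream FEA tools.

Each model component is written to its own mesh file (binary STL by default;
ASCII STL, OBJ and PLY are available) together with a JSON manifest mapping
every file to its anatomical name, tissue, Young's modulus (MPa) and Poisson
ratio, so the labeled geometry plus material set travels as one bundle.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import List, Union

from .vertebra import LabeledComponent, VertebraModel
from .disc import DiscModel
from .spine import SpineModel

__all__ = ["ExportBundle", "export", "SUPPORTED_FORMATS"]

SUPPORTED_FORMATS = {
    "stl": ("stl", "stl"),
    "stl_ascii": ("stl_ascii", "stl"),
    "obj": ("obj", "obj"),
    "ply": ("ply", "ply"),
}


class ExportFormatError(ValueError):
    pass


@dataclass
class ExportBundle:
    directory: Path
    manifest_path: Path
    manifest: dict

    @property
    def files(self) -> List[Path]:
        return [self.directory / e["file"] for e in self.manifest["components"]]


def _components(model) -> List[LabeledComponent]:
    if isinstance(model, VertebraModel):
        return model.components
    if isinstance(model, DiscModel):
        return [model.annulus, model.nucleus]
    if isinstance(model, SpineModel):
        return model.world_components()
    if isinstance(model, LabeledComponent):
        return [model]
    raise TypeError(f"cannot export {type(model).__name__}")


def _slug(name: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", name.lower()).strip("_")


def export(
    model: Union[VertebraModel, DiscModel, SpineModel, LabeledComponent],
    fmt: str,
    path: "str | Path",
) -> ExportBundle:
    """Write one mesh file per component plus ``manifest.json`` into ``path``."""
    key = fmt.strip().lower()
    if key not in SUPPORTED_FORMATS:
        raise ExportFormatError(
            f"unsupported format {fmt!r}; supported: {sorted(SUPPORTED_FORMATS)}"
        )
    file_type, ext = SUPPORTED_FORMATS[key]
    directory = Path(path)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    seen: dict = {}
    for comp in _components(model):
        stem = _slug(comp.anatomical_name) or "component"
        if stem in seen:
            seen[stem] += 1
            stem = f"{stem}_{seen[stem]}"
        else:
            seen[stem] = 1
        fname = f"{stem}.{ext}"
        data = comp.solid.mesh.export(file_type=file_type)
        mode = "wb" if isinstance(data, bytes) else "w"
        with open(directory / fname, mode) as fh:
            fh.write(data)
        entries.append(
            {
                "component": comp.anatomical_name,
                "tissue": comp.tissue.tissue,
                "youngs_modulus_E_MPa": comp.tissue.youngs_modulus_E,
                "poisson_ratio_nu": comp.tissue.poisson_ratio_nu,
                "file": fname,
                "triangles": int(len(comp.solid.faces)),
                "vertices": int(len(comp.solid.vertices)),
                "volume_mm3": comp.solid.volume,
            }
        )
    manifest = {"format": key, "units": "mm", "components": entries}
    manifest_path = directory / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return ExportBundle(directory=directory, manifest_path=manifest_path, manifest=manifest)
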