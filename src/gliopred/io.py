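"""Field, configuration and manifest persistence.

Volumetric fields travel as NIfTI-1 (voxel spacing in the header zooms,
origin in the affine translation); study/domain configurations as YAML;
time-course and experiment manifests as JSON. Every manifest records the
seeds it was produced with.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .grids import Grid, ScalarField
from .growth import TimeCourse

__all__ = [
    "save_field",
    "load_field",
    "save_config",
    "load_config",
    "save_timecourse_manifest",
    "save_json",
]


def save_field(field: ScalarField, path: str | Path) -> None:
    """Write a scalar field as NIfTI-1, carrying grid geometry in the header."""
    affine = np.diag([*field.grid.spacing, 1.0])
    affine[:3, 3] = field.grid.origin
    img = nib.Nifti1Image(field.values.astype(np.float32), affine)
    img.header.set_zooms(field.grid.spacing)
    img.header["descrip"] = field.role.encode()[:79]
    nib.save(img, str(path))


def load_field(path: str | Path, role: str = "generic") -> ScalarField:
    """Read a NIfTI-1 volume back into a :class:`ScalarField`."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(x) for x in img.affine[:3, 3])
    grid = Grid(data.shape, tuple(float(z) for z in zooms), origin)
    stored_role = img.header["descrip"].tobytes().split(b"\x00")[0].decode(errors="ignore")
    return ScalarField(grid, data, stored_role if stored_role else role)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_config(config, path: str | Path) -> None:
    """Serialize a (possibly nested) configuration dataclass to YAML."""
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=False))


def load_config(path: str | Path) -> dict:
    """Load a YAML configuration into a plain dict (caller rebuilds dataclasses)."""
    return yaml.safe_load(Path(path).read_text())


def save_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(_to_plain(obj), indent=2, default=str))


def save_timecourse_manifest(tc: TimeCourse, directory: str | Path,
                             prefix: str = "day", write_fields: bool = False) -> Path:
    """Write a time-course manifest (JSON), optionally with per-day NIfTI fields.

    The manifest records grid geometry, model parameters, solver metadata
    and the file layout; fields are written as one volume per day per
    species when ``write_fields`` is set.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "grid": {"shape": list(tc.grid.shape), "spacing": list(tc.grid.spacing),
                 "origin": list(tc.grid.origin)},
        "days": tc.days,
        "parameters": _to_plain(tc.parameters) if tc.parameters else None,
        "metadata": _to_plain(tc.metadata),
        "files": {},
    }
    if write_fields:
        for day in tc.days:
            files = {}
            for species, getter in (("tumor", tc.tumor), ("vasculature", tc.vasculature)):
                name = f"{prefix}{day:02d}_{species}.nii.gz"
                save_field(getter(day), directory / name)
                files[species] = name
            manifest["files"][str(day)] = files
    path = directory / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
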