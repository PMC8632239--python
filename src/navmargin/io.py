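"""File formats: NIfTI volumes/masks/fields, STL meshes, CSV/JSON tables.

The affine written to NIfTI encodes the package's RAS-mm convention
(isotropic spacing on the diagonal, origin in the translation column);
it is always written, never assumed on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .grids import DistanceField, LabelMask, Volume

__all__ = [
    "save_nifti",
    "load_volume",
    "load_mask",
    "load_distance_field",
    "save_mesh_stl",
    "save_fiducials_csv",
    "load_fiducials_csv",
    "save_json",
]


def _grid_from_affine(affine):
    spacing = float(affine[0, 0])
    if not np.allclose(np.diag(affine)[:3], spacing):
        raise ValueError("only isotropic axis-aligned affines are supported")
    return spacing, affine[:3, 3].copy()


def save_nifti(obj, path):
    import nibabel as nib

    if isinstance(obj, LabelMask):
        data = obj.voxels.astype(np.uint8)
    elif isinstance(obj, (Volume, DistanceField)):
        data = obj._array().astype(np.float32)
    else:
        raise TypeError(f"cannot save {type(obj).__name__} as NIfTI")
    img = nib.Nifti1Image(data, obj.affine)
    nib.save(img, str(path))


def _load(path, dtype):
    import nibabel as nib

    img = nib.load(str(path))
    spacing, origin = _grid_from_affine(img.affine)
    return np.asarray(img.dataobj).astype(dtype), spacing, origin


def load_volume(path) -> Volume:
    data, spacing, origin = _load(path, np.float32)
    return Volume(spacing=spacing, origin=origin, data=data)


def load_mask(path) -> LabelMask:
    data, spacing, origin = _load(path, bool)
    return LabelMask(spacing=spacing, origin=origin, voxels=data)


def load_distance_field(path) -> DistanceField:
    data, spacing, origin = _load(path, float)
    return DistanceField(spacing=spacing, origin=origin, values=data)


def save_mesh_stl(mesh, path):
    mesh.export(str(path))


def save_fiducials_csv(fiducials, path):
    """CSV with columns name,x,y,z (true positions, mm)."""
    lines = ["name,x,y,z"]
    for i, p in enumerate(np.asarray(fiducials.true_positions)):
        lines.append(f"F{i + 1},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_fiducials_csv(path) -> np.ndarray:
    rows = Path(path).read_text().strip().splitlines()[1:]
    return np.array([[float(v) for v in r.split(",")[1:4]] for r in rows])


def save_json(obj, path):
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")
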