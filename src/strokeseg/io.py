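"""NIfTI and transform file I/O.

Volumes are stored with a diagonal affine built from the voxel spacing
(axis-aligned grids, origin at voxel (0,0,0)).  A label atlas can be stored
either as six binary NIfTIs or as one integer-coded NIfTI with codes::

    1 = whole brain only     4 = ipsilateral ventricle
    2 = ipsilateral hemisphere   5 = contralateral ventricle
    3 = contralateral hemisphere 6 = periventricular zone

Overlap-decoding rules (the coded form is a precedence encoding, highest
code wins: ventricles > periventricular zone > hemispheres > brain):
whole brain = any code >= 1; ipsilateral hemisphere = codes {2, 4};
contralateral hemisphere = codes {3, 5}; ventricles = their own codes;
periventricular zone = code 6.  Note the coded form loses the hemisphere
membership of periventricular voxels; use the six-file form when that
matters.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np

from .label_propagation import SpatialTransform
from .volume import LabelAtlas, ScalarVolume

__all__ = [
    "load_volume",
    "save_volume",
    "load_atlas",
    "save_atlas",
    "encode_atlas",
    "decode_atlas",
    "load_transform",
    "save_transform",
]

PathLike = Union[str, Path]


def _affine(spacing) -> np.ndarray:
    return np.diag(list(spacing) + [1.0])


def load_volume(path: PathLike) -> ScalarVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ScalarVolume(data, spacing)


def load_echo_stack(path: PathLike) -> list[ScalarVolume]:
    """Load a 4D NIfTI (x, y, z, echo) as a list of echo volumes."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D echo stack, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return [ScalarVolume(data[..., i], spacing) for i in range(data.shape[3])]


def save_volume(vol: ScalarVolume, path: PathLike, dtype=np.float32) -> None:
    nib.save(
        nib.Nifti1Image(vol.values.astype(dtype), _affine(vol.spacing)), str(path)
    )


def save_mask(mask: np.ndarray, spacing, path: PathLike) -> None:
    nib.save(
        nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(spacing)), str(path)
    )


def encode_atlas(atlas: LabelAtlas) -> np.ndarray:
    """Integer-coded label volume (precedence encoding, see module docs)."""
    code = np.zeros(atlas.shape, dtype=np.uint8)
    code[atlas.wb] = 1
    code[atlas.ibh] = 2
    code[atlas.cbh] = 3
    code[atlas.pvz] = 6
    code[atlas.iv] = 4
    code[atlas.cv] = 5
    return code


def decode_atlas(code: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> LabelAtlas:
    code = np.asarray(code)
    return LabelAtlas(
        wb=code >= 1,
        ibh=np.isin(code, (2, 4)),
        cbh=np.isin(code, (3, 5)),
        iv=code == 4,
        cv=code == 5,
        pvz=code == 6,
        spacing=spacing,
    )


def save_atlas(atlas: LabelAtlas, path: PathLike) -> None:
    """Save as a single integer-coded NIfTI."""
    nib.save(
        nib.Nifti1Image(encode_atlas(atlas), _affine(atlas.spacing)), str(path)
    )


def load_atlas(path: PathLike) -> LabelAtlas:
    """Load an atlas from one coded NIfTI, or from a directory of six binary
    NIfTIs named ``wb/ibh/cbh/iv/cv/pvz.nii[.gz]``."""
    path = Path(path)
    if path.is_dir():
        masks, spacing = {}, None
        for name in LabelAtlas._FIELDS:
            hits = sorted(path.glob(f"{name}.nii*"))
            if not hits:
                raise FileNotFoundError(f"missing atlas mask {name} in {path}")
            vol = load_volume(hits[0])
            masks[name] = vol.values > 0.5
            spacing = vol.spacing
        return LabelAtlas(**masks, spacing=spacing)
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return decode_atlas(np.asarray(img.dataobj), spacing)


def save_transform(transform: SpatialTransform, path: PathLike) -> None:
    """Affine: 4x4 row-major plain text (mm).  Displacement field: a
    3-component NIfTI on the fixed grid (mm)."""
    path = Path(path)
    if transform.kind in ("rigid", "affine"):
        np.savetxt(path, transform.matrix, fmt="%.12g")
    else:
        nib.save(nib.Nifti1Image(transform.field.astype(np.float32), np.eye(4)), str(path))


def load_transform(path: PathLike) -> SpatialTransform:
    path = Path(path)
    if path.suffix in (".nii", ".gz") or "".join(path.suffixes).endswith(".nii.gz"):
        field = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
        return SpatialTransform(kind="displacement", field=field)
    matrix = np.loadtxt(path)
    if matrix.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix in {path}")
    return SpatialTransform(kind="affine", matrix=matrix)


def save_report(report: dict, path: PathLike) -> None:
    Path(path).write_text(json.dumps(report, indent=2, default=float) + "\n")
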