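"""Template-to-subject label propagation.

The six template masks are brought into a subject's space through a spatial
transform obtained either from the built-in multi-resolution rigid + affine
registration (normalized correlation metric, Gaussian image pyramid with
four rigid and two affine levels, powered by SimpleITK) or from an external
tool (a 4x4 affine text file or a dense displacement-field NIfTI, e.g. the
output of a non-rigid B-spline registration).  Labels are warped with
nearest-neighbor interpolation and the atlas containment invariants are
re-enforced afterwards.

Transform convention (the resampling convention): a transform maps a
physical point (mm) of the *fixed* (subject) grid to the corresponding
physical point of the *moving* (template) grid.  Grids are axis-aligned
with the origin at voxel (0,0,0).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volume import LabelAtlas, ScalarVolume

__all__ = [
    "SpatialTransform",
    "register_ncc",
    "propagate_labels",
    "warp_scalar",
    "ncc",
]


@dataclass
class SpatialTransform:
    """A rigid/affine 4x4 matrix (mm) or a dense displacement field.

    For ``kind`` in {"rigid", "affine"}: ``matrix`` is 4x4 homogeneous,
    mapping fixed-space mm coordinates to moving-space mm coordinates.
    For ``kind == "displacement"``: ``field`` has shape ``(nx, ny, nz, 3)``
    on the fixed grid, in mm; the mapping is ``p -> p + field(p)``.
    """

    kind: str
    matrix: Optional[np.ndarray] = None
    field: Optional[np.ndarray] = None
    final_ncc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind in ("rigid", "affine"):
            self.matrix = np.asarray(self.matrix, dtype=np.float64)
            if self.matrix.shape != (4, 4):
                raise ValueError("matrix must be 4x4")
            if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
                raise ValueError("singular linear part")
        elif self.kind == "displacement":
            self.field = np.asarray(self.field, dtype=np.float64)
            if self.field.ndim != 4 or self.field.shape[3] != 3:
                raise ValueError("field must have shape (nx, ny, nz, 3)")
        else:
            raise ValueError(f"unknown transform kind {self.kind!r}")

    @classmethod
    def identity(cls) -> "SpatialTransform":
        return cls(kind="rigid", matrix=np.eye(4))

    def map_points_mm(self, pts: np.ndarray) -> np.ndarray:
        """Map an ``(..., 3)`` array of fixed-space mm points."""
        if self.kind == "displacement":
            return pts + self.field.reshape(pts.shape)
        lin = self.matrix[:3, :3]
        return pts @ lin.T + self.matrix[:3, 3]


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized correlation coefficient (Pearson r) of two arrays."""
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        raise ValueError("NCC undefined for a constant image")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def _to_sitk(vol: ScalarVolume) -> sitk.Image:
    # SimpleITK expects (z, y, x) array layout
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.values.T))
    img.SetSpacing(tuple(vol.spacing))
    return img


def _sitk_to_matrix(tfm: sitk.Transform) -> np.ndarray:
    if isinstance(tfm, (sitk.Euler3DTransform, sitk.AffineTransform)):
        lin = np.array(tfm.GetMatrix()).reshape(3, 3)
        center = np.array(tfm.GetCenter())
        trans = np.array(tfm.GetTranslation())
    else:  # composite: flatten to a single affine
        comp = sitk.CompositeTransform(tfm)
        m = np.eye(4)
        for i in range(comp.GetNumberOfTransforms()):
            m = _sitk_to_matrix(comp.GetNthTransform(i)) @ m
        return m
    m = np.eye(4)
    m[:3, :3] = lin
    m[:3, 3] = trans + center - lin @ center
    return m


def _run_stage(
    fixed: sitk.Image,
    moving: sitk.Image,
    initial: sitk.Transform,
    shrink: list[int],
    sigmas: list[float],
) -> sitk.Transform:
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-5,
        numberOfIterations=200,
        relaxationFactor=0.5,
        gradientMagnitudeTolerance=1e-8,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(shrink)
    reg.SetSmoothingSigmasPerLevel(sigmas)
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOff()
    reg.SetInitialTransform(initial, inPlace=True)
    return reg.Execute(fixed, moving)


def register_ncc(
    moving: ScalarVolume,
    fixed: ScalarVolume,
    do_rigid: bool = True,
    do_affine: bool = True,
) -> SpatialTransform:
    """Coarse-to-fine rigid then affine registration maximizing NCC.

    ``moving`` is the template scan, ``fixed`` the subject scan (typically
    its echo sum).  Four pyramid levels are used for the rigid stage and two
    for the affine stage.  Returns the transform together with the final NCC
    between the warped moving image and the fixed image.
    """
    if moving.values.std() == 0.0 or fixed.values.std() == 0.0:
        raise ValueError("NCC undefined for a constant image")
    f_img, m_img = _to_sitk(fixed), _to_sitk(moving)
    tfm: sitk.Transform = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.Euler3DTransform(),
        sitk.CenteredTransformInitializerFilter.GEOMETRY,
    )
    kind = "rigid"
    if do_rigid:
        tfm = _run_stage(f_img, m_img, sitk.Euler3DTransform(tfm), [8, 4, 2, 1], [3, 2, 1, 0])
    if do_affine:
        rigid_m = _sitk_to_matrix(tfm)
        aff = sitk.AffineTransform(3)
        aff.SetMatrix(tuple(rigid_m[:3, :3].ravel()))
        aff.SetTranslation(tuple(rigid_m[:3, 3]))
        tfm = _run_stage(f_img, m_img, aff, [2, 1], [1, 0])
        kind = "affine"
    matrix = _sitk_to_matrix(tfm)
    out = SpatialTransform(kind=kind, matrix=matrix)
    warped = warp_scalar(moving, out, fixed.shape, fixed.spacing)
    out.final_ncc = ncc(warped.values, fixed.values)
    return out


def _moving_voxel_coords(
    transform: SpatialTransform,
    target_shape: tuple[int, int, int],
    target_spacing: tuple[float, float, float],
    source_spacing: tuple[float, float, float],
) -> np.ndarray:
    idx = np.indices(target_shape, dtype=np.float64)  # (3, nx, ny, nz)
    pts = np.stack(
        [idx[ax] * target_spacing[ax] for ax in range(3)], axis=-1
    )  # mm points on the fixed grid
    q = transform.map_points_mm(pts)
    return np.stack([q[..., ax] / source_spacing[ax] for ax in range(3)], axis=0)


def warp_scalar(
    source: ScalarVolume,
    transform: SpatialTransform,
    target_shape: tuple[int, int, int],
    target_spacing: tuple[float, float, float],
    order: int = 1,
) -> ScalarVolume:
    """Resample a source volume onto the target grid through the transform."""
    coords = _moving_voxel_coords(transform, target_shape, target_spacing, source.spacing)
    out = ndimage.map_coordinates(source.values, coords, order=order, mode="nearest")
    return ScalarVolume(out, target_spacing)


def propagate_labels(
    atlas: LabelAtlas,
    transform: SpatialTransform,
    target_shape: tuple[int, int, int],
    target_spacing: tuple[float, float, float],
) -> LabelAtlas:
    """Warp the six template masks onto the subject grid (nearest neighbor).

    The containment invariants are re-enforced by masking after warping.
    Raises if the warped whole-brain mask is empty (mirrors the visual QC
    step: the propagation failed).
    """
    coords = _moving_voxel_coords(transform, target_shape, target_spacing, atlas.spacing)

    def warp(mask: np.ndarray) -> np.ndarray:
        return (
            ndimage.map_coordinates(
                mask.astype(np.uint8), coords, order=0, mode="constant", cval=0
            )
            > 0
        )

    warped = atlas.map_masks(warp)
    warped.spacing = tuple(target_spacing)
    warped = warped.conformed()
    if not warped.wb.any():
        raise ValueError("propagation-failed: warped whole-brain mask is empty")
    return warped
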