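"""Preprocessing applied before segmentation.

Volumes are cropped to the tight bounding box of the propagated whole-brain
mask and rescaled to the unit intensity range.  Echo images additionally get
a per-slice intensity normalization: every slice's cumulative intensity
distribution is mapped onto that of a reference slice (the slice with the
maximum histogram entropy).  The quantitative T2 map is never slice-wise
renormalized — its voxel values are physical (ms) and comparable across
slices by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.exposure import match_histograms

from .volume import ScalarVolume

__all__ = [
    "PreprocessReport",
    "crop_to_label_bbox",
    "apply_crop",
    "uncrop_mask",
    "rescale_unit",
    "select_reference_slice",
    "per_slice_cdf_normalize",
    "sum_echoes",
]

ENTROPY_BINS = 64


@dataclass
class PreprocessReport:
    """Record of what preprocessing did (crop box, rescale range, ref slice)."""

    crop_box: tuple[int, int, int, int, int, int]  # (x0, x1, y0, y1, z0, z1), half-open
    original_shape: tuple[int, int, int]
    intensity_min: Optional[float] = None
    intensity_max: Optional[float] = None
    reference_slice: Optional[int] = None

    def slices(self) -> tuple[slice, slice, slice]:
        x0, x1, y0, y1, z0, z1 = self.crop_box
        return (slice(x0, x1), slice(y0, y1), slice(z0, z1))


def crop_to_label_bbox(
    image: ScalarVolume, brain_mask: np.ndarray
) -> tuple[ScalarVolume, PreprocessReport]:
    """Crop to the smallest axis-aligned box containing ``brain_mask``.

    The same crop (via :func:`apply_crop` with the returned report) is meant
    to be applied to all companion volumes and label masks.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != image.shape:
        raise ValueError("brain_mask shape mismatch")
    if not brain_mask.any():
        raise ValueError("empty brain mask: nothing to crop to")
    box = []
    for axis in range(3):
        proj = brain_mask.any(axis=tuple(ax for ax in range(3) if ax != axis))
        idx = np.flatnonzero(proj)
        box.extend((int(idx[0]), int(idx[-1]) + 1))
    report = PreprocessReport(crop_box=tuple(box), original_shape=image.shape)
    return apply_crop(image, report), report


def apply_crop(image: ScalarVolume, report: PreprocessReport) -> ScalarVolume:
    return ScalarVolume(image.values[report.slices()], image.spacing)


def uncrop_mask(mask: np.ndarray, report: PreprocessReport) -> np.ndarray:
    """Zero-pad a cropped-grid mask back onto the original grid."""
    full = np.zeros(report.original_shape, dtype=bool)
    full[report.slices()] = mask
    return full


def rescale_unit(image: ScalarVolume) -> ScalarVolume:
    """Min–max rescale to [0, 1]; a constant image maps to all zeros."""
    v = image.values
    lo, hi = float(v.min()), float(v.max())
    if hi - lo <= 0.0:
        return image.like(np.zeros_like(v))
    return image.like((v - lo) / (hi - lo))


def _slice_entropy(slice_vals: np.ndarray, bins: int = ENTROPY_BINS) -> float:
    counts, _ = np.histogram(slice_vals, bins=bins)
    p = counts[counts > 0] / slice_vals.size
    return float(-(p * np.log(p)).sum())


def select_reference_slice(echo_image: ScalarVolume) -> int:
    """Index of the slice with maximal Shannon entropy of its 64-bin histogram.

    Ties are broken toward the lowest index.  A constant slice has entropy 0.
    """
    entropies = [
        _slice_entropy(echo_image.values[:, :, z]) for z in range(echo_image.n_slices)
    ]
    return int(np.argmax(entropies))


def per_slice_cdf_normalize(
    echo_image: ScalarVolume, ref_slice: Optional[int] = None
) -> ScalarVolume:
    """Histogram-match every slice to the reference slice.

    Implements the monotone CDF-to-inverse-CDF mapping of each slice's
    intensity distribution onto the reference slice's distribution; the
    reference slice itself is unchanged up to quantization.  Preserves
    within-slice intensity rank order.
    """
    if ref_slice is None:
        ref_slice = select_reference_slice(echo_image)
    if not 0 <= ref_slice < echo_image.n_slices:
        raise ValueError(f"ref_slice {ref_slice} out of range")
    ref = echo_image.values[:, :, ref_slice]
    out = np.empty_like(echo_image.values)
    for z in range(echo_image.n_slices):
        if z == ref_slice:
            out[:, :, z] = ref
        else:
            out[:, :, z] = match_histograms(echo_image.values[:, :, z], ref)
    return echo_image.like(out)


def sum_echoes(echoes: Sequence[ScalarVolume]) -> ScalarVolume:
    """Voxelwise sum of an echo train (used as the registration image)."""
    if len(echoes) == 0:
        raise ValueError("need at least one echo")
    first = echoes[0]
    total = np.zeros_like(first.values)
    for e in echoes:
        if e.shape != first.shape:
            raise ValueError("echo shape mismatch")
        total += e.values
    return first.like(total)
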