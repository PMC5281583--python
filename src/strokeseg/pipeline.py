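"""The four chained segmentation stages and their orchestration.

Stage order (after label propagation and preprocessing):

1. whole brain on the 4th echo image,
2. contralateral ventricle on the T2 map, restricted to the contralateral
   hemisphere ``R_CBH = R_WB \\ M_IBH``,
3. both ventricles on the T2 map inside ``R_WB``, with the ventricle model
   held fixed (learned from the contralateral ventricle) and the
   edge-stopping gradient map enabled,
4. stroke on the T2 map, initialized from a voxelwise model comparison and
   restricted to the ipsilateral hemisphere with ventricles and the
   periventricular zone excluded.

All default stage weights live in :class:`~strokeseg.levelset.StageParams`
class methods.  No step ever consults ground-truth labels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from . import preprocessing as pp
from .label_propagation import SpatialTransform, propagate_labels
from .levelset import (
    StageParams,
    evolve,
    fit_gaussian_model,
    fit_histogram_model,
    gradient_map,
    log_prob_map,
)
from .volume import LabelAtlas, ScalarVolume

__all__ = [
    "SegmentationBundle",
    "stage_params_from_config",
    "segment_whole_brain",
    "segment_contralateral_ventricle",
    "segment_ventricles",
    "init_stroke_mask",
    "dense_area_filter",
    "segment_stroke",
    "run_pipeline",
]

log = logging.getLogger(__name__)

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationBundle:
    """All derived regions of one run, on the cropped grid, plus provenance."""

    r_wb: np.ndarray
    r_cbh: np.ndarray
    r_ibh: np.ndarray
    r_cv: np.ndarray
    r_v: np.ndarray
    r_s_init: np.ndarray
    r_stroke: np.ndarray
    spacing: tuple[float, float, float]
    provenance: dict = field(default_factory=dict)
    crop_report: Optional[pp.PreprocessReport] = None

    def validate(self) -> None:
        if np.any(self.r_cv & ~self.r_cbh):
            raise ValueError("R_CV must lie in R_CBH")
        if np.any(self.r_v & ~self.r_wb):
            raise ValueError("R_V must lie in R_WB")
        if np.any(self.r_stroke & ~self.r_ibh):
            raise ValueError("R_stroke must lie in R_IBH")
        if np.any(self.r_stroke & self.r_v):
            raise ValueError("R_stroke must not intersect the ventricles")

    def volumes_mm3(self) -> dict[str, float]:
        voxvol = float(np.prod(self.spacing))
        return {
            name: float(getattr(self, name).sum()) * voxvol
            for name in ("r_wb", "r_cbh", "r_ibh", "r_cv", "r_v", "r_stroke")
        }

    def stroke_on_original_grid(self) -> np.ndarray:
        """Lesion mask zero-padded back onto the uncropped input grid."""
        if self.crop_report is None:
            return self.r_stroke
        return pp.uncrop_mask(self.r_stroke, self.crop_report)


_STAGES = ("whole_brain", "contralateral_ventricle", "ventricles", "stroke")


def stage_params_from_config(config: Optional[dict]) -> dict[str, StageParams]:
    """Resolve per-stage parameters, starting from the tuned defaults.

    ``config`` maps stage names to dicts with any of the keys
    ``alpha, mu, n_iter, object_model, background_model, object_fixed,
    background_fixed, use_gradient_map, input_image``.
    """
    params = {name: getattr(StageParams, name)() for name in _STAGES}
    if not config:
        return params
    for stage, overrides in config.items():
        if stage not in params:
            raise ValueError(f"unknown stage {stage!r}")
        p = params[stage]
        for key, val in (overrides or {}).items():
            attr = {"object_model": "object_model_kind",
                    "background_model": "background_model_kind"}.get(key, key)
            if not hasattr(p, attr):
                raise ValueError(f"unknown parameter {key!r} for stage {stage!r}")
            setattr(p, attr, val)
        p.__post_init__()
    return params


# ---------------------------------------------------------------------------
# stage 1: whole brain


def _postprocess_brain(mask: np.ndarray) -> np.ndarray:
    """Per-slice hole filling and radius-2 disk opening, then the largest
    26-connected 3D component."""
    out = np.empty_like(mask)
    selem = disk(2)
    for z in range(mask.shape[2]):
        sl = ndimage.binary_fill_holes(mask[:, :, z])
        out[:, :, z] = ndimage.binary_opening(sl, structure=selem)
    labels, n = ndimage.label(out, structure=_STRUCT26)
    if n == 0:
        return out
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def segment_whole_brain(
    echo4: ScalarVolume, atlas: LabelAtlas, params: Optional[StageParams] = None
) -> np.ndarray:
    """Whole-brain mask from the (preprocessed) fourth echo image.

    The level set starts from the propagated whole-brain label and runs on
    the full grid; the result is hole-filled, opened with a radius-2 disk
    per slice, and reduced to its largest connected component.
    """
    params = params or StageParams.whole_brain()
    mask = evolve(echo4, atlas.wb, obj=None, bg=None, params=params)
    mask = _postprocess_brain(mask)
    if not mask.any():
        raise ValueError("brain-not-found")
    return mask


# ---------------------------------------------------------------------------
# stage 2: contralateral ventricle


def segment_contralateral_ventricle(
    t2: ScalarVolume,
    atlas: LabelAtlas,
    r_wb: np.ndarray,
    params: Optional[StageParams] = None,
) -> np.ndarray:
    """Contralateral ventricle from the T2 map inside ``R_CBH = R_WB \\ M_IBH``."""
    params = params or StageParams.contralateral_ventricle()
    r_cbh = r_wb & ~atlas.ibh
    init = atlas.cv & r_cbh
    if not init.any():
        raise ValueError("cv-not-found: propagated ventricle label empty in R_CBH")
    mask = evolve(t2, init, obj=None, bg=None, params=params, domain=r_cbh)
    if not mask.any():
        raise ValueError("cv-not-found")
    return mask


# ---------------------------------------------------------------------------
# stage 3: both ventricles


def segment_ventricles(
    t2: ScalarVolume,
    atlas: LabelAtlas,
    r_wb: np.ndarray,
    r_cv: np.ndarray,
    params: Optional[StageParams] = None,
) -> np.ndarray:
    """Both ventricles inside ``R_WB``.

    The ventricle (object) model is a histogram learned from the segmented
    contralateral ventricle and held fixed; the background model adapts.
    The gradient map derived from the contralateral-ventricle Gaussian
    energy keeps the contour from leaking into lesion tissue that touches
    the ventricles.  If the evolution empties, the propagated ventricle
    labels are returned as a logged fallback.
    """
    params = params or StageParams.ventricles()
    init = (atlas.iv | atlas.cv) & r_wb
    obj = fit_histogram_model(t2, r_cv, fixed=True)
    g = gradient_map(t2, r_cv) if params.use_gradient_map else None
    if not init.any():
        log.warning("ventricles: empty initialization; falling back to template labels")
        return (atlas.iv | atlas.cv) & r_wb
    mask = evolve(t2, init, obj=obj, bg=None, params=params, domain=r_wb, g=g)
    if not mask.any():
        log.warning("ventricles: empty result; falling back to template labels")
        return init
    return mask


# ---------------------------------------------------------------------------
# stage 4: stroke


def init_stroke_mask(
    t2: ScalarVolume,
    atlas: LabelAtlas,
    r_wb: np.ndarray,
    r_v: np.ndarray,
    apply_filter: bool = True,
) -> np.ndarray:
    """Voxelwise model-comparison initialization of the stroke stage.

    Histogram models are fitted on the whole brain and on the contralateral
    hemisphere, each with ventricles and the periventricular zone excluded.
    Candidate voxels are those (in the ipsilateral evolution domain) where
    the whole-brain model assigns strictly higher probability than the
    contralateral model — the lesion inflates the whole-brain histogram at
    elevated T2 but not the contralateral one.  Components without a dense
    core are then filtered out.
    """
    excl = r_v | atlas.pvz
    r_cbh = r_wb & ~atlas.ibh
    region_b = r_wb & ~excl
    region_cbh = r_cbh & ~excl
    if not region_b.any() or not region_cbh.any():
        return np.zeros_like(r_wb)
    model_b = fit_histogram_model(t2, region_b)
    model_cbh = fit_histogram_model(t2, region_cbh)
    domain = (r_wb & atlas.ibh) & ~excl
    cand = (
        log_prob_map(model_b, t2).values > log_prob_map(model_cbh, t2).values
    ) & domain
    if apply_filter:
        cand = dense_area_filter(cand)
    return cand


def _disk_offsets(radius: int = 4) -> np.ndarray:
    r = np.arange(-radius, radius + 1)
    xx, yy = np.meshgrid(r, r, indexing="ij")
    k = (xx**2 + yy**2) <= radius**2
    k[radius, radius] = False  # the voxel itself is excluded
    return k


def dense_area_filter(mask: np.ndarray, radius: int = 4, frac: float = 0.75) -> np.ndarray:
    """Keep components of ``mask`` that intersect at least one *dense* voxel.

    A mask voxel is dense when at least ``frac`` of its within-slice
    disk-of-``radius`` neighbors (the voxel itself excluded; at borders the
    fraction is taken over the in-bounds neighbors) also belong to the mask.
    Components are 26-connected in 3D.
    """
    mask = np.asarray(mask, dtype=bool)
    kernel = _disk_offsets(radius)[:, :, None]
    inside = ndimage.convolve(mask.astype(np.float64), kernel, mode="constant", cval=0.0)
    in_bounds = ndimage.convolve(
        np.ones(mask.shape), kernel, mode="constant", cval=0.0
    )
    dense = mask & (inside >= frac * in_bounds - 1e-9)
    if not dense.any():
        return np.zeros_like(mask)
    labels, n = ndimage.label(mask, structure=_STRUCT26)
    keep = np.unique(labels[dense])
    keep = keep[keep > 0]
    return np.isin(labels, keep)


def segment_stroke(
    t2: ScalarVolume,
    atlas: LabelAtlas,
    r_wb: np.ndarray,
    r_v: np.ndarray,
    r_s_init: np.ndarray,
    params: Optional[StageParams] = None,
) -> np.ndarray:
    """Final lesion mask, evolved inside ``R_IBH \\ (R_V ∪ M_PVZ)``.

    The background model is a histogram fixed to the contralateral
    hemisphere; the object (lesion) model adapts from the filtered
    initialization.  An empty initialization means no lesion is detected.
    """
    params = params or StageParams.stroke()
    excl = r_v | atlas.pvz
    domain = (r_wb & atlas.ibh) & ~excl
    init = r_s_init & domain
    if not init.any():
        log.info("no-lesion-detected: empty stroke initialization")
        return np.zeros_like(r_wb)
    r_cbh = r_wb & ~atlas.ibh
    bg = fit_histogram_model(t2, r_cbh, fixed=True)
    return evolve(t2, init, obj=None, bg=bg, params=params, domain=domain)


# ---------------------------------------------------------------------------
# orchestration


def run_pipeline(
    t2: ScalarVolume,
    echoes: Sequence[ScalarVolume],
    atlas: LabelAtlas,
    config: Optional[dict] = None,
    transform: Optional[SpatialTransform] = None,
) -> tuple[SegmentationBundle, dict]:
    """Run preprocessing and all four stages; fully deterministic.

    Parameters
    ----------
    t2 : ScalarVolume
        Quantitative T2 map (ms).
    echoes : sequence of ScalarVolume
        The multi-echo train (at least four echoes; the fourth, 1-based, is
        used for whole-brain segmentation).
    atlas : LabelAtlas
        Template labels.  If ``transform`` is given they are first
        propagated onto the subject grid, otherwise they are taken to be in
        subject space already.
    config : dict, optional
        Per-stage parameter overrides (see :func:`stage_params_from_config`).

    Returns
    -------
    bundle : SegmentationBundle
    report : dict
        Volumes (mm³) per region, stage parameters, and the crop box.
    """
    if len(echoes) < 4:
        raise ValueError("need at least 4 echoes (whole-brain stage uses the 4th)")
    params = stage_params_from_config(config)
    if transform is not None:
        atlas = propagate_labels(atlas, transform, t2.shape, t2.spacing)
    if atlas.shape != t2.shape:
        raise ValueError("atlas and T2 grids differ (missing transform?)")

    # preprocessing: crop everything to the propagated brain bbox, rescale,
    # and slice-normalize the echo used for segmentation
    t2c, crop = pp.crop_to_label_bbox(t2, atlas.wb)
    atlas_c = atlas.map_masks(lambda m: m[crop.slices()])
    echo4 = pp.apply_crop(echoes[3], crop)
    echo4 = pp.rescale_unit(echo4)
    ref = pp.select_reference_slice(echo4)
    echo4 = pp.per_slice_cdf_normalize(echo4, ref)
    echo4 = pp.rescale_unit(echo4)
    lo, hi = float(t2c.values.min()), float(t2c.values.max())
    t2u = pp.rescale_unit(t2c)
    crop.intensity_min, crop.intensity_max, crop.reference_slice = lo, hi, ref

    try:
        r_wb = segment_whole_brain(echo4, atlas_c, params["whole_brain"])
    except ValueError as err:
        raise RuntimeError(f"whole-brain stage failed: {err}") from err
    try:
        r_cv = segment_contralateral_ventricle(
            t2u, atlas_c, r_wb, params["contralateral_ventricle"]
        )
    except ValueError as err:
        raise RuntimeError(f"contralateral-ventricle stage failed: {err}") from err
    r_v = segment_ventricles(t2u, atlas_c, r_wb, r_cv, params["ventricles"])
    r_s_init = init_stroke_mask(t2u, atlas_c, r_wb, r_v)
    r_stroke = segment_stroke(t2u, atlas_c, r_wb, r_v, r_s_init, params["stroke"])

    bundle = SegmentationBundle(
        r_wb=r_wb,
        r_cbh=r_wb & ~atlas_c.ibh,
        r_ibh=r_wb & atlas_c.ibh,
        r_cv=r_cv,
        r_v=r_v,
        r_s_init=r_s_init,
        r_stroke=r_stroke,
        spacing=t2.spacing,
        crop_report=crop,
        provenance={name: vars(p).copy() for name, p in params.items()},
    )
    bundle.validate()
    report = {
        "volumes_mm3": bundle.volumes_mm3(),
        "lesion_volume_mm3": bundle.volumes_mm3()["r_stroke"],
        "crop_box": list(crop.crop_box),
        "reference_slice": ref,
        "stage_params": bundle.provenance,
    }
    return bundle, report
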