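"""Region-based level-set engine (Chan–Vese / Rousson–Deriche energy).

A level set ``phi`` partitions the image domain into object
``{phi >= 0}`` and background ``{phi < 0}``.  It is evolved to minimize

    E(phi) = alpha * g(x) * Length(dOmega_O) + mu * Area(Omega_O)
             - sum_{Omega_O} log P(I(x); Omega_O)
             - sum_{Omega_B} log P(I(x); Omega_B)

where the region likelihoods ``P`` are either Gaussian or histogram models
estimated from the current partition (or held fixed), and ``g`` is an
optional edge-stopping weight on the perimeter term.

Numerical scheme
----------------
Explicit gradient descent with a CFL-bounded time step.  The curvature
(perimeter) force is gated by a smoothed Dirac delta of ``phi`` as in
Chan–Vese; the data and area forces act on every domain voxel so that a
voxel's sign flips exactly when flipping lowers the partition energy.
``phi`` is maintained as an (approximate) signed distance function,
re-initialized at a fixed interval.  Evolution can be restricted to an
arbitrary domain mask; voxels outside it are never touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import ndimage

from .volume import ScalarVolume

__all__ = [
    "SD_FLOOR",
    "HIST_EPS",
    "GaussianModel",
    "HistogramModel",
    "RegionModel",
    "StageParams",
    "LevelSetState",
    "fit_gaussian_model",
    "fit_histogram_model",
    "log_prob_map",
    "gradient_map",
    "energy",
    "evolve",
    "signed_distance",
]

#: floor on the Gaussian standard deviation (in units of the unit intensity
#: range) so degenerate regions never produce infinite log-densities
SD_FLOOR = 1e-3
#: probability-mass floor per histogram bin (re-normalized after flooring)
HIST_EPS = 1e-8
#: default number of equal-width histogram bins over the unit range
DEFAULT_BINS = 64
#: width of the smoothed Dirac delta (voxels)
DIRAC_EPS = 1.5
#: CFL-like bound on the explicit time step
CFL = 0.45
#: cap on |phi| (voxels) applied at (re)initialization; keeps every voxel
#: within a few data-force steps of a sign change instead of stranding far
#: voxels at large distances
PHI_CAP = 3.0


# ---------------------------------------------------------------------------
# region models


@dataclass(frozen=True)
class GaussianModel:
    """Maximum-likelihood Gaussian intensity model of a region."""

    mean: float
    sd: float
    fixed: bool = False

    def __post_init__(self) -> None:
        if not (self.sd >= SD_FLOOR):
            raise ValueError(f"sd {self.sd} below floor {SD_FLOOR}")

    @property
    def kind(self) -> str:
        return "gaussian"

    def log_prob(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=np.float64)
        return -0.5 * ((v - self.mean) / self.sd) ** 2 - np.log(
            self.sd * np.sqrt(2.0 * np.pi)
        )


@dataclass(frozen=True)
class HistogramModel:
    """Piecewise-constant (histogram) intensity model of a region.

    ``edges`` are ``n_bins + 1`` increasing bin edges; ``mass`` sums to one.
    Queries outside the stated range are clamped to the boundary bins, so the
    log-probability is finite everywhere.
    """

    edges: np.ndarray
    mass: np.ndarray
    fixed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", np.asarray(self.edges, dtype=np.float64))
        object.__setattr__(self, "mass", np.asarray(self.mass, dtype=np.float64))
        if self.edges.ndim != 1 or self.edges.size != self.mass.size + 1:
            raise ValueError("edges must have len(mass)+1 entries")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if np.any(self.mass < HIST_EPS * 0.5) or abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("mass must be floored and sum to 1")

    @property
    def kind(self) -> str:
        return "histogram"

    @property
    def n_bins(self) -> int:
        return self.mass.size

    def log_prob(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=np.float64)
        idx = np.searchsorted(self.edges, v, side="right") - 1
        idx = np.clip(idx, 0, self.n_bins - 1)
        return np.log(self.mass[idx])


RegionModel = Union[GaussianModel, HistogramModel]


def fit_gaussian_model(
    image: ScalarVolume, region: np.ndarray, fixed: bool = False
) -> GaussianModel:
    """ML Gaussian fit (divide-by-n variance) of the intensities in ``region``.

    The standard deviation is clamped from below at :data:`SD_FLOOR`.
    """
    region = np.asarray(region, dtype=bool)
    vals = image.values[region]
    if vals.size == 0:
        raise ValueError("empty-region-model")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=0))
    return GaussianModel(mean=mean, sd=max(sd, SD_FLOOR), fixed=fixed)


def fit_histogram_model(
    image: ScalarVolume,
    region: np.ndarray,
    n_bins: int = DEFAULT_BINS,
    value_range: tuple[float, float] = (0.0, 1.0),
    fixed: bool = False,
) -> HistogramModel:
    """Equal-width-bin histogram fit over ``value_range`` of the region.

    Per-bin mass is count/total, floored at :data:`HIST_EPS` and renormalized.
    """
    region = np.asarray(region, dtype=bool)
    vals = image.values[region]
    if vals.size == 0:
        raise ValueError("empty-region-model")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = value_range
    if not hi > lo:
        raise ValueError("invalid value_range")
    counts, edges = np.histogram(np.clip(vals, lo, hi), bins=n_bins, range=(lo, hi))
    mass = counts / counts.sum()
    mass = np.maximum(mass, HIST_EPS)
    mass = mass / mass.sum()
    return HistogramModel(edges=edges, mass=mass, fixed=fixed)


def log_prob_map(model: RegionModel, image: ScalarVolume) -> ScalarVolume:
    """Voxelwise ``log P(I(x))`` under a region model; finite everywhere."""
    return image.like(model.log_prob(image.values))


def gradient_map(image: ScalarVolume, cv_region: np.ndarray) -> ScalarVolume:
    """Edge-stopping weight derived from the contralateral-ventricle model.

    A Gaussian model is fitted on ``cv_region``; its negative log-density
    ``e_v(x)`` is min–max scaled over the whole volume to [0, 1] and the map
    is ``g = 1 - e_v(x)^2``.  Voxels that look like ventricle (low energy)
    get ``g ≈ 1`` (full perimeter smoothing), dissimilar voxels get ``g ≈ 0``,
    which stops the contour there.  A constant image yields ``g ≡ 1``.
    """
    model = fit_gaussian_model(image, cv_region)
    e = -model.log_prob(image.values)
    lo, hi = float(e.min()), float(e.max())
    if hi - lo <= 0.0:
        return image.like(np.ones_like(e))
    e = (e - lo) / (hi - lo)
    return image.like(1.0 - e**2)


# ---------------------------------------------------------------------------
# stage parameters (one per segmentation stage)


@dataclass
class StageParams:
    """Weights and model choices of one segmentation stage."""

    input_image: str = "t2map"  # {"echo4", "t2map"}
    object_model_kind: str = "gaussian"  # {"gaussian", "histogram"}
    background_model_kind: str = "gaussian"
    object_fixed: bool = False
    background_fixed: bool = False
    alpha: float = 0.0
    mu: float = 0.0
    n_iter: int = 80
    use_gradient_map: bool = False

    def __post_init__(self) -> None:
        if self.input_image not in ("echo4", "t2map"):
            raise ValueError(f"unknown input_image {self.input_image!r}")
        for kind in (self.object_model_kind, self.background_model_kind):
            if kind not in ("gaussian", "histogram"):
                raise ValueError(f"unknown model kind {kind!r}")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")

    # default parameter columns of the four stages
    @classmethod
    def whole_brain(cls) -> "StageParams":
        return cls(
            input_image="echo4",
            object_model_kind="gaussian",
            background_model_kind="gaussian",
            alpha=5.0,
            mu=2.0,
            n_iter=80,
        )

    @classmethod
    def contralateral_ventricle(cls) -> "StageParams":
        return cls(
            input_image="t2map",
            object_model_kind="gaussian",
            background_model_kind="gaussian",
            alpha=0.1,
            mu=0.0,
            n_iter=120,
        )

    @classmethod
    def ventricles(cls) -> "StageParams":
        return cls(
            input_image="t2map",
            object_model_kind="histogram",
            background_model_kind="histogram",
            object_fixed=True,
            alpha=2.0,
            mu=1.5,
            n_iter=120,
            use_gradient_map=True,
        )

    @classmethod
    def stroke(cls) -> "StageParams":
        return cls(
            input_image="t2map",
            object_model_kind="histogram",
            background_model_kind="histogram",
            background_fixed=True,
            alpha=0.3,
            mu=0.0,
            n_iter=80,
        )


@dataclass
class LevelSetState:
    """Evolution state: the level-set field, its domain, and iteration count."""

    phi: np.ndarray
    domain_mask: np.ndarray
    iteration: int = 0

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=np.float64)
        self.domain_mask = np.asarray(self.domain_mask, dtype=bool)
        if self.phi.shape != self.domain_mask.shape:
            raise ValueError("phi and domain_mask shapes differ")
        if not np.all(np.isfinite(self.phi)):
            raise ValueError("phi must be finite")

    @property
    def object_mask(self) -> np.ndarray:
        """Object = {phi >= 0} (ties count as object) within the domain."""
        return (self.phi >= 0.0) & self.domain_mask


# ---------------------------------------------------------------------------
# energy bookkeeping


def _boundary_faces(mask: np.ndarray, domain: np.ndarray):
    """Yield, per axis, the face pairs between object and background voxels.

    Only faces whose two incident voxels both lie inside ``domain`` are
    counted (the grid boundary itself contributes no perimeter).
    """
    for axis in range(3):
        a = [slice(None)] * 3
        b = [slice(None)] * 3
        a[axis] = slice(None, -1)
        b[axis] = slice(1, None)
        a, b = tuple(a), tuple(b)
        both = domain[a] & domain[b]
        faces = both & (mask[a] != mask[b])
        yield a, b, faces


def _weighted_perimeter(
    mask: np.ndarray, domain: np.ndarray, g: Optional[np.ndarray]
) -> float:
    total = 0.0
    for a, b, faces in _boundary_faces(mask, domain):
        if g is None:
            total += float(faces.sum())
        else:
            w = 0.5 * (g[a] + g[b])
            total += float(w[faces].sum())
    return total


def energy(
    state: LevelSetState,
    image: ScalarVolume,
    obj: RegionModel,
    bg: RegionModel,
    params: StageParams,
    g: Optional[ScalarVolume] = None,
) -> float:
    """Evaluate the segmentation energy of the current partition.

    Length is the (optionally ``g``-weighted) count of object/background
    voxel-face pairs; Area is the object voxel count; both in voxel units.
    Data terms are sums of ``-log P`` over the object and background parts of
    the evolution domain.
    """
    if state.phi.shape != image.values.shape:
        raise ValueError("state and image shapes differ")
    domain = state.domain_mask
    obj_mask = (state.phi >= 0.0) & domain
    bg_mask = domain & ~obj_mask
    g_arr = None if g is None else g.values
    e = params.alpha * _weighted_perimeter(obj_mask, domain, g_arr)
    e += params.mu * float(obj_mask.sum())
    vals = image.values
    e -= float(obj.log_prob(vals[obj_mask]).sum())
    e -= float(bg.log_prob(vals[bg_mask]).sum())
    return e


# ---------------------------------------------------------------------------
# evolution


def signed_distance(mask: np.ndarray) -> np.ndarray:
    """Signed Euclidean distance (voxel units): positive inside the mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.all():
        return np.ones(mask.shape)
    if not mask.any():
        return -np.ones(mask.shape)
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    return inside - outside


def _dirac(phi: np.ndarray, eps: float = DIRAC_EPS) -> np.ndarray:
    return eps / (np.pi * (eps**2 + phi**2))


def _curvature(phi: np.ndarray) -> np.ndarray:
    """Mean curvature div(grad phi / |grad phi|); singleton axes are skipped."""
    axes = [ax for ax in range(3) if phi.shape[ax] > 1]
    grads = np.gradient(phi, axis=axes) if len(axes) > 1 else [np.gradient(phi, axis=axes[0])]
    norm = np.sqrt(sum(gr**2 for gr in grads)) + 1e-8
    kappa = np.zeros_like(phi)
    for gr, ax in zip(grads, axes):
        kappa += np.gradient(gr / norm, axis=ax)
    return kappa


def _maybe_refit(
    model: Optional[RegionModel],
    kind: str,
    fixed: bool,
    image: ScalarVolume,
    region: np.ndarray,
) -> Optional[RegionModel]:
    """Re-estimate an adaptive model from ``region``; keep the old one if the
    region is empty (the evolution may transiently empty a side)."""
    if model is not None and (fixed or getattr(model, "fixed", False)):
        return model
    if not region.any():
        return model
    if kind == "gaussian":
        return fit_gaussian_model(image, region)
    return fit_histogram_model(image, region)


def evolve(
    image: ScalarVolume,
    phi0: np.ndarray,
    obj: Optional[RegionModel],
    bg: Optional[RegionModel],
    params: StageParams,
    domain: Optional[np.ndarray] = None,
    g: Optional[ScalarVolume] = None,
    reinit_interval: int = 20,
    stop_frac: float = 1e-4,
    return_state: bool = False,
):
    """Evolve the level set for at most ``params.n_iter`` iterations.

    Parameters
    ----------
    phi0 : boolean mask or signed field
        Initialization; a boolean mask is converted to a signed distance.
        Its object part is intersected with ``domain``.
    obj, bg : RegionModel or None
        Initial region models.  ``None`` means "estimate from the initial
        partition" with the kind given by ``params``.  Non-fixed models are
        re-estimated from the current partition every iteration.
    domain : boolean mask, optional
        Voxels allowed to evolve; ``phi`` is frozen outside it.
    g : ScalarVolume, optional
        Edge-stopping weight for the perimeter force (used when
        ``params.use_gradient_map``); ``None`` is equivalent to ``g ≡ 1``.

    Returns
    -------
    mask : boolean ndarray
        Final object mask ``{phi >= 0} ∩ domain``.  Deterministic.
    """
    vals = image.values
    if domain is None:
        domain = np.ones(vals.shape, dtype=bool)
    else:
        domain = np.asarray(domain, dtype=bool)
        if domain.shape != vals.shape:
            raise ValueError("domain shape mismatch")
    phi0 = np.asarray(phi0)
    if phi0.shape != vals.shape:
        raise ValueError("phi0 shape mismatch")
    init_mask = (phi0 >= 0.0) if phi0.dtype != bool else phi0
    init_mask = init_mask & domain
    if not init_mask.any():
        raise ValueError("empty-initialization")

    phi = np.clip(signed_distance(init_mask), -PHI_CAP, PHI_CAP)
    obj = _maybe_refit(obj, params.object_model_kind, params.object_fixed, image, init_mask)
    bg_region0 = domain & ~init_mask
    bg = _maybe_refit(bg, params.background_model_kind, params.background_fixed, image, bg_region0)
    if obj is None or bg is None:
        raise ValueError("cannot estimate region models: a side of the partition is empty")

    g_arr = g.values if (g is not None and params.use_gradient_map) else None
    n_domain = int(domain.sum())
    mask = init_mask
    it = 0
    for it in range(1, params.n_iter + 1):
        obj = _maybe_refit(obj, params.object_model_kind, params.object_fixed, image, mask)
        bg = _maybe_refit(
            bg, params.background_model_kind, params.background_fixed, image, domain & ~mask
        )
        force = obj.log_prob(vals) - bg.log_prob(vals) - params.mu
        if params.alpha > 0.0:
            kappa = _curvature(phi)
            curv = params.alpha * _dirac(phi) * kappa
            if g_arr is not None:
                curv = curv * g_arr
            force = force + curv
        fmax = float(np.abs(force[domain]).max())
        if fmax == 0.0:
            break
        dt = CFL / fmax
        phi_new = phi + dt * force
        phi = np.where(domain, phi_new, phi)
        new_mask = (phi >= 0.0) & domain
        changed = int((new_mask != mask).sum())
        mask = new_mask
        if it % reinit_interval == 0:
            sd = np.clip(signed_distance(mask | ((phi >= 0.0) & ~domain)), -PHI_CAP, PHI_CAP)
            phi = np.where(domain, sd, phi)
        # the change-based criterion is only meaningful once the front has had
        # time to move (no voxel can flip during the first few CFL-bounded
        # steps from a fresh signed distance), so it is armed after the first
        # reinitialization interval
        if it >= reinit_interval and changed < stop_frac * n_domain:
            break

    if return_state:
        return mask, LevelSetState(phi=phi, domain_mask=domain, iteration=it)
    return mask
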