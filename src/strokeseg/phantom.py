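"""Deterministic synthetic mouse-brain phantoms.

Each phantom is an ellipsoidal "brain" split by a midline plane into
hemispheres, with a curved ventricle pair, an optional ischemic lesion in
the ipsilateral hemisphere, per-tissue T2 values (ms) with Gaussian texture
plus additive noise, a matching multi-echo train synthesized from the T2
map, a ground-truth label atlas, and a template atlas that is optionally
warped by a small smooth random deformation to emulate imperfect label
propagation.

Default geometry and echo train mirror a typical 7 T MSME mouse protocol
(0.12 x 0.12 x 0.50 mm voxels, 16 slices, TE 9 ms, 20 echoes).  Default
tissue T2 values (healthy ~40 ms, CSF ~90 ms, lesion ~65 ms) are chosen so
the lesion and ventricle distributions partially overlap — the confound the
segmentation method is designed around — and are configuration, not claims
about mouse physiology.

Lesion archetypes: ``striatal`` (one deep blob), ``corticostriatal`` (a
larger blob extending into cortex), ``fragmented`` (two disjoint blobs),
``large-edema`` (a large lesion engulfing the ipsilateral ventricle), and
``none``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
from scipy import ndimage

from .volume import LabelAtlas, ScalarVolume

__all__ = [
    "PhantomSpec",
    "PhantomData",
    "generate_phantom",
    "synthesize_echoes",
    "phantom_with_echoes",
]

ARCHETYPES = ("striatal", "corticostriatal", "fragmented", "large-edema", "none")


@dataclass
class PhantomSpec:
    """Parameters of a synthetic phantom; same seed => identical outputs."""

    shape: tuple[int, int, int] = (96, 96, 16)
    spacing: tuple[float, float, float] = (0.12, 0.12, 0.50)
    t2_healthy: tuple[float, float] = (40.0, 3.0)  # (mean ms, texture sd ms)
    t2_ventricle: tuple[float, float] = (90.0, 8.0)
    t2_lesion: tuple[float, float] = (65.0, 6.0)
    t2_background: tuple[float, float] = (15.0, 4.0)
    archetype: str = "corticostriatal"
    lesion_volume_mm3: float = 40.0
    noise_sd: float = 2.0  # additive noise on the T2 map, ms
    te_ms: float = 9.0
    n_echoes: int = 20
    echo_noise_sd: float = 0.02  # additive noise on echo images, PD units
    seed: int = 0
    perfect_labels: bool = False
    template_perturb_voxels: float = 2.0

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        for pair in (self.t2_healthy, self.t2_ventricle, self.t2_lesion, self.t2_background):
            if pair[1] < 0:
                raise ValueError("texture sd must be >= 0")
        if self.noise_sd < 0 or self.echo_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class PhantomData:
    """Everything one phantom provides."""

    t2: ScalarVolume
    pd: ScalarVolume
    truth_atlas: LabelAtlas
    truth_lesion: np.ndarray
    template_atlas: LabelAtlas
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# geometry helpers (all in voxel coordinates)


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = np.zeros(shape)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _tube(shape, points, r_xy: float, r_z: float) -> np.ndarray:
    """Union of anisotropic ellipsoids along a sampled centerline."""
    mask = np.zeros(shape, dtype=bool)
    for p in points:
        mask |= _ellipsoid(shape, p, (r_xy, r_xy, r_z))
    return mask


def _ventricle_pair(shape, center):
    cx, cy, cz = center
    u = np.linspace(0.0, 1.0, 40)
    masks = []
    for s in (+1.0, -1.0):  # +1 ipsilateral, -1 contralateral
        pts = np.stack(
            [
                cx + s * (shape[0] * (0.07 + 0.06 * u)),
                cy - shape[1] * 0.19 + shape[1] * 0.38 * u,
                cz + 1.2 * np.sin(np.pi * u) - 0.4,
            ],
            axis=1,
        )
        masks.append(_tube(shape, pts, r_xy=2.3, r_z=1.35))
    return masks  # [ipsilateral, contralateral]


def _scaled_blob(shape, center, ratios, scale) -> np.ndarray:
    return _ellipsoid(shape, center, tuple(r * scale for r in ratios))


def _fit_volume(build, target_voxels: float, allowed: np.ndarray, tol: float = 0.01):
    """Bisect a scale factor so that |build(s) & allowed| hits the target."""
    lo, hi = 0.2, 60.0
    if (build(hi) & allowed).sum() < target_voxels:
        raise ValueError("infeasible lesion volume for this hemisphere")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        count = (build(mid) & allowed).sum()
        if abs(count - target_voxels) <= tol * target_voxels:
            return build(mid) & allowed
        if count < target_voxels:
            lo = mid
        else:
            hi = mid
    return build(0.5 * (lo + hi)) & allowed


def _lesion_mask(spec: PhantomSpec, atlas: LabelAtlas, center) -> np.ndarray:
    shape = spec.shape
    cx, cy, cz = center
    voxvol = float(np.prod(spec.spacing))
    target = spec.lesion_volume_mm3 / voxvol
    if spec.archetype == "none" or target <= 0:
        return np.zeros(shape, dtype=bool)
    allowed = atlas.ibh & ~atlas.iv
    nx, ny, nz = shape
    if spec.archetype == "striatal":
        c = (cx + 0.18 * nx, cy - 0.04 * ny, cz)
        return _fit_volume(lambda s: _scaled_blob(shape, c, (1.2, 1.0, 0.30), s), target, allowed)
    if spec.archetype == "corticostriatal":
        c = (cx + 0.24 * nx, cy, cz)
        return _fit_volume(lambda s: _scaled_blob(shape, c, (1.1, 1.5, 0.36), s), target, allowed)
    if spec.archetype == "large-edema":
        c = (cx + 0.11 * nx, cy, cz)  # engulfs the ipsilateral ventricle
        return _fit_volume(lambda s: _scaled_blob(shape, c, (1.1, 1.6, 0.40), s), target, allowed)
    # fragmented: two disjoint blobs, half the target volume each
    c1 = (cx + 0.17 * nx, cy - 0.22 * ny, cz - 0.09 * nz)
    c2 = (cx + 0.21 * nx, cy + 0.22 * ny, cz + 0.09 * nz)
    b1 = _fit_volume(lambda s: _scaled_blob(shape, c1, (1.1, 1.0, 0.32), s), target / 2, allowed)
    b2 = _fit_volume(lambda s: _scaled_blob(shape, c2, (1.0, 1.1, 0.32), s), target / 2, allowed)
    if (b1 & b2).any():
        raise ValueError("infeasible lesion volume: fragments merged")
    return b1 | b2


def _smooth_warp(atlas: LabelAtlas, amplitude: float, rng) -> LabelAtlas:
    """Warp all masks by one smooth random displacement (max `amplitude` voxels)."""
    shape = atlas.shape
    disp = []
    for ax in range(3):
        d = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=(6, 6, 2))
        peak = np.abs(d).max()
        amp = amplitude if ax < 2 else amplitude / 2.0  # slices are thick
        disp.append(d / peak * amp if peak > 0 else d)
    idx = np.indices(shape, dtype=np.float64)
    coords = [idx[ax] + disp[ax] for ax in range(3)]

    def warp(mask: np.ndarray) -> np.ndarray:
        return (
            ndimage.map_coordinates(
                mask.astype(np.uint8), coords, order=0, mode="constant", cval=0
            )
            > 0
        )

    out = atlas.map_masks(warp)
    out.spacing = atlas.spacing
    return out.conformed()


# ---------------------------------------------------------------------------
# main entry points


def generate_phantom(spec: PhantomSpec) -> PhantomData:
    """Build a phantom: T2 map, PD map, truth labels + lesion, template labels."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    nx, ny, nz = shape
    center = ((nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0)
    cx = center[0]

    brain = _ellipsoid(shape, center, (0.40 * nx, 0.44 * ny, 0.47 * nz))
    xs = np.arange(nx)[:, None, None]
    ibh = brain & (xs > cx)
    cbh = brain & (xs < cx)
    iv, cv = _ventricle_pair(shape, center)
    iv &= ibh
    cv &= cbh
    ventricles = iv | cv
    pvz = np.zeros(shape, dtype=bool)
    for z in range(nz):
        pvz[:, :, z] = ndimage.binary_dilation(ventricles[:, :, z], iterations=3)
    pvz = pvz & brain & ~ventricles

    truth = LabelAtlas(wb=brain, ibh=ibh, cbh=cbh, iv=iv, cv=cv, pvz=pvz, spacing=spec.spacing)
    truth.validate()
    lesion = _lesion_mask(spec, truth, center) & ~ventricles

    # tissue T2 with per-tissue Gaussian texture, then additive noise
    t2 = np.empty(shape)
    texture = rng.standard_normal(shape)
    for mask, (mean, sd) in (
        (~brain, spec.t2_background),
        (brain, spec.t2_healthy),
        (lesion, spec.t2_lesion),
        (ventricles, spec.t2_ventricle),
    ):
        t2[mask] = mean + sd * texture[mask]
    if spec.noise_sd > 0:
        t2 = t2 + spec.noise_sd * rng.standard_normal(shape)
    t2 = np.maximum(t2, 1.0)

    pd = np.where(brain, 1.0, 0.15)

    if spec.perfect_labels or spec.template_perturb_voxels <= 0:
        template = truth.copy()
    else:
        template = _smooth_warp(truth, spec.template_perturb_voxels, rng)

    return PhantomData(
        t2=ScalarVolume(t2, spec.spacing),
        pd=ScalarVolume(pd, spec.spacing),
        truth_atlas=truth,
        truth_lesion=lesion,
        template_atlas=template,
        spec=spec,
    )


def synthesize_echoes(
    t2: ScalarVolume,
    pd: ScalarVolume,
    te_ms: float = 9.0,
    n_echoes: int = 20,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> list[ScalarVolume]:
    """Multi-echo train from a T2 map: echo n (1-based) = PD * exp(-n*TE/T2).

    Additive Gaussian noise of ``noise_sd`` (PD units) is applied per echo.
    Raises if T2 is non-positive anywhere tissue is present (PD > 0).
    """
    if t2.shape != pd.shape:
        raise ValueError("T2 and PD grids differ")
    if np.any((pd.values > 0) & (t2.values <= 0)):
        raise ValueError("non-positive T2 inside tissue")
    if rng is None:
        rng = np.random.default_rng(0)
    t2safe = np.maximum(t2.values, 1e-6)
    echoes = []
    for n in range(1, n_echoes + 1):
        signal = pd.values * np.exp(-n * te_ms / t2safe)
        if noise_sd > 0:
            signal = signal + noise_sd * rng.standard_normal(signal.shape)
        echoes.append(t2.like(signal))
    return echoes


def phantom_with_echoes(spec: PhantomSpec) -> tuple[PhantomData, list[ScalarVolume]]:
    """Convenience: phantom plus its echo train (noise seeded from the spec)."""
    data = generate_phantom(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    echoes = synthesize_echoes(
        data.t2, data.pd, spec.te_ms, spec.n_echoes, spec.echo_noise_sd, rng
    )
    return data, echoes
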