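"""Core in-memory containers: scalar volumes and anatomical label atlases.

Axis convention: arrays are indexed ``(x, y, z)`` with ``z`` the slice index
(0-based).  Spacing is ``(dx, dy, dz)`` in mm.  In-plane resolution of mouse
brain MSME scans is much finer than the slice thickness (e.g. 0.12 mm vs
0.5 mm), which is why several morphological steps downstream operate per
slice in 2D.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np

__all__ = ["ScalarVolume", "LabelAtlas"]


@dataclass
class ScalarVolume:
    """A 3D scalar image (quantitative T2 map in ms, or echo image in a.u.).

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Finite voxel values.
    spacing : tuple of float
        Voxel size ``(dx, dy, dz)`` in mm, strictly positive.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if any(s < m for s, m in zip(self.values.shape, (2, 2, 1))):
            raise ValueError(f"volume too small: shape={self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_slices(self) -> int:
        return self.values.shape[2]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz

    def like(self, values: np.ndarray) -> "ScalarVolume":
        """A new volume on the same grid with different values."""
        return ScalarVolume(np.asarray(values, dtype=np.float64), self.spacing)

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.values.copy(), self.spacing)


def _as_bool(mask: np.ndarray, shape: tuple[int, int, int], name: str) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tuple(shape):
        raise ValueError(f"{name}: shape {mask.shape} != grid {tuple(shape)}")
    return mask


@dataclass
class LabelAtlas:
    """The six anatomical template/propagated masks on one grid.

    ``wb`` whole brain, ``ibh``/``cbh`` ipsi-/contralateral brain hemisphere,
    ``iv``/``cv`` ipsi-/contralateral ventricle, ``pvz`` periventricular zone.

    Invariants (checked by :meth:`validate`, enforceable by :meth:`conformed`):
    ``ibh | cbh ⊆ wb``, ``ibh ∩ cbh = ∅``, ``iv ⊆ ibh``, ``cv ⊆ cbh``.
    """

    wb: np.ndarray
    ibh: np.ndarray
    cbh: np.ndarray
    iv: np.ndarray
    cv: np.ndarray
    pvz: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    _FIELDS = ("wb", "ibh", "cbh", "iv", "cv", "pvz")

    def __post_init__(self) -> None:
        shape = np.asarray(self.wb).shape
        for name in self._FIELDS:
            setattr(self, name, _as_bool(getattr(self, name), shape, name))
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.wb.shape

    def masks(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self._FIELDS}

    def validate(self) -> None:
        """Raise ValueError if any hemisphere/ventricle containment is violated."""
        if np.any((self.ibh | self.cbh) & ~self.wb):
            raise ValueError("hemispheres must lie within the whole brain")
        if np.any(self.ibh & self.cbh):
            raise ValueError("hemispheres must be disjoint")
        if np.any(self.iv & ~self.ibh):
            raise ValueError("ipsilateral ventricle must lie in ipsilateral hemisphere")
        if np.any(self.cv & ~self.cbh):
            raise ValueError("contralateral ventricle must lie in contralateral hemisphere")

    def conformed(self) -> "LabelAtlas":
        """Return a copy with the containment invariants enforced by masking.

        Used after nearest-neighbor warping, which can violate containment at
        region boundaries.
        """
        wb = self.wb.copy()
        ibh = self.ibh & wb
        cbh = self.cbh & wb & ~ibh
        return LabelAtlas(
            wb=wb,
            ibh=ibh,
            cbh=cbh,
            iv=self.iv & ibh,
            cv=self.cv & cbh,
            pvz=self.pvz.copy(),
            spacing=self.spacing,
        )

    def map_masks(self, fn) -> "LabelAtlas":
        """Apply ``fn`` to every mask (e.g. cropping); returns a new atlas."""
        return LabelAtlas(
            **{name: fn(getattr(self, name)) for name in self._FIELDS},
            spacing=self.spacing,
        )

    def copy(self) -> "LabelAtlas":
        return self.map_masks(np.copy)
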