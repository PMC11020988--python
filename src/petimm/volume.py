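"""3D SUV volumes and volume-of-interest masks.

A volume is a 3D grid of standardized uptake values (SUV, unitless,
body-weight normalized) with anisotropic voxel spacing in mm.  World
coordinates are in mm; voxel indices are 0-based, and the world position of
index ``i`` along an axis is ``origin + i * spacing`` — i.e. a voxel's
position is its center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["SUVVolume", "VOIMask", "sphere_mask"]


@dataclass
class SUVVolume:
    """A 3D grid of SUVs with voxel spacing and origin in mm.

    Parameters
    ----------
    values
        3D float array, non-negative and finite.
    voxel_spacing_mm
        Strictly positive spacing per axis ``(dx, dy, dz)``.
    origin_mm
        World position of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.values.shape}")
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError(f"voxel spacing must be strictly positive, got {self.voxel_spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("SUV values must be finite")
        if np.any(self.values < 0):
            raise ValueError("SUV values must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_spacing_mm
        return dx * dy * dz

    def world_to_index(self, point_mm) -> tuple[int, int, int]:
        """Nearest voxel index of a world point (mm)."""
        idx = np.rint(
            (np.asarray(point_mm, dtype=float) - np.asarray(self.origin_mm))
            / np.asarray(self.voxel_spacing_mm)
        ).astype(int)
        return tuple(int(i) for i in idx)

    def index_to_world(self, index) -> np.ndarray:
        return np.asarray(self.origin_mm) + np.asarray(index, dtype=float) * np.asarray(
            self.voxel_spacing_mm
        )

    def contains_index(self, index) -> bool:
        return all(0 <= i < n for i, n in zip(index, self.shape))

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers (open grids, broadcastable)."""
        grids = np.ogrid[0 : self.shape[0], 0 : self.shape[1], 0 : self.shape[2]]
        return tuple(
            o + g * s for g, s, o in zip(grids, self.voxel_spacing_mm, self.origin_mm)
        )

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.values.astype(np.float32), self.affine())

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "SUVVolume":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
        origin = tuple(float(x) for x in aff[:3, 3])
        return cls(np.asarray(img.dataobj, dtype=float), spacing, origin)


@dataclass
class VOIMask:
    """A binary region on the same grid as its paired :class:`SUVVolume`."""

    values: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.values.shape}")
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_count(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.voxel_spacing_mm
        return dx * dy * dz

    @property
    def volume_cm3(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3 / 1000.0

    def check_aligned(self, volume: SUVVolume) -> None:
        if self.shape != volume.shape:
            raise ValueError(
                f"mask shape {self.shape} does not match volume shape {volume.shape}"
            )

    def save(self, path) -> None:
        aff = np.diag(list(self.voxel_spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(self.values.astype(np.uint8), aff), str(path))

    @classmethod
    def load(cls, path, label: str = "") -> "VOIMask":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
        origin = tuple(float(x) for x in aff[:3, 3])
        return cls(np.asarray(img.dataobj) > 0, spacing, origin, label=label)


def sphere_mask(volume: SUVVolume, center_mm, radius_mm: float, label: str = "") -> VOIMask:
    """Boolean mask of voxels whose centers lie within a sphere.

    Membership is by voxel-center inclusion (``distance <= radius``); no
    partial-volume weighting.
    """
    if radius_mm <= 0:
        raise ValueError("radius must be positive")
    cx, cy, cz = (float(c) for c in center_mm)
    gx, gy, gz = volume.voxel_centers_mm()
    d2 = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2
    return VOIMask(d2 <= radius_mm**2, volume.voxel_spacing_mm, volume.origin_mm, label=label)
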