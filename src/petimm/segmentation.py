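"""Tumor delineation by Nestle's adaptive threshold, plus grid resampling.

The adaptive threshold is

    T = w * mean{ SUV in tumor core } + mean SUV of background,

where the core is the set of tumor voxels strictly above ``core_fraction``
(default 70%) of the tumor's maximum SUV and ``w`` defaults to 0.3.  The
formula is self-referential — the threshold defines the tumor that defines
the core — so delineation runs it as a fixed-point iteration from a
seed-anchored initial estimate until the mask stabilizes.

The background mean is taken over a shell at 8–16 mm from the current tumor
estimate (excluding any supplied organ masks), or over an explicit
caller-supplied background mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import SUVVolume, VOIMask

__all__ = [
    "SegmentationConfig",
    "DelineationResult",
    "resample_to_analysis_grid",
    "nestle_threshold",
    "delineate_tumor",
    "ANALYSIS_SPACING_MM",
]

#: Analysis grid spacing (mm) used for all feature extraction.
ANALYSIS_SPACING_MM = (4.07, 4.07, 2.5)


@dataclass
class SegmentationConfig:
    """Knobs of the adaptive-threshold delineation.

    ``weight`` and ``core_fraction`` are the constants of the threshold
    equation (0.3 and 0.70); the shell bounds define the local background
    annulus in mm from the current tumor surface.
    """

    core_fraction: float = 0.70
    weight: float = 0.30
    background_mode: str = "shell"  # "shell" | "explicit_mask"
    shell_inner_mm: float = 8.0
    shell_outer_mm: float = 16.0
    max_iterations: int = 20
    connectivity: int = 26  # 6 | 18 | 26

    def __post_init__(self) -> None:
        if not 0 < self.core_fraction < 1:
            raise ValueError("core_fraction must be in (0, 1)")
        if not 0 < self.weight < 1:
            raise ValueError("weight must be in (0, 1)")
        if self.background_mode not in ("shell", "explicit_mask"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")
        if not 0 < self.shell_inner_mm < self.shell_outer_mm:
            raise ValueError("require 0 < shell_inner_mm < shell_outer_mm")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")

    @property
    def structure(self) -> np.ndarray:
        order = {6: 1, 18: 2, 26: 3}[self.connectivity]
        return ndimage.generate_binary_structure(3, order)


@dataclass
class DelineationResult:
    mask: VOIMask
    threshold: float
    iterations: int
    converged: bool
    background_mean: float

    def __iter__(self):
        # unpack as (mask, threshold, iterations)
        return iter((self.mask, self.threshold, self.iterations))


def resample_to_analysis_grid(
    volume: SUVVolume, target_spacing_mm=ANALYSIS_SPACING_MM
) -> SUVVolume:
    """Trilinearly resample a volume onto a grid with the target spacing.

    The target grid covers the same physical extent as the source (within
    one target voxel per axis); voxel centers are aligned so that the first
    and last target centers sit inside the source field of view.
    """
    target = tuple(float(t) for t in target_spacing_mm)
    if any(t <= 0 for t in target):
        raise ValueError("target spacing must be strictly positive")
    if not np.all(np.isfinite(volume.values)):
        raise ValueError("cannot resample non-finite values")

    src_spacing = np.asarray(volume.voxel_spacing_mm)
    src_shape = np.asarray(volume.shape)
    extent = src_shape * src_spacing
    new_shape = np.maximum(1, np.rint(extent / np.asarray(target)).astype(int))

    # world coordinate of target voxel j: edge-aligned with the source grid
    # (source coverage starts at origin - spacing/2)
    new_origin = np.asarray(volume.origin_mm) - src_spacing / 2.0 + np.asarray(target) / 2.0

    coords = np.meshgrid(
        *[
            (new_origin[a] + np.arange(new_shape[a]) * target[a] - volume.origin_mm[a])
            / src_spacing[a]
            for a in range(3)
        ],
        indexing="ij",
    )
    resampled = ndimage.map_coordinates(volume.values, coords, order=1, mode="nearest")
    np.clip(resampled, 0.0, None, out=resampled)
    return SUVVolume(resampled, target, tuple(float(x) for x in new_origin))


def nestle_threshold(
    volume: SUVVolume,
    tumor_estimate: VOIMask,
    background_mean: float,
    config: SegmentationConfig | None = None,
) -> float:
    """Adaptive SUV threshold for one tumor estimate.

    Returns ``weight * mean(core) + background_mean`` where the core is the
    set of estimate voxels strictly above ``core_fraction * max(estimate)``.
    """
    config = config or SegmentationConfig()
    tumor_estimate.check_aligned(volume)
    vals = volume.values[tumor_estimate.values]
    if vals.size == 0:
        raise ValueError("tumor estimate is empty")
    if background_mean < 0:
        raise ValueError("background mean must be non-negative")
    core = vals[vals > config.core_fraction * vals.max()]
    # non-empty for core_fraction < 1: the max itself always qualifies
    assert core.size > 0
    return float(config.weight * core.mean() + background_mean)


def _component_containing(above: np.ndarray, anchor: tuple[int, int, int], structure) -> np.ndarray:
    labels, _ = ndimage.label(above, structure=structure)
    lab = labels[anchor]
    if lab == 0:
        return np.zeros_like(above)
    return labels == lab


def _shell_background(
    mask: np.ndarray,
    volume: SUVVolume,
    config: SegmentationConfig,
    exclude: np.ndarray | None,
) -> float:
    dist = ndimage.distance_transform_edt(~mask, sampling=volume.voxel_spacing_mm)
    shell = (dist >= config.shell_inner_mm) & (dist <= config.shell_outer_mm)
    if exclude is not None:
        shell &= ~exclude
    if not shell.any():
        raise ValueError("background shell is empty")
    return float(volume.values[shell].mean())


def delineate_tumor(
    volume: SUVVolume,
    seed_point_mm,
    config: SegmentationConfig | None = None,
    organ_masks: tuple[VOIMask, ...] = (),
    background_mask: VOIMask | None = None,
    local_max_radius_mm: float = 12.0,
) -> DelineationResult:
    """Delineate the seed's tumor by fixed-point adaptive thresholding.

    The initial estimate is the connected component (per
    ``config.connectivity``) containing the seed at half the local maximum
    SUV near the seed.  Each iteration measures the background, applies
    :func:`nestle_threshold`, and re-extracts the component; iteration stops
    when the mask is unchanged or ``max_iterations`` is reached (the latter
    sets ``converged=False`` and emits a warning rather than failing).
    """
    config = config or SegmentationConfig()
    seed_idx = volume.world_to_index(seed_point_mm)
    if not volume.contains_index(seed_idx):
        raise ValueError(f"seed point {tuple(seed_point_mm)} lies outside the grid")
    if volume.values[seed_idx] <= 0:
        raise ValueError("SUV at the seed must be positive")
    if config.background_mode == "explicit_mask" and background_mask is None:
        raise ValueError("background_mode='explicit_mask' requires a background mask")

    exclude = None
    if organ_masks:
        exclude = np.zeros(volume.shape, dtype=bool)
        for m in organ_masks:
            m.check_aligned(volume)
            exclude |= m.values

    # local maximum in a box of radius local_max_radius_mm around the seed
    lo = [
        max(0, seed_idx[a] - int(round(local_max_radius_mm / volume.voxel_spacing_mm[a])))
        for a in range(3)
    ]
    hi = [
        min(
            volume.shape[a],
            seed_idx[a] + int(round(local_max_radius_mm / volume.voxel_spacing_mm[a])) + 1,
        )
        for a in range(3)
    ]
    box = volume.values[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
    rel = np.unravel_index(int(np.argmax(box)), box.shape)
    anchor = tuple(l + r for l, r in zip(lo, rel))
    local_max = float(volume.values[anchor])

    structure = config.structure
    mask = _component_containing(volume.values > 0.5 * local_max, anchor, structure)
    if not mask.any():
        raise ValueError("initial tumor estimate is empty")

    threshold = 0.5 * local_max
    bg = 0.0
    converged = False
    iterations = 0
    for iterations in range(1, config.max_iterations + 1):
        est = VOIMask(mask, volume.voxel_spacing_mm, volume.origin_mm, label="tumor_estimate")
        if config.background_mode == "shell":
            bg = _shell_background(mask, volume, config, exclude)
        else:
            background_mask.check_aligned(volume)
            bg = float(volume.values[background_mask.values].mean())
        threshold = nestle_threshold(volume, est, bg, config)
        # anchor at the estimate's hottest voxel: always above the threshold
        flat = np.where(mask.ravel())[0]
        hot = flat[int(np.argmax(volume.values.ravel()[flat]))]
        anchor = tuple(int(i) for i in np.unravel_index(hot, volume.shape))
        new_mask = _component_containing(volume.values > threshold, anchor, structure)
        if not new_mask.any():
            raise ValueError(
                f"tumor mask emptied during iteration (last threshold {threshold:.4g})"
            )
        if np.array_equal(new_mask, mask):
            converged = True
            break
        mask = new_mask
    if not converged:
        warnings.warn(
            f"delineation did not converge in {config.max_iterations} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return DelineationResult(
        mask=VOIMask(mask, volume.voxel_spacing_mm, volume.origin_mm, label="tumor"),
        threshold=threshold,
        iterations=iterations,
        converged=converged,
        background_mean=bg,
    )
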