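"""Synthetic PET phantoms with known ground truth.

A phantom is a 3D SUV volume containing a spherical, texture-heterogeneous
tumor plus reference organs (liver, spleen, six vertebral bodies) in a noisy
soft-tissue background.  Every region's geometry and true mean uptake are
recorded so segmentation, feature extraction and reference-uptake
measurements can be validated against ground truth.

Tumor and organ texture is modelled as Gaussian white noise convolved with
an isotropic Gaussian kernel (correlation length in mm) and rescaled to a
target marginal standard deviation, giving direct control over the true
coefficient of variation.  No PET physics (scatter, attenuation,
partial-volume PSF, reconstruction) is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import SUVVolume, VOIMask, sphere_mask

__all__ = ["OrganSpec", "PhantomSpec", "GroundTruth", "generate_phantom", "default_phantom_spec"]

VERTEBRA_LABELS = tuple(f"vertebra_{i}" for i in range(1, 7))
ORGAN_LABELS = ("liver", "spleen") + VERTEBRA_LABELS


@dataclass
class OrganSpec:
    """A spherical reference region: label, center (mm), radius (mm), mean SUV, texture SD."""

    label: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    suv_mean: float
    suv_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in ORGAN_LABELS:
            raise ValueError(f"unknown organ label {self.label!r}; expected one of {ORGAN_LABELS}")
        if self.radius_mm <= 0:
            raise ValueError(f"organ {self.label}: radius must be positive")
        if self.suv_mean <= 0:
            raise ValueError(f"organ {self.label}: mean SUV must be positive")
        if self.suv_sd < 0:
            raise ValueError(f"organ {self.label}: SUV sd must be non-negative")


@dataclass
class PhantomSpec:
    """Geometry and intensity model of one synthetic PET volume.

    Defaults emulate a colorectal primary (mean SUV 7, true CoV ≈ 0.24) in a
    soft-tissue background of SUV 1, with liver/spleen/vertebral reference
    regions at typical physiologic uptake, on the 4.07 × 4.07 × 2.5 mm
    analysis grid.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 56)
    voxel_spacing_mm: tuple[float, float, float] = (4.07, 4.07, 2.5)
    background_suv_mean: float = 1.0
    background_suv_sd: float = 0.05
    tumor_center_mm: tuple[float, float, float] = (65.0, 65.0, 70.0)
    tumor_radius_mm: float = 18.75
    tumor_suv_mean: float = 7.0
    tumor_texture_sd: float = 1.68
    texture_correlation_len_mm: float = 6.0
    organ_specs: tuple[OrganSpec, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_spacing_mm = tuple(float(s) for s in self.voxel_spacing_mm)
        if any(n < 1 for n in self.grid_shape):
            raise ValueError("grid shape must be positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")
        if self.tumor_radius_mm <= 0:
            raise ValueError("tumor radius must be positive")
        if self.tumor_suv_mean <= 0 or self.background_suv_mean <= 0:
            raise ValueError("mean SUVs must be positive")
        if min(self.tumor_texture_sd, self.background_suv_sd, self.noise_sd) < 0:
            raise ValueError("SUV standard deviations must be non-negative")
        if self.texture_correlation_len_mm <= 0:
            raise ValueError("texture correlation length must be positive")
        self.organ_specs = tuple(self.organ_specs)
        labels = [o.label for o in self.organ_specs]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate organ labels")
        n_vert = sum(1 for l in labels if l.startswith("vertebra_"))
        if self.organ_specs and n_vert != 6:
            raise ValueError(f"expected 6 vertebrae, got {n_vert}")

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.grid_shape, self.voxel_spacing_mm))

    def true_tumor_volume_cm3(self) -> float:
        return 4.0 / 3.0 * math.pi * (self.tumor_radius_mm / 10.0) ** 3


@dataclass
class GroundTruth:
    """Masks and true values of every generated region."""

    tumor_mask: VOIMask
    organ_masks: dict[str, VOIMask]
    true_tumor_volume_cm3: float
    true_region_means: dict[str, float]

    def to_index(self) -> dict:
        return {
            "true_tumor_volume_cm3": self.true_tumor_volume_cm3,
            "true_region_means": dict(self.true_region_means),
            "regions": ["tumor"] + sorted(self.organ_masks),
        }


def _check_geometry(spec: PhantomSpec) -> None:
    regions = [("tumor", spec.tumor_center_mm, spec.tumor_radius_mm)]
    regions += [(o.label, o.center_mm, o.radius_mm) for o in spec.organ_specs]
    extent = spec.extent_mm
    for label, center, radius in regions:
        for c, e in zip(center, extent):
            if c - radius < -0.5 * min(spec.voxel_spacing_mm) or c + radius > e:
                raise ValueError(f"region {label!r} exceeds the grid extent {extent}")
    for i, (la, ca, ra) in enumerate(regions):
        for lb, cb, rb in regions[i + 1 :]:
            d = math.dist(ca, cb)
            if d < ra + rb:
                raise ValueError(f"regions {la!r} and {lb!r} overlap (center distance {d:.1f} mm)")


def _textured_region(
    mask: np.ndarray,
    mean: float,
    sd: float,
    corr_len_mm: float,
    spacing: tuple[float, float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Values for one region: smoothed Gaussian field with the target marginal sd."""
    if sd == 0:
        return np.full(int(mask.sum()), float(mean))
    field = rng.standard_normal(mask.shape)
    sigma_vox = [corr_len_mm / s for s in spacing]
    field = ndimage.gaussian_filter(field, sigma=sigma_vox, mode="reflect")
    field /= field.std()  # restore unit marginal sd after smoothing
    return mean + sd * field[mask]


def generate_phantom(spec: PhantomSpec) -> tuple[SUVVolume, GroundTruth]:
    """Generate one phantom volume plus its ground truth.

    Deterministic for a fixed ``spec.seed``.  Negative values arising from
    noise are clipped to 0 (SUV is non-negative by definition).
    """
    _check_geometry(spec)
    rng = np.random.default_rng(spec.seed)
    spacing = spec.voxel_spacing_mm

    values = spec.background_suv_mean + spec.background_suv_sd * rng.standard_normal(
        spec.grid_shape
    )

    # reference volume used only for geometry helpers
    geom = SUVVolume(np.zeros(spec.grid_shape), spacing)

    tumor_mask = sphere_mask(geom, spec.tumor_center_mm, spec.tumor_radius_mm, label="tumor")
    values[tumor_mask.values] = _textured_region(
        tumor_mask.values,
        spec.tumor_suv_mean,
        spec.tumor_texture_sd,
        spec.texture_correlation_len_mm,
        spacing,
        rng,
    )

    organ_masks: dict[str, VOIMask] = {}
    true_means = {"tumor": spec.tumor_suv_mean, "background": spec.background_suv_mean}
    for organ in spec.organ_specs:
        m = sphere_mask(geom, organ.center_mm, organ.radius_mm, label=organ.label)
        if m.voxel_count == 0:
            raise ValueError(f"organ {organ.label!r} contains no voxel centers")
        values[m.values] = _textured_region(
            m.values, organ.suv_mean, organ.suv_sd, spec.texture_correlation_len_mm, spacing, rng
        )
        organ_masks[organ.label] = m
        true_means[organ.label] = organ.suv_mean

    if spec.noise_sd > 0:
        values += spec.noise_sd * rng.standard_normal(spec.grid_shape)
    np.clip(values, 0.0, None, out=values)

    volume = SUVVolume(values, spacing)
    truth = GroundTruth(
        tumor_mask=tumor_mask,
        organ_masks=organ_masks,
        true_tumor_volume_cm3=spec.true_tumor_volume_cm3(),
        true_region_means=true_means,
    )
    return volume, truth


def default_phantom_spec(seed: int = 0, **overrides) -> PhantomSpec:
    """A full phantom: tumor + liver + spleen + six vertebrae on the default grid.

    The liver sphere is large enough to hold the 3-cm measurement VOI, the
    spleen the 2-cm VOI, and each vertebra the 1.5-cm vertebral VOI.
    """
    organs = [
        OrganSpec("liver", (190.0, 75.0, 70.0), 24.0, 2.1, 0.10),
        OrganSpec("spleen", (190.0, 185.0, 70.0), 17.0, 1.7, 0.10),
    ]
    for i, z in enumerate(np.linspace(15.0, 125.0, 6)):
        organs.append(OrganSpec(f"vertebra_{i + 1}", (130.0, 210.0, float(z)), 9.0, 1.8, 0.10))
    defaults = dict(organ_specs=tuple(organs), noise_sd=0.05, seed=seed)
    defaults.update(overrides)
    return PhantomSpec(**defaults)
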