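"""Bone-marrow, liver and spleen uptake and the BLR/SLR ratios.

Protocol: a spherical VOI per vertebral body (six vertebrae of the thoracic
and lumbar spine); within each, the mean SUV of voxels strictly above 75% of
the VOI's maximum is the vertebral measurement, and the BM SUV is the
unweighted mean of the six.  Liver SUV is the plain mean of a 3-cm spherical
VOI, spleen SUV of a 2-cm spherical VOI.  BLR = BM/liver, SLR =
spleen/liver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .volume import SUVVolume, VOIMask, sphere_mask

__all__ = [
    "ReferenceUptake",
    "vertebral_suv",
    "bm_suv",
    "organ_suv",
    "uptake_ratios",
    "measure_reference_uptake",
    "VERTEBRAL_VOI_DIAMETER_MM",
    "LIVER_VOI_DIAMETER_MM",
    "SPLEEN_VOI_DIAMETER_MM",
]

VERTEBRAL_VOI_DIAMETER_MM = 15.0
LIVER_VOI_DIAMETER_MM = 30.0
SPLEEN_VOI_DIAMETER_MM = 20.0


@dataclass
class ReferenceUptake:
    """Reference-organ uptake of one patient/phantom."""

    bm_suv: float
    liver_suv: float
    spleen_suv: float
    blr: float
    slr: float
    per_vertebra_suv: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.per_vertebra_suv) != 6:
            raise ValueError("expected six vertebral measurements")

    def as_dict(self) -> dict[str, float]:
        d = {
            "bm_suv": self.bm_suv,
            "liver_suv": self.liver_suv,
            "spleen_suv": self.spleen_suv,
            "blr": self.blr,
            "slr": self.slr,
        }
        d.update({f"vertebra_{i + 1}_suv": v for i, v in enumerate(self.per_vertebra_suv)})
        return d


def vertebral_suv(volume: SUVVolume, voi: VOIMask, core_fraction: float = 0.75) -> float:
    """Mean SUV of VOI voxels strictly above ``core_fraction`` of the VOI max.

    A perfectly uniform VOI has no voxel strictly above the cutoff; in that
    degenerate case the mean over all VOI voxels is returned with a warning.
    """
    voi.check_aligned(volume)
    vals = volume.values[voi.values]
    if vals.size == 0:
        raise ValueError("vertebral VOI is empty")
    core = vals[vals > core_fraction * vals.max()]
    if core.size == 0:
        warnings.warn(
            "uniform vertebral VOI: falling back to the mean over all VOI voxels",
            RuntimeWarning,
        )
        return float(vals.mean())
    return float(core.mean())


def bm_suv(
    volume: SUVVolume, vertebral_vois, core_fraction: float = 0.75
) -> tuple[float, tuple[float, ...]]:
    """Bone-marrow SUV: unweighted mean of the six vertebral measurements."""
    vois = list(vertebral_vois)
    if len(vois) != 6:
        raise ValueError(f"expected exactly six vertebral VOIs, got {len(vois)}")
    per = tuple(vertebral_suv(volume, v, core_fraction) for v in vois)
    return float(np.mean(per)), per


def organ_suv(volume: SUVVolume, center_mm, diameter_mm: float) -> float:
    """Mean SUV of voxels whose centers lie within the spherical VOI."""
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    m = sphere_mask(volume, center_mm, diameter_mm / 2.0)
    if m.voxel_count == 0:
        raise ValueError(
            f"spherical VOI at {tuple(center_mm)} (d={diameter_mm} mm) contains no voxel centers"
        )
    return float(volume.values[m.values].mean())


def uptake_ratios(bm: float, spleen: float, liver: float) -> tuple[float, float]:
    """(BLR, SLR) = (BM/liver, spleen/liver)."""
    if liver <= 0:
        raise ValueError("liver SUV must be positive")
    return bm / liver, spleen / liver


def measure_reference_uptake(
    volume: SUVVolume,
    vertebral_vois,
    liver_center_mm,
    spleen_center_mm,
    liver_diameter_mm: float = LIVER_VOI_DIAMETER_MM,
    spleen_diameter_mm: float = SPLEEN_VOI_DIAMETER_MM,
    core_fraction: float = 0.75,
) -> ReferenceUptake:
    """Full reference-organ protocol on one volume."""
    bm, per = bm_suv(volume, vertebral_vois, core_fraction)
    liver = organ_suv(volume, liver_center_mm, liver_diameter_mm)
    spleen = organ_suv(volume, spleen_center_mm, spleen_diameter_mm)
    blr, slr = uptake_ratios(bm, spleen, liver)
    return ReferenceUptake(
        bm_suv=bm,
        liver_suv=liver,
        spleen_suv=spleen,
        blr=blr,
        slr=slr,
        per_vertebra_suv=per,
    )
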