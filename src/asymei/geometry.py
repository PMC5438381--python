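"""Cone-beam geometry of the two-mask scanning system.

Conventions: distances along the optical axis are in metres, measured from
the source; pitches, apertures and lateral displacements are in micrometres.
``x`` is the scan / phase-sensitive direction, ``y`` is vertical.  Pixel
indices are 0-based and maps are sampled at pixel centers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GeometryError",
    "SystemGeometry",
    "MaskSpec",
    "projected_pitch",
    "demagnified_pitch",
    "displacement_at_m2",
    "refraction_to_displacement",
    "displacement_scale",
    "scan_step",
    "effective_pixel",
]


class GeometryError(ValueError):
    """Invalid geometry parameters or sample placement."""


@dataclass(frozen=True)
class SystemGeometry:
    """Source-to-element distances and detector layout.

    ``z_m1``/``z_m2``/``z_det`` are source -> pre-sample mask / detector
    mask / detector distances (m).  ``z_sample`` defaults to ``z_m1``
    (sample immediately downstream of the pre-sample mask, the standard
    edge-illumination arrangement) and may be overridden.
    """

    z_m1: float
    z_m2: float
    z_det: float
    detector_pitch: float = 100.0  # um
    focal_spot: float = 80.0  # um; blurring is folded into the IC width
    z_sample: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.z_m1 < self.z_m2 <= self.z_det):
            raise GeometryError(
                f"require 0 < z_m1 < z_m2 <= z_det, got "
                f"({self.z_m1}, {self.z_m2}, {self.z_det})"
            )
        if self.detector_pitch <= 0 or self.focal_spot <= 0:
            raise GeometryError("detector_pitch and focal_spot must be > 0")
        zs = self.z_m1 if self.z_sample is None else self.z_sample
        if not (self.z_m1 <= zs < self.z_m2):
            raise GeometryError(
                f"sample plane must satisfy z_m1 <= z_sample < z_m2, got {zs}"
            )
        object.__setattr__(self, "z_sample", float(zs))

    @property
    def m1_to_m2_magnification(self) -> float:
        return self.z_m2 / self.z_m1


@dataclass(frozen=True)
class MaskSpec:
    """Pitch/aperture layout of one mask, plus its subgroup shift pattern."""

    label: str  # "M1" or "M2"
    pitch: float  # um
    aperture: float  # um
    subgroup_shifts: Sequence[float] = ()  # um; empty for unshifted masks

    def __post_init__(self) -> None:
        if self.label not in ("M1", "M2"):
            raise GeometryError(f"mask label must be 'M1' or 'M2', got {self.label!r}")
        if not 0.0 < self.aperture < self.pitch:
            raise GeometryError(
                f"require 0 < aperture < pitch, got aperture={self.aperture}, "
                f"pitch={self.pitch}"
            )
        object.__setattr__(self, "subgroup_shifts", tuple(float(s) for s in self.subgroup_shifts))

    @property
    def n_subgroups(self) -> int:
        return len(self.subgroup_shifts)


def projected_pitch(mask_pitch: float, z_mask: float, z_det: float) -> float:
    """Cone-beam projection of a mask pitch onto the detector plane (um)."""
    if z_mask <= 0:
        raise GeometryError(f"z_mask must be > 0, got {z_mask}")
    if z_det < z_mask:
        raise GeometryError(f"require z_mask <= z_det, got {z_mask} > {z_det}")
    return mask_pitch * z_det / z_mask


def demagnified_pitch(detector_pitch: float, z_mask: float, z_det: float) -> float:
    """Mask pitch whose cone-beam projection at the detector equals ``detector_pitch``.

    Inverse of :func:`projected_pitch`; e.g. 100 um detector pixels demand a
    75 um pitch at 1.5 m and a 97.5 um pitch at 1.95 m for a 2 m detector
    distance.
    """
    if z_det <= 0:
        raise GeometryError(f"z_det must be > 0, got {z_det}")
    if z_mask <= 0 or z_mask > z_det:
        raise GeometryError(f"require 0 < z_mask <= z_det, got {z_mask}")
    return detector_pitch * z_mask / z_det


def displacement_at_m2(angle_rad, geom: SystemGeometry, z_sample: Optional[float] = None):
    """Lateral beamlet displacement at the detector-mask plane (um).

    A refraction angle ``angle_rad`` acquired at the sample plane displaces
    the beamlet by ``angle * (z_m2 - z_sample)`` by the time it reaches M2.
    """
    zs = geom.z_sample if z_sample is None else float(z_sample)
    if not (geom.z_m1 <= zs < geom.z_m2):
        raise GeometryError(f"sample plane must lie in [z_m1, z_m2), got {zs}")
    return np.asarray(angle_rad, dtype=float) * (geom.z_m2 - zs) * 1e6


def displacement_scale(geom: SystemGeometry, z_sample: Optional[float] = None) -> float:
    """Micrometres of equivalent M1 displacement per radian of refraction.

    The IC is parametrized in M1-displacement units, so the M2-plane
    displacement is rescaled by the M1 -> M2 magnification ``z_m2 / z_m1``.
    """
    zs = geom.z_sample if z_sample is None else float(z_sample)
    if not (geom.z_m1 <= zs < geom.z_m2):
        raise GeometryError(f"sample plane must lie in [z_m1, z_m2), got {zs}")
    return (geom.z_m2 - zs) * 1e6 / geom.m1_to_m2_magnification


def refraction_to_displacement(angle_rad, z_sample: Optional[float], geom: SystemGeometry):
    """Convert a refraction angle (rad) to IC displacement units (um at M1)."""
    return np.asarray(angle_rad, dtype=float) * displacement_scale(geom, z_sample)


def scan_step(speed_mm_s: float, frame_rate_hz: float) -> float:
    """Object travel per detector frame, in micrometres.

    Returns the exact quotient ``1000 * speed / frame_rate``; e.g. 2.5 mm/s
    at 32 Hz gives 78.125 um per frame (the nominal effective pixel of the
    modelled system is the 75 um demagnified detector pitch).
    """
    if speed_mm_s <= 0 or frame_rate_hz <= 0:
        raise GeometryError(
            f"speed and frame rate must be > 0, got ({speed_mm_s}, {frame_rate_hz})"
        )
    return 1000.0 * speed_mm_s / frame_rate_hz


def effective_pixel(geom: SystemGeometry) -> float:
    """Detector pixel demagnified to the pre-sample-mask plane (um)."""
    return demagnified_pitch(geom.detector_pitch, geom.z_m1, geom.z_det)
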