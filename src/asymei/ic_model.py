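"""Parametric illumination-curve (IC) model and asymmetric sampling schemes.

The IC is the bell-shaped detected-intensity response obtained by laterally
displacing the pre-sample mask.  The retrieval algebra consumes only the
local value ``R``, first derivative ``Rdot`` and second derivative ``Rddot``
of the IC at four fixed sampling points, so the model exposes exactly that
triple, with analytic derivatives.

The default functional form is a Gaussian on a constant pedestal:

    R(phi) = baseline + (peak_amplitude - baseline) * exp(-(phi - center)^2 / (2 width^2))

All displacements ``phi`` are lateral pre-sample-mask displacements in
micrometres.  Alternate bell shapes can be added behind the same
evaluation contract (``ic_eval`` returning ``(R, Rdot, Rddot)``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ICParameterError",
    "SchemeError",
    "IlluminationCurve",
    "SamplingScheme",
    "make_ic",
    "ic_eval",
    "place_half_max_scheme",
    "scheme_from_shifts",
]


class ICParameterError(ValueError):
    """Invalid illumination-curve parameters."""


class SchemeError(ValueError):
    """A sampling scheme could not be constructed or violates its invariants."""


@dataclass(frozen=True)
class IlluminationCurve:
    """Gaussian-on-pedestal illumination curve.

    Parameters
    ----------
    peak_amplitude:
        Value of the curve at its maximum, dimensionless fraction in (0, 1].
    width:
        Gaussian sigma of the bell, in micrometres of mask displacement.
    baseline:
        Constant offset (transmission through the mask septa), >= 0 and
        strictly below ``peak_amplitude``.
    center:
        Displacement of the IC maximum, micrometres.
    """

    peak_amplitude: float
    width: float
    baseline: float = 0.0
    center: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite([self.peak_amplitude, self.width, self.baseline, self.center]).all():
            raise ICParameterError("IC parameters must be finite")
        if self.width <= 0:
            raise ICParameterError(f"width must be > 0, got {self.width}")
        if self.baseline < 0:
            raise ICParameterError(f"baseline must be >= 0, got {self.baseline}")
        if self.peak_amplitude <= self.baseline:
            raise ICParameterError(
                f"peak_amplitude ({self.peak_amplitude}) must exceed baseline ({self.baseline})"
            )
        if not 0.0 < self.peak_amplitude <= 1.0:
            raise ICParameterError(
                f"peak_amplitude must lie in (0, 1], got {self.peak_amplitude}"
            )

    @property
    def amplitude(self) -> float:
        """Height of the bell above the pedestal."""
        return self.peak_amplitude - self.baseline

    def value(self, phi):
        """R(phi)."""
        u = (np.asarray(phi, dtype=float) - self.center) / self.width
        return self.baseline + self.amplitude * np.exp(-0.5 * u * u)

    def slope(self, phi):
        """dR/dphi."""
        phi = np.asarray(phi, dtype=float)
        u = (phi - self.center) / self.width
        g = self.amplitude * np.exp(-0.5 * u * u)
        return -g * u / self.width

    def curvature(self, phi):
        """d2R/dphi2."""
        phi = np.asarray(phi, dtype=float)
        u = (phi - self.center) / self.width
        g = self.amplitude * np.exp(-0.5 * u * u)
        return g * (u * u - 1.0) / (self.width * self.width)

    def __call__(self, phi):
        return self.value(phi)


def make_ic(
    peak_amplitude: float,
    width: float,
    baseline: float = 0.0,
    center: float = 0.0,
) -> IlluminationCurve:
    """Construct a validated :class:`IlluminationCurve`."""
    return IlluminationCurve(
        peak_amplitude=float(peak_amplitude),
        width=float(width),
        baseline=float(baseline),
        center=float(center),
    )


def ic_eval(ic: IlluminationCurve, phi):
    """Evaluate the IC and its first two derivatives at displacement ``phi``.

    Returns the triple ``(R, Rdot, Rddot)``; accepts scalars or arrays.
    """
    return ic.value(phi), ic.slope(phi), ic.curvature(phi)


@dataclass(frozen=True)
class SamplingScheme:
    """Four asymmetric sampling points on an illumination curve.

    ``offsets`` are the four mask displacements *relative to the IC center*,
    in ascending order, pair-symmetric: ``offsets[0] == -offsets[3]`` and
    ``offsets[1] == -offsets[2]``.  Index ``j = 1`` (array index 0) is the
    most negative offset; the retrieval formulas are applied with this
    ordering.  The per-point IC triples are precomputed at construction.
    """

    offsets: tuple
    ic: IlluminationCurve
    R: np.ndarray = field(init=False, repr=False, compare=False)
    Rdot: np.ndarray = field(init=False, repr=False, compare=False)
    Rddot: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        off = np.asarray(self.offsets, dtype=float)
        if off.shape != (4,):
            raise SchemeError(f"exactly 4 sampling offsets required, got {off.shape}")
        if not np.all(np.diff(off) > 0):
            raise SchemeError(f"offsets must be strictly ascending/distinct, got {off}")
        scale = float(np.max(np.abs(off)))
        if scale == 0.0:
            raise SchemeError("all offsets are zero: no asymmetry to sample")
        tol = 1e-9 * scale
        if abs(off[0] + off[3]) > tol or abs(off[1] + off[2]) > tol:
            raise SchemeError(
                "offsets must be pair-symmetric about the IC center "
                f"(got {off}); the closed-form retrieval assumes this symmetry"
            )
        object.__setattr__(self, "offsets", tuple(off))
        R, Rdot, Rddot = ic_eval(self.ic, self.positions)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "Rdot", Rdot)
        object.__setattr__(self, "Rddot", Rddot)

    @property
    def positions(self) -> np.ndarray:
        """Absolute mask displacements of the four points (center + offsets)."""
        return self.ic.center + np.asarray(self.offsets, dtype=float)


def place_half_max_scheme(
    ic: IlluminationCurve, inner_fraction: float = 1.0 / 3.0
) -> SamplingScheme:
    """Place the four points with the outer pair at 50% of the IC maximum.

    The outer offsets ``+/-d`` solve ``R(center + d) = baseline +
    0.5 * (R_max - baseline)``; the inner pair sits at
    ``+/- inner_fraction * d``.  For the default layout derived from mask
    subgroup shifts ``{-s, 0, s, 2s}`` the four points are
    ``{-3s/2, -s/2, +s/2, +3s/2}``, i.e. ``inner_fraction = 1/3``.
    """
    if not 0.0 < inner_fraction < 1.0:
        raise SchemeError(
            f"inner_fraction must lie strictly in (0, 1), got {inner_fraction}"
        )
    half = ic.baseline + 0.5 * (ic.peak_amplitude - ic.baseline)

    def f(d: float) -> float:
        return float(ic.value(ic.center + d) - half)

    hi = ic.width
    # bracket outward from the center; the Gaussian guarantees a crossing
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6 * ic.width:  # pragma: no cover - pathological
            raise SchemeError("failed to bracket the half-maximum of the IC")
    try:
        d = brentq(f, 0.0, hi, xtol=1e-15 * ic.width, rtol=8.881784197001252e-16)
    except ValueError as exc:  # pragma: no cover - pathological
        raise SchemeError(f"half-maximum root finding failed: {exc}") from exc
    inner = inner_fraction * d
    return SamplingScheme(offsets=(-d, -inner, inner, d), ic=ic)


def scheme_from_shifts(
    ic: IlluminationCurve,
    shifts: Sequence[float],
    global_offset: float,
) -> SamplingScheme:
    """Build a scheme from the mask subgroup shifts plus a global alignment offset.

    The printed subgroup shifts ``{-s, 0, s, 2s}`` are not symmetric about
    zero; a global offset of ``-s/2`` (equivalently an IC center at ``+s/2``)
    maps them onto the symmetric points ``{-3s/2, -s/2, +s/2, +3s/2}``.
    Offsets are ``shift + global_offset - center``, sorted ascending; a
    non-symmetric result is rejected because the retrieval formulas assume
    pair symmetry.
    """
    shifts = np.asarray(shifts, dtype=float)
    if shifts.shape != (4,):
        raise SchemeError(f"exactly 4 subgroup shifts required, got {shifts.shape}")
    offsets = np.sort(shifts + float(global_offset) - ic.center)
    return SamplingScheme(offsets=tuple(offsets), ic=ic)
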