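"""Synthetic phantoms and the asymmetric edge-illumination scan simulator.

A phantom is described by three co-registered pixel maps — transmission
``I_R``, refraction angle (rad) and scattering-angle variance (rad^2) — the
three channels the retrieval recovers.  The scan simulator moves the
phantom through the fan of beamlets one step per frame and draws Poisson
counts around the second-order illumination-curve expansion

    I_j = I_R * [R_j + Rdot_j * dphi + 1/2 * Rddot_j * dphi^2
                 + 1/2 * Rddot_j * sigma2]

evaluated at each detector column's subgroup point, with ``dphi`` and
``sigma2`` expressed in IC-displacement units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .geometry import SystemGeometry, displacement_scale, effective_pixel
from .ic_model import SamplingScheme

__all__ = [
    "Material",
    "MATERIALS",
    "Slab",
    "Wedge",
    "Cylinder",
    "Sphere",
    "PhantomMaps",
    "ScanFrames",
    "generate_phantom",
    "expected_intensity",
    "simulate_scan",
    "simulate_flats",
    "wavelength_um",
    "wavenumber_um",
]

# hc in keV*um
_HC_KEV_UM = 1.23984193e-3


def wavelength_um(energy_keV: float) -> float:
    """X-ray wavelength in micrometres for a photon energy in keV."""
    if energy_keV <= 0:
        raise ValueError(f"energy must be > 0 keV, got {energy_keV}")
    return _HC_KEV_UM / energy_keV


def wavenumber_um(energy_keV: float) -> float:
    """Wavenumber k = 2*pi/lambda in 1/um."""
    return 2.0 * np.pi / wavelength_um(energy_keV)


@dataclass(frozen=True)
class Material:
    """Optical constants of a phantom material.

    ``delta`` and ``beta`` are the decrements of the complex refractive
    index ``n = 1 - delta + i*beta`` at the working energy; ``scatter`` is
    the scattering-angle variance accumulated per micrometre of traversed
    thickness (rad^2/um), modelling unresolved microstructure.
    """

    delta: float
    beta: float
    scatter: float = 0.0

    def __post_init__(self) -> None:
        if self.beta < 0 or self.scatter < 0:
            raise ValueError("beta and scatter must be >= 0")


# Nominal single-energy constants around 80 keV; synthetic values for
# simulation purposes, not tabulated reference data.
MATERIALS = {
    "pmma": Material(delta=3.3e-8, beta=1.5e-10, scatter=0.0),
    "water": Material(delta=3.0e-8, beta=1.6e-10, scatter=0.0),
    "aluminium": Material(delta=8.4e-8, beta=1.4e-9, scatter=0.0),
    "foam": Material(delta=3.0e-9, beta=2.0e-11, scatter=5.0e-16),
}


def _resolve_material(material: Union[str, Material]) -> Material:
    if isinstance(material, Material):
        return material
    try:
        return MATERIALS[material]
    except KeyError:
        raise ValueError(
            f"unknown material {material!r}; known: {sorted(MATERIALS)}"
        ) from None


@dataclass(frozen=True)
class Slab:
    """Uniform-thickness rectangle spanning all rows: x in [x0, x1] (um)."""

    x0: float
    x1: float
    thickness: float  # um
    material: Union[str, Material]

    def thickness_map(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        t = np.zeros((y.size, x.size))
        t[:, (x >= self.x0) & (x <= self.x1)] = self.thickness
        return t


@dataclass(frozen=True)
class Wedge:
    """Thickness ramp from t0 at x0 to t1 at x1, spanning all rows."""

    x0: float
    x1: float
    t0: float
    t1: float
    material: Union[str, Material]

    def thickness_map(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        t = np.zeros((y.size, x.size))
        inside = (x >= self.x0) & (x <= self.x1)
        frac = (x[inside] - self.x0) / (self.x1 - self.x0)
        t[:, inside] = self.t0 + (self.t1 - self.t0) * frac
        return t


@dataclass(frozen=True)
class Cylinder:
    """Circular cylinder with axis along y (perpendicular to the scan direction).

    Projected thickness t(x) = 2*sqrt(r^2 - (x - cx)^2).
    """

    cx: float
    radius: float
    material: Union[str, Material]

    def thickness_map(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        dx = x - self.cx
        t1d = 2.0 * np.sqrt(np.clip(self.radius**2 - dx**2, 0.0, None))
        return np.broadcast_to(t1d, (y.size, x.size)).copy()


@dataclass(frozen=True)
class Sphere:
    """Sphere centred at (cx, cy); t = 2*sqrt(r^2 - (x-cx)^2 - (y-cy)^2)."""

    cx: float
    cy: float
    radius: float
    material: Union[str, Material]

    def thickness_map(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        dx2 = (x[None, :] - self.cx) ** 2
        dy2 = (y[:, None] - self.cy) ** 2
        return 2.0 * np.sqrt(np.clip(self.radius**2 - dx2 - dy2, 0.0, None))


@dataclass
class PhantomMaps:
    """The three retrievable channels on a common pixel grid.

    ``transmission`` is I_R in (0, 1]; ``refraction`` is the refraction
    angle in rad (x-gradient of the accumulated delta * thickness);
    ``scatter_var`` is the scattering-angle variance in rad^2.
    """

    transmission: np.ndarray
    refraction: np.ndarray
    scatter_var: np.ndarray
    pixel_size: float  # um

    def __post_init__(self) -> None:
        self.transmission = np.asarray(self.transmission, dtype=float)
        self.refraction = np.asarray(self.refraction, dtype=float)
        self.scatter_var = np.asarray(self.scatter_var, dtype=float)
        if not (
            self.transmission.shape == self.refraction.shape == self.scatter_var.shape
        ):
            raise ValueError("phantom maps must share one shape")
        if self.transmission.ndim != 2:
            raise ValueError("phantom maps must be 2-D (ny, nx)")
        for name in ("transmission", "refraction", "scatter_var"):
            if not np.isfinite(getattr(self, name)).all():
                raise ValueError(f"{name} map contains non-finite values")
        if np.any(self.transmission <= 0) or np.any(self.transmission > 1):
            raise ValueError("transmission must lie in (0, 1]")
        if np.any(self.scatter_var < 0):
            raise ValueError("scatter_var must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def shape(self) -> tuple:
        return self.transmission.shape


def generate_phantom(
    shapes: Sequence,
    shape: tuple,
    pixel_size: float,
    energy_keV: float = 80.0,
    transmission_floor: float = 1e-12,
) -> PhantomMaps:
    """Rasterize a list of shapes into :class:`PhantomMaps`.

    Overlapping shapes composite by adding projected thickness.  Per shape:
    transmission multiplies by ``exp(-2 k beta t)``, the refractive phase
    column ``delta * t`` accumulates and is differentiated along x (the scan
    direction) to give the refraction angle, and scattering variance adds
    ``material.scatter * t``.  An empty shape list yields vacuum.
    """
    ny, nx = shape
    x = (np.arange(nx) + 0.5) * pixel_size
    y = (np.arange(ny) + 0.5) * pixel_size
    k = wavenumber_um(energy_keV)

    attenuation = np.zeros((ny, nx))  # 2*k*beta*t, summed
    delta_t = np.zeros((ny, nx))
    scatter = np.zeros((ny, nx))
    for s in shapes:
        mat = _resolve_material(s.material)
        t = s.thickness_map(x, y)
        attenuation += 2.0 * k * mat.beta * t
        delta_t += mat.delta * t
        scatter += mat.scatter * t

    transmission = np.exp(-attenuation)
    n_under = int(np.count_nonzero(transmission < transmission_floor))
    if n_under:
        warnings.warn(
            f"transmission underflow in {n_under} pixels; clipped to "
            f"{transmission_floor}",
            RuntimeWarning,
            stacklevel=2,
        )
        transmission = np.clip(transmission, transmission_floor, 1.0)

    if nx > 1:
        refraction = np.gradient(delta_t, pixel_size, axis=1)
    else:
        refraction = np.zeros_like(delta_t)
    return PhantomMaps(
        transmission=transmission,
        refraction=refraction,
        scatter_var=scatter,
        pixel_size=pixel_size,
    )


def expected_intensity(
    scheme: SamplingScheme,
    j: int,
    transmission,
    dphi_disp,
    sigma2_disp,
    clip: bool = True,
):
    """Noise-free normalized intensity at subgroup point ``j`` (1-based).

    Implements the second-order expansion
    ``I_R * [R_j + Rdot_j*dphi + 0.5*Rddot_j*dphi^2 + 0.5*Rddot_j*sigma2]``
    with ``dphi``/``sigma2`` in IC-displacement units (um, um^2).  Negative
    results (expansion evaluated outside its validity) are clipped to zero
    with a warning when ``clip`` is true.
    """
    if not 1 <= j <= 4:
        raise ValueError(f"subgroup index j must be in [1, 4], got {j}")
    i = j - 1
    dphi = np.asarray(dphi_disp, dtype=float)
    s2 = np.asarray(sigma2_disp, dtype=float)
    out = np.asarray(transmission, dtype=float) * (
        scheme.R[i]
        + scheme.Rdot[i] * dphi
        + 0.5 * scheme.Rddot[i] * (dphi * dphi + s2)
    )
    if clip and np.any(out < 0):
        warnings.warn(
            "expected intensity < 0 (expansion outside validity); clipped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        out = np.clip(out, 0.0, None)
    return out


@dataclass
class ScanFrames:
    """Per-frame, per-column photon counts from one object scan plus flats.

    ``counts`` has shape ``(n_frames, ny, n_columns)``: frame index is the
    scan position, ``ny`` the vertical detector rows covered by the phantom,
    columns are along the scan direction.  A column of subgroup ``j`` sees
    object column ``o`` at frame ``o + col_frame_offsets[c]``.
    """

    counts: np.ndarray
    flats_before: np.ndarray
    flats_after: np.ndarray
    column_subgroup: np.ndarray  # (n_columns,), labels 1..4
    scan_step: float  # um per frame
    flux_per_frame: float  # expected photons per column per frame at R=1
    seed: int
    col_frame_offsets: np.ndarray  # (n_columns,), frames
    n_object_cols: int

    def __post_init__(self) -> None:
        self.column_subgroup = np.asarray(self.column_subgroup, dtype=int)
        self.col_frame_offsets = np.asarray(self.col_frame_offsets, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (n_frames, ny, n_columns)")
        ncol = self.counts.shape[2]
        if self.column_subgroup.shape != (ncol,):
            raise ValueError("column_subgroup must have one label per column")
        if self.col_frame_offsets.shape != (ncol,):
            raise ValueError("col_frame_offsets must have one entry per column")
        labels, counts_per = np.unique(self.column_subgroup, return_counts=True)
        if not np.array_equal(labels, np.arange(1, 5)) or len(set(counts_per)) != 1:
            raise ValueError(
                "every subgroup label 1..4 must occur an equal number of times"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def n_frames(self) -> int:
        return self.counts.shape[0]

    @property
    def n_columns(self) -> int:
        return self.counts.shape[2]


def _subgroup_pattern(n_columns: int) -> np.ndarray:
    if n_columns % 4 != 0:
        raise ValueError(f"n_columns must be a multiple of 4, got {n_columns}")
    return (np.arange(n_columns) % 4) + 1


def _expectation(
    phantom: PhantomMaps,
    scheme: SamplingScheme,
    column_subgroup: np.ndarray,
    col_frame_offsets: np.ndarray,
    n_frames: int,
    disp_scale: float,
) -> np.ndarray:
    """Noise-free normalized intensity grid (n_frames, ny, n_columns)."""
    ny, nx = phantom.shape
    ncol = column_subgroup.size
    dphi = phantom.refraction * disp_scale
    s2 = phantom.scatter_var * disp_scale**2
    grid = np.empty((n_frames, ny, ncol))
    clipped = 0
    for c in range(ncol):
        jdx = column_subgroup[c] - 1
        grid[:, :, c] = scheme.R[jdx]  # vacuum outside the object
        o0 = int(round(col_frame_offsets[c]))
        f_lo, f_hi = max(o0, 0), min(o0 + nx, n_frames)
        if f_hi <= f_lo:
            continue
        obj = slice(f_lo - o0, f_hi - o0)
        vals = expected_intensity(
            scheme,
            int(column_subgroup[c]),
            phantom.transmission[:, obj],
            dphi[:, obj],
            s2[:, obj],
            clip=False,
        )
        neg = vals < 0
        if np.any(neg):
            clipped += int(np.count_nonzero(neg))
            vals = np.clip(vals, 0.0, None)
        grid[f_lo:f_hi, :, c] = np.moveaxis(vals, 1, 0)
    if clipped:
        warnings.warn(
            f"{clipped} expected intensities < 0 were clipped to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    return grid


def simulate_scan(
    phantom: PhantomMaps,
    geom: SystemGeometry,
    scheme: SamplingScheme,
    flux_per_frame: float,
    n_columns: int = 128,
    seed: int = 0,
    noise: bool = True,
    n_flats: int = 32,
    scan_step_um: Optional[float] = None,
    z_sample: Optional[float] = None,
) -> ScanFrames:
    """Simulate one lateral object scan through the asymmetric mask system.

    Columns repeat the four subgroup points in an interleaved pattern
    (default 128 columns -> 32 per subgroup).  Adjacent columns are spaced
    by one effective pixel at the sample plane; the default scan step equals
    that spacing, so column ``c`` sees object column ``o`` at frame
    ``o + c``.  Counts are Poisson with mean ``flux_per_frame * I_j``
    (deterministic expectation when ``noise=False``); flats are generated
    the same way for a vacuum object.  Deterministic given ``seed``.
    """
    if flux_per_frame <= 0:
        raise ValueError(f"flux_per_frame must be > 0, got {flux_per_frame}")
    step = effective_pixel(geom) if scan_step_um is None else float(scan_step_um)
    if step <= 0:
        raise ValueError("scan step must be > 0")
    col_spacing = effective_pixel(geom)
    k = col_spacing / step
    if abs(k - round(k)) > 1e-9:
        raise ValueError(
            f"column spacing ({col_spacing} um) must be an integer multiple of "
            f"the scan step ({step} um); got ratio {k}"
        )
    k = int(round(k))
    if abs(phantom.pixel_size - step) > 1e-9 * step:
        warnings.warn(
            f"phantom pixel size ({phantom.pixel_size} um) differs from the "
            f"scan step ({step} um); the phantom is sampled per scan position",
            RuntimeWarning,
            stacklevel=2,
        )

    column_subgroup = _subgroup_pattern(n_columns)
    col_frame_offsets = k * np.arange(n_columns, dtype=float)
    ny, nx = phantom.shape
    n_frames = nx + k * (n_columns - 1)
    disp = displacement_scale(geom, z_sample)

    lam = flux_per_frame * _expectation(
        phantom, scheme, column_subgroup, col_frame_offsets, n_frames, disp
    )
    rng_scan, rng_before, rng_after = np.random.default_rng(seed).spawn(3)
    counts = rng_scan.poisson(lam).astype(np.int64) if noise else lam

    flat_lam = flux_per_frame * scheme.R[column_subgroup - 1]
    flat_lam = np.broadcast_to(flat_lam, (n_flats, ny, n_columns))
    if noise:
        flats_before = rng_before.poisson(flat_lam).astype(np.int64)
        flats_after = rng_after.poisson(flat_lam).astype(np.int64)
    else:
        flats_before = np.array(flat_lam, dtype=float)
        flats_after = np.array(flat_lam, dtype=float)

    return ScanFrames(
        counts=counts,
        flats_before=flats_before,
        flats_after=flats_after,
        column_subgroup=column_subgroup,
        scan_step=step,
        flux_per_frame=float(flux_per_frame),
        seed=int(seed),
        col_frame_offsets=col_frame_offsets,
        n_object_cols=nx,
    )


def simulate_flats(
    geom: SystemGeometry,
    scheme: SamplingScheme,
    flux_per_frame: float,
    n_flats: int,
    n_columns: int = 128,
    ny: int = 1,
    seed: int = 0,
    noise: bool = True,
):
    """Generate (before, after) flat stacks for a vacuum field of view."""
    if flux_per_frame <= 0:
        raise ValueError(f"flux_per_frame must be > 0, got {flux_per_frame}")
    column_subgroup = _subgroup_pattern(n_columns)
    lam = flux_per_frame * scheme.R[column_subgroup - 1]
    lam = np.broadcast_to(lam, (n_flats, ny, n_columns))
    if not noise:
        return np.array(lam, dtype=float), np.array(lam, dtype=float)
    rng_before, rng_after = np.random.default_rng(seed).spawn(2)
    return (
        rng_before.poisson(lam).astype(np.int64),
        rng_after.poisson(lam).astype(np.int64),
    )
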