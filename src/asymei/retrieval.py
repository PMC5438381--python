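"""Inverse pipeline: flat-fielding, subgroup assembly and closed-form retrieval.

The multimodal retrieval solves the four-point second-order system in
closed form, pixel-wise:

    I_R     = 1/2 * (I1 + I2 + I3 + I4) / (R1 + R2)
    dphi    = [(I1 + I2) - (I3 + I4)] / (I1 + I2 + I3 + I4)
              * (R1 + R2) / (Rdot1 + Rdot2)
    sigma2  = 2 * [R1*(I2 + I3) - R2*(I1 + I4)] / [Rddot2 * (I1 + I4)]
              - dphi^2

valid for small refraction/scattering and a pair-symmetric scheme with the
outer points at 50% of the IC maximum.  DPC is returned in IC-displacement
units (um); dark field in um^2; both convert to angular units through the
geometry module.  Dark-field values may be negative under noise and are
reported unclipped together with a quality mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import SystemGeometry, displacement_scale
from .forward_sim import ScanFrames, wavenumber_um
from .ic_model import IlluminationCurve, SamplingScheme, ic_eval

__all__ = [
    "RetrievalError",
    "GridError",
    "SubgroupImages",
    "RetrievedImages",
    "flat_field",
    "assemble_subgroups",
    "retrieve_multimodal",
    "retrieve_single_shot",
]

log = logging.getLogger(__name__)


class RetrievalError(ValueError):
    """Retrieval preconditions violated."""


class GridError(ValueError):
    """Subgroup column offsets are incommensurate with the scan grid."""


@dataclass
class SubgroupImages:
    """Four co-registered normalized images, one per asymmetric subgroup.

    ``images`` is ``(4, ny, nx)`` ordered by ascending scheme offset; a
    no-sample region of image ``j`` equals ``R_j``.  ``n_summed`` records
    how many column-images were averaged into each subgroup.
    """

    images: np.ndarray
    scheme: SamplingScheme
    n_summed: np.ndarray

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.n_summed = np.asarray(self.n_summed, dtype=int)
        if self.images.ndim != 3 or self.images.shape[0] != 4:
            raise ValueError("images must have shape (4, ny, nx)")
        if self.n_summed.shape != (4,):
            raise ValueError("n_summed must have 4 entries")

    @property
    def shape(self) -> tuple:
        return self.images.shape[1:]


@dataclass
class RetrievedImages:
    """Co-registered absorption, DPC and dark-field maps.

    ``dpc`` is in IC-displacement units (um at the M1 plane), ``darkfield``
    in um^2; use :meth:`dpc_radians` / :meth:`darkfield_radians2` for
    angular units.  ``invalid`` flags pixels lost to zero denominators;
    ``negative_df`` flags (unclipped) negative dark-field pixels.
    """

    absorption: np.ndarray
    dpc: np.ndarray
    darkfield: np.ndarray
    invalid: np.ndarray
    negative_df: np.ndarray
    phase_map: Optional[np.ndarray] = None

    def dpc_radians(self, geom: SystemGeometry, z_sample: Optional[float] = None):
        return self.dpc / displacement_scale(geom, z_sample)

    def darkfield_radians2(self, geom: SystemGeometry, z_sample: Optional[float] = None):
        return self.darkfield / displacement_scale(geom, z_sample) ** 2


def flat_field(frames: ScanFrames, scheme: SamplingScheme) -> np.ndarray:
    """Normalize raw counts by the per-column flat reference, rescaled by R_j.

    The reference for each (row, column) is the mean of the before and after
    flat stacks, so a linear gain drift over the scan is compensated to
    first order.  The rescaling by the subgroup's ``R_j`` makes a vacuum
    pixel equal ``R_j``, the convention the closed-form retrieval assumes.
    Columns whose reference is not strictly positive propagate as NaN.
    """
    ref = 0.5 * (
        np.asarray(frames.flats_before, dtype=float).mean(axis=0)
        + np.asarray(frames.flats_after, dtype=float).mean(axis=0)
    )  # (ny, n_columns)
    bad = ~(ref > 0)
    if np.any(bad):
        log.warning(
            "flat_field masked_columns n_masked=%d", int(np.count_nonzero(bad))
        )
        ref = np.where(bad, np.nan, ref)
    r_col = scheme.R[frames.column_subgroup - 1]
    return np.asarray(frames.counts, dtype=float) / ref[None, :, :] * r_col[None, None, :]


def assemble_subgroups(
    normalized: np.ndarray,
    column_subgroup: np.ndarray,
    col_frame_offsets: np.ndarray,
    n_object_cols: int,
    scheme: SamplingScheme,
    interpolate: bool = True,
) -> SubgroupImages:
    """Shift column-image stacks onto the object grid and average per subgroup.

    Column ``c`` sees object column ``o`` at frame ``o + col_frame_offsets[c]``.
    Integer offsets (to 1e-6 of a frame) use a pure shift; fractional
    offsets use linear interpolation between the two bracketing frames, or
    raise :class:`GridError` when ``interpolate`` is disabled.  NaN frames
    (masked columns) are excluded from the average.
    """
    normalized = np.asarray(normalized, dtype=float)
    column_subgroup = np.asarray(column_subgroup, dtype=int)
    offsets = np.asarray(col_frame_offsets, dtype=float)
    n_frames, ny, ncol = normalized.shape
    nx = int(n_object_cols)

    images = np.empty((4, ny, nx))
    n_summed = np.zeros(4, dtype=int)
    for j in range(1, 5):
        cols = np.flatnonzero(column_subgroup == j)
        if cols.size == 0:
            raise RetrievalError(f"no columns assigned to subgroup {j}")
        acc = np.zeros((ny, nx))
        cnt = np.zeros((ny, nx))
        for c in cols:
            off = offsets[c]
            o0 = int(np.floor(off))
            frac = off - o0
            if frac < 1e-6 or frac > 1 - 1e-6:
                idx = int(round(off))
                if idx < 0 or idx + nx > n_frames:
                    raise GridError(
                        f"column {c}: frames [{idx}, {idx + nx}) outside scan "
                        f"of {n_frames} frames"
                    )
                img = normalized[idx : idx + nx, :, c]
            else:
                if not interpolate:
                    raise GridError(
                        f"column {c}: fractional frame offset {off} requires "
                        "interpolation, which is disabled"
                    )
                if o0 < 0 or o0 + 1 + nx > n_frames:
                    raise GridError(
                        f"column {c}: frames [{o0}, {o0 + 1 + nx}) outside scan "
                        f"of {n_frames} frames"
                    )
                img = (1.0 - frac) * normalized[o0 : o0 + nx, :, c] + frac * normalized[
                    o0 + 1 : o0 + 1 + nx, :, c
                ]
            img = img.T  # (ny, nx)
            good = np.isfinite(img)
            acc[good] += img[good]
            cnt += good
        with np.errstate(invalid="ignore", divide="ignore"):
            images[j - 1] = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
        n_summed[j - 1] = cols.size
    return SubgroupImages(images=images, scheme=scheme, n_summed=n_summed)


def retrieve_multimodal(sub: SubgroupImages) -> RetrievedImages:
    """Closed-form four-point retrieval of absorption, DPC and dark field.

    Zero denominators (vanishing total intensity or vanishing ``I1 + I4``)
    yield NaN pixels, counted and logged, never silent zeros.
    """
    scheme = sub.scheme
    r1, r2 = scheme.R[0], scheme.R[1]
    rd1, rd2 = scheme.Rdot[0], scheme.Rdot[1]
    rdd2 = scheme.Rddot[1]
    if rd1 + rd2 == 0:
        raise RetrievalError("scheme has Rdot1 + Rdot2 = 0; DPC is not invertible")
    if rdd2 == 0:
        raise RetrievalError("scheme has Rddot2 = 0; dark field is not invertible")

    i1, i2, i3, i4 = sub.images
    total = i1 + i2 + i3 + i4
    outer = i1 + i4
    with np.errstate(invalid="ignore", divide="ignore"):
        absorption = 0.5 * total / (r1 + r2)
        dpc = ((i1 + i2) - (i3 + i4)) / total * (r1 + r2) / (rd1 + rd2)
        darkfield = 2.0 * (r1 * (i2 + i3) - r2 * outer) / (rdd2 * outer) - dpc**2
        dpc = np.where(total != 0, dpc, np.nan)
        darkfield = np.where((outer != 0) & (total != 0), darkfield, np.nan)

    invalid = ~(np.isfinite(absorption) & np.isfinite(dpc) & np.isfinite(darkfield))
    negative_df = np.isfinite(darkfield) & (darkfield < 0)
    n_invalid = int(np.count_nonzero(invalid))
    if n_invalid:
        log.warning("retrieve_multimodal invalid_pixels n=%d", n_invalid)
    return RetrievedImages(
        absorption=absorption,
        dpc=dpc,
        darkfield=darkfield,
        invalid=invalid,
        negative_df=negative_df,
    )


def retrieve_single_shot(
    i1: np.ndarray,
    ic: IlluminationCurve,
    phi1: float,
    delta_beta: float,
    geom: SystemGeometry,
    energy_keV: float,
    pixel_size: float,
    z_sample: Optional[float] = None,
) -> np.ndarray:
    """Single-image phase map of a homogeneous object from the beamlet-1 image.

    The IC is linearized about the first sampling point ``phi1`` so that the
    normalized image couples the transmission ``F = exp(-2 k beta t)`` and
    its x-derivative through the fixed ``delta/beta`` ratio:

        I1 / R1 = F - a * dF/dx,   a = (Rdot1/R1) * C * (delta/beta) / (2k)

    with ``C`` the displacement scale (um/rad).  The first-order linear ODE
    is integrated exactly along x with an exponential integrating factor
    (``F(x) = (1/a) * int_x^inf exp(-(s-x)/a) y(s) ds`` for ``a > 0``),
    discretized exactly for piecewise-linear ``y`` — an unconditionally
    stable one-sided exponential smoothing with scale ``|a|``.  The phase
    follows as ``(delta/beta) * ln(F) / 2`` without requiring delta and
    beta separately.  Vacuum maps to zero phase.
    """
    if delta_beta <= 0:
        raise RetrievalError(f"delta/beta ratio must be > 0, got {delta_beta}")
    if pixel_size <= 0:
        raise RetrievalError("pixel_size must be > 0")
    r1_val, rdot1, _ = ic_eval(ic, phi1)
    r1_val = float(r1_val)
    rdot1 = float(rdot1)
    if abs(rdot1) < 1e-12 * ic.peak_amplitude / ic.width:
        raise RetrievalError(
            "beamlet 1 sits at an IC extremum (zero slope); the single-shot "
            "linearization is not invertible there"
        )
    i1 = np.atleast_2d(np.asarray(i1, dtype=float))
    c_scale = displacement_scale(geom, z_sample)
    k = wavenumber_um(energy_keV)
    a = (rdot1 / r1_val) * c_scale * delta_beta / (2.0 * k)  # um

    y = i1 / r1_val
    f = _solve_linearized_profile(y, a, pixel_size)
    f = np.clip(f, 1e-12, None)
    return 0.5 * delta_beta * np.log(f)


def _solve_linearized_profile(y: np.ndarray, a: float, dx: float) -> np.ndarray:
    """Solve ``F - a * dF/dx = y`` along the last axis.

    Exact exponential-integrator recurrence for piecewise-linear ``y``:
    with ``r = dx/|a|`` and ``q = exp(-r)``,

        F_i = (1 - q - c) * y_i + c * y_{i+1} + q * F_{i+1}   (a > 0)

    where ``c = (1 - q*(1+r)) / r``; for ``a < 0`` the axis is flipped.
    All weights are positive and sum to one, so the solve is stable and
    preserves the range of ``y``.
    """
    if a == 0.0:
        return y.copy()
    if a < 0.0:
        return _solve_linearized_profile(y[..., ::-1], -a, dx)[..., ::-1]
    r = dx / a
    q = np.exp(-r)
    c = (1.0 - q * (1.0 + r)) / r
    # g_i = contribution of the [x_i, x_{i+1}] segment; constant beyond the edge
    y_next = np.concatenate([y[..., 1:], y[..., -1:]], axis=-1)
    g = (1.0 - q - c) * y + c * y_next
    f = np.empty_like(y)
    f[..., -1] = y[..., -1]  # flat continuation beyond the field of view
    for i in range(y.shape[-1] - 2, -1, -1):
        f[..., i] = g[..., i] + q * f[..., i + 1]
    return f
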