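"""Non-rigid alignment of echo/repetition images and complex averaging.

All magnitude images are registered to a common reference magnitude with a
pyramidal, diffusion-regularized optical-flow algorithm, the recovered
displacement fields are applied to the complex data (real and imaginary
channels interpolated separately, so phase wraps are never interpolated
across), and repetitions are averaged as complex vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field
from scipy import ndimage
from skimage.registration import optical_flow_tvl1

from .errors import DegenerateInputError, InvalidGeometryError
from .geometry import Geometry2D
from .phantom import EchoSeries


class RegistrationSettings(BaseModel):
    """Optical-flow registration parameters (all logged by the pipeline)."""

    attachment: float = Field(15.0, gt=0)
    tightness: float = Field(0.3, gt=0)
    num_warp: int = Field(5, ge=1)
    num_iter: int = Field(10, ge=1)
    tol: float = Field(1e-4, gt=0)
    prefilter: bool = True
    #: displacement magnitudes below this are treated as an exact identity
    identity_threshold_px: float = Field(1e-3, ge=0)
    #: register every (rep, echo) to (rep 1, echo 1), or register first
    #: echoes only and reuse the field within each repetition
    target: Literal["first_echo", "per_repetition"] = "per_repetition"


@dataclass
class DeformationField:
    """Per-voxel displacement (2, rows, cols) in pixels, row/col order.

    ``displacement`` maps fixed-frame coordinates to the sample positions
    in the moving image: warped(p) = moving(p + d(p)).
    """

    displacement: np.ndarray
    geometry: Geometry2D | None = None

    @property
    def mean_magnitude(self) -> float:
        return float(np.mean(np.hypot(*self.displacement)))


def register(
    moving: np.ndarray,
    fixed: np.ndarray,
    settings: RegistrationSettings | None = None,
) -> DeformationField:
    """Estimate the displacement field mapping ``moving`` onto ``fixed``.

    Guarantees that warping with the returned field does not increase the
    mean squared intensity difference: if the flow estimate is worse than
    the identity, the identity is returned.
    """
    settings = settings or RegistrationSettings()
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise InvalidGeometryError("moving and fixed images differ in shape")
    if np.ptp(fixed) == 0 or np.ptp(moving) == 0:
        raise DegenerateInputError("constant image cannot be registered")

    flow = optical_flow_tvl1(
        fixed,
        moving,
        attachment=settings.attachment,
        tightness=settings.tightness,
        num_warp=settings.num_warp,
        num_iter=settings.num_iter,
        tol=settings.tol,
        prefilter=settings.prefilter,
    )
    field = DeformationField(displacement=np.asarray(flow, dtype=float))

    warped = _warp_real(moving, field.displacement)
    if np.mean((warped - fixed) ** 2) > np.mean((moving - fixed) ** 2):
        field = DeformationField(displacement=np.zeros_like(field.displacement))
    return field


def _sample_coords(displacement: np.ndarray) -> np.ndarray:
    rows, cols = displacement.shape[1:]
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.stack([rr + displacement[0], cc + displacement[1]])


def _warp_real(img: np.ndarray, displacement: np.ndarray) -> np.ndarray:
    return ndimage.map_coordinates(
        img, _sample_coords(displacement), order=1, mode="nearest"
    )


def warp_complex(image: np.ndarray, field: DeformationField) -> np.ndarray:
    """Warp a complex image by interpolating real and imaginary channels.

    The output phase is the phase of the warped complex signal; wrapped
    phase values are never interpolated directly.  A field that is zero (or
    negligibly small) everywhere returns the input unchanged.
    """
    d = field.displacement
    if not np.all(np.isfinite(d)):
        raise InvalidGeometryError("deformation field contains non-finite values")
    if image.shape != d.shape[1:]:
        raise InvalidGeometryError("image and field shapes differ")
    if np.max(np.abs(d)) == 0:
        return image.copy()
    coords = _sample_coords(d)
    re = ndimage.map_coordinates(image.real, coords, order=1, mode="nearest")
    im = ndimage.map_coordinates(image.imag, coords, order=1, mode="nearest")
    return re + 1j * im


def align_and_average(
    series: EchoSeries, settings: RegistrationSettings | None = None
) -> EchoSeries:
    """Register all echo/repetition images to the reference and average.

    Every image is aligned to the repetition-1, echo-1 magnitude frame and
    the aligned complex signals are averaged across repetitions (vector
    averaging, implicitly magnitude-weighted).  The output has a single
    repetition.  Fields whose maximum displacement is below the identity
    threshold are treated as exact identities, so identical repetitions
    average to themselves bit-for-bit.
    """
    settings = settings or RegistrationSettings()
    n_reps, n_echoes = series.n_reps, series.n_echoes
    fixed = series.magnitude(0, 0)

    aligned = np.empty_like(series.data)
    rep_fields: list[DeformationField | None] = [None] * n_reps
    for r in range(n_reps):
        for j in range(n_echoes):
            if r == 0 and j == 0:
                aligned[r, j] = series.data[r, j]
                continue
            if settings.target == "per_repetition":
                if rep_fields[r] is None:
                    rep_fields[r] = _registration_or_identity(
                        series.magnitude(r, 0), fixed, settings
                    )
                field = rep_fields[r]
            else:
                field = _registration_or_identity(
                    series.magnitude(r, j), fixed, settings
                )
            aligned[r, j] = warp_complex(series.data[r, j], field)

    # average deviations from the first repetition so that averaging k
    # identical signals is the exact identity
    averaged = aligned[0:1] + (aligned - aligned[0:1]).mean(axis=0, keepdims=True)
    return EchoSeries(
        data=averaged,
        te_list=series.te_list.copy(),
        delta_t=series.delta_t,
        geometry=series.geometry,
    )


def _registration_or_identity(moving, fixed, settings) -> DeformationField:
    field = register(moving, fixed, settings)
    if np.max(np.abs(field.displacement)) < settings.identity_threshold_px:
        field = DeformationField(displacement=np.zeros_like(field.displacement))
    return field
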