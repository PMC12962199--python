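"""Shim benefit quantification: masked field statistics and bSSFP response.

Balanced SSFP exhibits signal nulls ("bands") at off-resonance frequencies
near +-n/(2*TR) for odd n.  The steady-state transverse magnitude is
evaluated from the standard closed-form expression with a configurable RF
phase-cycling increment (180 degrees by default, which centres the
passband on resonance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .errors import ConfigurationError, EmptyMaskError
from .fieldmap import FieldMap
from .segmentation import LungMask


class BssfpParams(BaseModel):
    """Sequence and relaxation parameters of the bSSFP rendering."""

    tr_ms: float = Field(1.38, gt=0)
    te_ms: float = Field(0.6, gt=0)
    flip_angle_deg: float = 25.0
    t1_ms: float = Field(1300.0, gt=0)
    t2_ms: float = Field(40.0, gt=0)
    phase_cycling_deg: float = 180.0
    m0: float = Field(1.0, gt=0)

    @model_validator(mode="after")
    def _check(self):
        if not self.te_ms < self.tr_ms:
            raise ValueError("te must be smaller than tr")
        if not 0 < self.flip_angle_deg < 180:
            raise ValueError("flip angle must lie in (0, 180) degrees")
        if self.t2_ms > self.t1_ms:
            raise ValueError("t2 must not exceed t1")
        return self


@dataclass
class MaskStats:
    """Summary statistics of a field over a mask."""

    mean_hz: float
    range_hz: float
    std_hz: float
    n_voxels: int
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    def to_dict(self) -> dict:
        return {
            "mean_hz": self.mean_hz,
            "range_hz": self.range_hz,
            "std_hz": self.std_hz,
            "n_voxels": self.n_voxels,
            "hist_counts": self.hist_counts.tolist(),
            "hist_edges": self.hist_edges.tolist(),
        }


def mask_stats(field: FieldMap, mask, bins: int = 50) -> MaskStats:
    """Mean, max-min range, std and histogram of the in-mask field."""
    m = mask.mask if isinstance(mask, LungMask) else np.asarray(mask, dtype=bool)
    m = m & field.valid_mask
    if not m.any():
        raise EmptyMaskError("no valid in-mask voxels")
    vals = field.nu_hat[m]
    counts, edges = np.histogram(vals, bins=bins)
    return MaskStats(
        mean_hz=float(vals.mean()),
        range_hz=float(vals.max() - vals.min()),
        std_hz=float(vals.std()),
        n_voxels=int(vals.size),
        hist_counts=counts,
        hist_edges=edges,
    )


def band_frequencies(params: BssfpParams, n_max: int = 1) -> np.ndarray:
    """Banding frequencies +-n/(2*TR) in Hz for odd n up to ``n_max``."""
    if n_max < 1:
        raise ConfigurationError("n_max must be >= 1")
    tr_s = params.tr_ms * 1e-3
    odd = np.arange(1, n_max + 1, 2, dtype=float)
    freqs = odd / (2.0 * tr_s)
    return np.sort(np.concatenate([-freqs, freqs]))


def bssfp_profile(params: BssfpParams, nu) -> np.ndarray:
    """Steady-state bSSFP transverse magnitude at off-resonance ``nu`` (Hz).

    Periodic in nu with period 1/TR and symmetric about 0; with 180-degree
    phase cycling the minima sit at +-1/(2*TR).
    """
    nu = np.asarray(nu, dtype=float)
    tr = params.tr_ms * 1e-3
    e1 = np.exp(-tr / (params.t1_ms * 1e-3))
    e2 = np.exp(-tr / (params.t2_ms * 1e-3))
    alpha = np.deg2rad(params.flip_angle_deg)
    theta = 2.0 * np.pi * nu * tr + np.deg2rad(params.phase_cycling_deg)
    ca, sa = np.cos(alpha), np.sin(alpha)
    ct = np.cos(theta)
    num = params.m0 * (1.0 - e1) * sa * np.abs(1.0 - e2 * np.exp(1j * theta))
    den = np.abs((1.0 - e1 * ca) * (1.0 - e2 * ct) - e2 * (e1 - ca) * (e2 - ct))
    return num / den


def render_bssfp(
    nu_map: np.ndarray | FieldMap,
    m0: np.ndarray,
    params: BssfpParams,
    mask=None,
    bins: int = 50,
):
    """Per-voxel bSSFP magnitude image, optionally with an in-mask histogram.

    Returns ``(image, (hist_counts, hist_edges) | None)``.
    """
    nu = nu_map.nu_hat if isinstance(nu_map, FieldMap) else np.asarray(nu_map, float)
    if nu.shape != np.asarray(m0).shape:
        raise ConfigurationError("nu map and m0 map shapes differ")
    image = np.asarray(m0, float) * bssfp_profile(params, nu)
    hist = None
    if mask is not None:
        m = mask.mask if isinstance(mask, LungMask) else np.asarray(mask, bool)
        counts, edges = np.histogram(image[m], bins=bins)
        hist = (counts, edges)
    return image, hist
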