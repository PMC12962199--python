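"""Voxel-wise off-resonance estimation from incremental echo phases.

Each voxel's complex echo signals are normalized to the first echo,
s_j1 = s_j / s_1, whose principal-value phases evolve linearly,

    phi_j1 = nu * 2*pi * (j-1)*dT + phi0 ,

so (nu_hat, phi0_hat) follow from an ordinary linear least-squares fit of
phase against echo index.  Because the inter-echo spacing is short, the
incremental phases stay inside (-pi, pi] for the off-resonance ranges of
interest and no unwrapping is required; a guard flags voxels whose
consecutive increments approach pi.  T2* is estimated from the slope of
log-magnitude against TE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DegenerateInputError
from .geometry import Geometry2D
from .phantom import EchoSeries

#: first-echo magnitude floor, as a fraction of the in-image 99th percentile
MAGNITUDE_FLOOR_FRAC = 0.05

#: consecutive incremental phase steps above this fraction of pi are suspect
WRAP_GUARD_FRAC = 0.9


@dataclass
class FieldMap:
    """Per-voxel off-resonance estimate and fit diagnostics."""

    nu_hat: np.ndarray             # Hz
    phi0_hat: np.ndarray           # rad
    residual_rms: np.ndarray       # rad
    precision_hz: np.ndarray       # frequency standard error, Hz
    valid_mask: np.ndarray         # bool
    wrap_suspect: np.ndarray | None = None
    intercept_dropped: bool = False
    geometry: Geometry2D | None = None


def incremental_ratios(series: EchoSeries):
    """Normalize every echo to the first: ratio_j = s_j / s_1.

    Returns ``(ratios, phases, valid_mask)`` where ``phases[j]`` is the
    principal argument of ratio_j (``phases[0]`` is identically 0) and
    ``valid_mask`` marks voxels whose first-echo magnitude is above the
    noise floor.  Expects a single-repetition (already averaged) series.
    """
    if series.n_reps != 1:
        raise ConfigurationError(
            f"expected a single averaged repetition, got {series.n_reps}"
        )
    s = series.data[0]
    mag1 = np.abs(s[0])
    floor = MAGNITUDE_FLOOR_FRAC * np.percentile(mag1, 99)
    valid = mag1 > floor

    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(valid, s / s[0:1], 0.0)
    ratios[0] = np.where(valid, 1.0, 0.0)
    phases = np.angle(ratios)
    phases[0] = 0.0
    return ratios, phases, valid


def fit_fieldmap(
    phases: np.ndarray,
    te_spacing: float,
    weights: np.ndarray | None = None,
    valid_mask: np.ndarray | None = None,
    geometry: Geometry2D | None = None,
) -> FieldMap:
    """Linear least-squares fit of incremental phase against echo time.

    ``phases`` has shape (n_echoes, rows, cols); ``te_spacing`` is the
    inter-echo spacing in microseconds.  With only two echoes the intercept
    is underdetermined and forced to zero (flagged on the output).  The
    per-voxel frequency standard error follows from the fit residuals and
    the design matrix.
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.shape[0]
    if n < 2:
        raise ConfigurationError("at least 2 echoes are required")
    if valid_mask is None:
        valid_mask = np.ones(phases.shape[1:], dtype=bool)
    if not np.any(valid_mask):
        raise DegenerateInputError("no valid voxels to fit")
    if not np.all(np.isfinite(phases[:, valid_mask])):
        raise ConfigurationError("non-finite phases on valid voxels")

    dt_s = te_spacing * 1e-6
    t = np.arange(n, dtype=float) * dt_s           # (j-1)*dT, seconds
    tc = t[:, None, None]

    steps = np.abs(np.diff(phases, axis=0))
    wrap_suspect = np.any(steps > WRAP_GUARD_FRAC * np.pi, axis=0) & valid_mask

    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != phases.shape:
            raise ConfigurationError("weights must match phases shape")
    else:
        w = np.ones_like(phases)

    if n == 2:
        # regression through the origin: phi0 fixed at 0
        slope = phases[1] / dt_s
        intercept = np.zeros_like(slope)
        resid = np.zeros_like(phases)
        intercept_dropped = True
    else:
        sw = w.sum(axis=0)
        t_mean = (w * tc).sum(axis=0) / sw
        p_mean = (w * phases).sum(axis=0) / sw
        stt = (w * (tc - t_mean) ** 2).sum(axis=0)
        stp = (w * (tc - t_mean) * (phases - p_mean)).sum(axis=0)
        slope = stp / stt
        intercept = p_mean - slope * t_mean
        resid = phases - (slope * tc + intercept)
        intercept_dropped = False

    nu_hat = slope / (2.0 * np.pi)
    residual_rms = np.sqrt(np.mean(resid**2, axis=0))

    if n > 2:
        stt_u = np.sum((t - t.mean()) ** 2)
        rss = np.sum(resid**2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            se_slope = np.sqrt(rss / (n - 2) / stt_u)
        precision_hz = se_slope / (2.0 * np.pi)
    else:
        precision_hz = np.full_like(nu_hat, np.inf)

    invalid = ~valid_mask
    for arr in (nu_hat, intercept, residual_rms, precision_hz):
        arr[invalid] = 0.0
    precision_hz[invalid] = np.inf

    return FieldMap(
        nu_hat=nu_hat,
        phi0_hat=intercept,
        residual_rms=residual_rms,
        precision_hz=precision_hz,
        valid_mask=valid_mask.copy(),
        wrap_suspect=wrap_suspect,
        intercept_dropped=intercept_dropped,
        geometry=geometry,
    )


def fieldmap_from_series(
    series: EchoSeries, weights_from_magnitude: bool = False
) -> FieldMap:
    """Convenience wrapper: incremental normalization followed by the fit."""
    ratios, phases, valid = incremental_ratios(series)
    weights = np.abs(ratios) if weights_from_magnitude else None
    return fit_fieldmap(
        phases,
        te_spacing=series.delta_t,
        weights=weights,
        valid_mask=valid,
        geometry=series.geometry,
    )


def estimate_t2star(magnitudes: np.ndarray, te_list: np.ndarray):
    """T2* from the slope of log-magnitude against TE.

    ``magnitudes`` has shape (n_echoes, ...) and ``te_list`` is in
    microseconds; returns ``(t2star_us, r_squared, valid)``.  Voxels with a
    non-positive magnitude at any echo are invalid; non-decaying voxels get
    a T2* of +inf with undefined (NaN) R^2.
    """
    m = np.asarray(magnitudes, dtype=float)
    te = np.asarray(te_list, dtype=float)
    n = m.shape[0]
    if te.size != n or n < 2:
        raise ConfigurationError("te_list must match the echo axis (>= 2 echoes)")
    valid = np.all(m > 0, axis=0)

    logm = np.where(m > 0, np.log(np.where(m > 0, m, 1.0)), 0.0)
    tc = te.reshape((n,) + (1,) * (m.ndim - 1))
    t_mean = te.mean()
    y_mean = logm.mean(axis=0)
    stt = np.sum((te - t_mean) ** 2)
    slope = ((tc - t_mean) * (logm - y_mean)).sum(axis=0) / stt
    resid = logm - (y_mean + slope * (tc - t_mean))
    rss = np.sum(resid**2, axis=0)
    tss = np.sum((logm - y_mean) ** 2, axis=0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t2star = np.where(slope < 0, -1.0 / slope, np.inf)
        r2 = np.where(tss > 0, 1.0 - rss / tss, np.nan)
    t2star = np.where(valid, t2star, np.nan)
    r2 = np.where(valid, r2, np.nan)
    return t2star, r2, valid
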