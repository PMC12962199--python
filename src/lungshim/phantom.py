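"""Synthetic 2D coronal thorax phantom and TR-shifted multi-echo simulation.

The phantom provides ground truth for every downstream stage: a proton
density map with a body ellipse and two lung regions, an ultra-short lung
T2*, a structured off-resonance field (negative above the diaphragm,
positive near the apex) rescaled to requested in-lung statistics, and
per-repetition respiratory deformations.  The forward model per voxel and
echo j is

    s_j = M0 * exp(-TE_j / T2*) * exp(i * (2*pi*nu*TE_j + phi0)) + n_j

with TE_j = (j-1) * dT + TE_1 and n_j complex Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field
from scipy import ndimage

from .errors import ConfigurationError, InvalidGeometryError
from .geometry import Geometry2D


class PhantomParams(BaseModel):
    """Configuration of the thorax phantom."""

    matrix: int = 128
    fov_mm: float = 450.0
    slice_y_mm: float = 0.0

    # tissue values
    soft_m0: float = Field(1.0, gt=0)
    lung_m0: float = Field(0.25, gt=0)
    soft_t2star_us: float = Field(20000.0, gt=0)   # >= 10 ms
    lung_t2star_us: float = Field(640.0, gt=0)
    phi0_base_rad: float = 0.2
    phi0_gradient_rad: float = 0.15                # smooth spatial phi0 variation
    m0_texture: float = Field(0.10, ge=0)          # relative smooth texture in body

    # off-resonance field model (amplitudes before rescaling)
    background_linear_hz: float = 30.0
    background_quad_hz: float = 20.0
    diaphragm_amplitude_hz: float = -120.0         # negative blob above diaphragm
    apex_amplitude_hz: float = 90.0                # positive blob near apex
    blob_sigma_frac: float = Field(0.10, gt=0)     # Gaussian width / matrix

    # requested in-lung statistics; None disables rescaling
    nu_target_mean_hz: float | None = 85.0
    nu_target_range_hz: float | None = 434.0


@dataclass
class PhantomTruth:
    """Ground-truth maps of the phantom."""

    m0_map: np.ndarray          # proton density scale, a.u.
    t2star_map: np.ndarray      # us
    nu_map: np.ndarray          # Hz
    phi0_map: np.ndarray        # rad
    lung_mask: np.ndarray       # bool
    body_mask: np.ndarray       # bool
    deformations: list | None = None   # per-repetition (2, R, C) displacement, px


@dataclass
class EchoSeries:
    """Complex image stack indexed [repetition, echo, row, col]."""

    data: np.ndarray            # complex128
    te_list: np.ndarray         # us, strictly increasing, constant spacing
    delta_t: float              # us
    geometry: Geometry2D

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.complex128)
        self.te_list = np.asarray(self.te_list, dtype=float)
        if self.data.ndim != 4:
            raise ConfigurationError("data must be [rep, echo, row, col]")
        if self.te_list.size != self.data.shape[1]:
            raise ConfigurationError("te_list length must match echo axis")
        if self.te_list.size < 2:
            raise ConfigurationError("at least 2 echoes are required")
        spacings = np.diff(self.te_list)
        if not np.all(spacings > 0) or not np.allclose(spacings, self.delta_t):
            raise ConfigurationError(
                "te_list must be strictly increasing with constant spacing delta_t"
            )

    @property
    def n_reps(self) -> int:
        return self.data.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[1]

    def magnitude(self, rep: int, echo: int) -> np.ndarray:
        return np.abs(self.data[rep, echo])


def make_te_list(te1: float, delta_t: float, n_echoes: int) -> np.ndarray:
    """TE_j = (j-1)*dT + TE_1 for j = 1..n, in the units of the inputs."""
    if te1 <= 0 or delta_t <= 0:
        raise ConfigurationError("te1 and delta_t must be positive")
    if n_echoes < 2:
        raise ConfigurationError("n_echoes must be >= 2 for field mapping")
    return te1 + delta_t * np.arange(n_echoes, dtype=float)


def _ellipse(rows, cols, center_rc, semi_rc):
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    return ((r - center_rc[0]) / semi_rc[0]) ** 2 + (
        (c - center_rc[1]) / semi_rc[1]
    ) ** 2 <= 1.0


def _gaussian_blob(rows, cols, center_rc, sigma_px):
    r = np.arange(rows)[:, None]
    c = np.arange(cols)[None, :]
    return np.exp(
        -(((r - center_rc[0]) ** 2 + (c - center_rc[1]) ** 2) / (2.0 * sigma_px**2))
    )


def make_phantom(params: PhantomParams, seed: int) -> tuple[PhantomTruth, Geometry2D]:
    """Build ground-truth maps for a two-lung coronal thorax phantom.

    The off-resonance field is a low-order harmonic background plus negative
    Gaussian perturbations above the diaphragm and positive ones near the
    apex of each lung, affinely rescaled so the in-lung mean and max-min
    range match the requested targets exactly.
    """
    n = int(params.matrix)
    if n < 32:
        raise InvalidGeometryError(f"matrix must be >= 32, got {n}")
    geometry = Geometry2D(
        matrix=(n, n), fov_mm=(params.fov_mm, params.fov_mm), slice_y_mm=params.slice_y_mm
    )
    rng = np.random.default_rng(seed)
    rows = cols = n

    body = _ellipse(rows, cols, (0.50 * n, 0.50 * n), (0.42 * n, 0.40 * n))

    # lungs: two ellipses, right lung (image left) slightly larger
    lung_r = _ellipse(rows, cols, (0.44 * n, 0.325 * n), (0.27 * n, 0.135 * n))
    lung_l = _ellipse(rows, cols, (0.45 * n, 0.675 * n), (0.25 * n, 0.125 * n))
    lungs = (lung_r | lung_l) & body
    lab, ncomp = ndimage.label(lungs)
    if ncomp != 2:
        raise ConfigurationError("lung regions merged or split; adjust geometry")

    m0 = np.zeros((rows, cols))
    m0[body] = params.soft_m0
    m0[lungs] = params.lung_m0
    if params.m0_texture > 0:
        texture = ndimage.gaussian_filter(rng.standard_normal((rows, cols)), 0.06 * n)
        texture /= max(np.abs(texture).max(), 1e-12)
        m0[body] *= 1.0 + params.m0_texture * texture[body]

    t2star = np.full((rows, cols), params.soft_t2star_us)
    t2star[lungs] = params.lung_t2star_us

    # off-resonance: harmonic background + diaphragm/apex perturbations
    z_mm, x_mm = geometry.coordinate_grids()
    zn = z_mm / (params.fov_mm / 2.0)
    xn = x_mm / (params.fov_mm / 2.0)
    nu = params.background_linear_hz * (0.6 * zn + 0.3 * xn)
    nu += params.background_quad_hz * (zn**2 - 0.5 * xn**2)

    sig = params.blob_sigma_frac * n
    for lung in (lung_r, lung_l):
        rr, cc = np.nonzero(lung)
        c_mid = cc.mean()
        r_bottom, r_top = rr.max(), rr.min()
        nu += params.diaphragm_amplitude_hz * _gaussian_blob(
            rows, cols, (r_bottom, c_mid), sig
        )
        nu += params.apex_amplitude_hz * _gaussian_blob(rows, cols, (r_top, c_mid), sig)

    if params.nu_target_mean_hz is not None or params.nu_target_range_hz is not None:
        vals = nu[lungs]
        raw_mean = vals.mean()
        raw_range = vals.max() - vals.min()
        scale = 1.0
        if params.nu_target_range_hz is not None:
            if raw_range <= 0:
                raise ConfigurationError(
                    "in-lung field is constant; requested range is infeasible"
                )
            scale = params.nu_target_range_hz / raw_range
        target_mean = (
            params.nu_target_mean_hz
            if params.nu_target_mean_hz is not None
            else scale * raw_mean
        )
        nu = scale * (nu - raw_mean) + target_mean

    phi0 = params.phi0_base_rad + params.phi0_gradient_rad * (0.5 * zn - 0.3 * xn)

    truth = PhantomTruth(
        m0_map=m0,
        t2star_map=t2star,
        nu_map=nu,
        phi0_map=phi0,
        lung_mask=lungs,
        body_mask=body,
    )
    return truth, geometry


def make_respiratory_deformations(
    truth: PhantomTruth,
    n_reps: int,
    motion_amplitude: float,
    seed: int,
    residual_frac: float = 0.1,
) -> list[np.ndarray]:
    """Per-repetition (2, R, C) displacement fields in pixels.

    Repetition 0 is the undeformed reference.  Motion is dominated by a
    head-foot translation concentrated at and below the diaphragm,
    sinusoidal in the repetition index, plus a small smooth random residual.
    """
    rows, cols = truth.m0_map.shape
    rng = np.random.default_rng(seed)
    rr = np.nonzero(truth.lung_mask)[0]
    diaphragm_row = rr.max() if rr.size else int(0.7 * rows)
    r_idx = np.arange(rows)[:, None] * np.ones((1, cols))
    weight = 1.0 / (1.0 + np.exp(-(r_idx - diaphragm_row) / (0.05 * rows)))
    weight = ndimage.gaussian_filter(weight, 0.03 * rows)

    fields = []
    for r in range(n_reps):
        d = np.zeros((2, rows, cols))
        if r > 0 and motion_amplitude != 0:
            phase = np.sin(2.0 * np.pi * r / n_reps)
            d[0] = motion_amplitude * phase * weight
            for axis in range(2):
                noise = ndimage.gaussian_filter(
                    rng.standard_normal((rows, cols)), 0.1 * rows
                )
                noise /= max(np.abs(noise).max(), 1e-12)
                d[axis] += residual_frac * motion_amplitude * phase * noise
        fields.append(d)
    return fields


def _warp_map(img: np.ndarray, disp: np.ndarray) -> np.ndarray:
    """Pull-back warp: out(p) = img(p + disp(p)), linear interpolation."""
    rows, cols = img.shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.stack([rr + disp[0], cc + disp[1]])
    return ndimage.map_coordinates(img, coords, order=1, mode="nearest")


def simulate_echo_series(
    truth: PhantomTruth,
    geometry: Geometry2D,
    te1: float,
    delta_t: float,
    n_echoes: int,
    n_reps: int,
    snr: float,
    motion_amplitude: float,
    seed: int,
) -> EchoSeries:
    """Simulate the TR-shifted multi-echo GRE acquisition.

    ``te1``/``delta_t`` are in microseconds.  Noise sigma per complex channel
    is (mean in-lung first-echo magnitude) / snr; ``snr=np.inf`` disables
    noise.  Each repetition is warped by its respiratory deformation before
    the signal model is evaluated; the generated deformations are stored in
    ``truth.deformations`` for use as an oracle.
    """
    if snr <= 0:
        raise ConfigurationError("snr must be positive")
    rows, cols = truth.m0_map.shape
    if abs(motion_amplitude) >= min(rows, cols):
        raise ConfigurationError("motion amplitude exceeds image extent")
    te_list = make_te_list(te1, delta_t, n_echoes)
    rng = np.random.default_rng(seed)

    deformations = make_respiratory_deformations(
        truth, n_reps, motion_amplitude, seed=seed
    )
    truth.deformations = deformations

    te_s = te_list * 1e-6
    data = np.empty((n_reps, n_echoes, rows, cols), dtype=np.complex128)
    for r in range(n_reps):
        disp = deformations[r]
        if np.any(disp):
            m0 = _warp_map(truth.m0_map, disp)
            t2 = _warp_map(truth.t2star_map, disp)
            nu = _warp_map(truth.nu_map, disp)
            phi0 = _warp_map(truth.phi0_map, disp)
        else:
            m0, t2, nu, phi0 = (
                truth.m0_map,
                truth.t2star_map,
                truth.nu_map,
                truth.phi0_map,
            )
        for j in range(n_echoes):
            mag = m0 * np.exp(-te_list[j] / t2)
            phase = 2.0 * np.pi * nu * te_s[j] + phi0
            data[r, j] = mag * np.exp(1j * phase)

    if np.isfinite(snr):
        ref = truth.m0_map * np.exp(-te_list[0] / truth.t2star_map)
        sigma = ref[truth.lung_mask].mean() / snr
        noise = rng.normal(scale=sigma, size=(2, n_reps, n_echoes, rows, cols))
        data += noise[0] + 1j * noise[1]

    return EchoSeries(data=data, te_list=te_list, delta_t=float(delta_t), geometry=geometry)
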