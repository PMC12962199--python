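"""NIfTI and sidecar I/O for echo series, truth maps, field maps and masks.

An echo series is stored as a magnitude/phase NIfTI pair per repetition
(4D: rows x cols x 1 x echoes) plus a JSON sidecar carrying the echo-time
list (microseconds), the inter-echo spacing and the geometry.  Real/
imaginary pairs are also accepted on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConfigurationError
from .fieldmap import FieldMap
from .geometry import Geometry2D
from .phantom import EchoSeries, PhantomTruth

SIDECAR_NAME = "series.json"


def _to_nifti(array_2d_stack: np.ndarray, geometry: Geometry2D) -> nib.Nifti1Image:
    # (echo, row, col) -> (row, col, 1, echo) so viewers see a 4D time series
    if array_2d_stack.ndim == 2:
        vol = array_2d_stack[:, :, None]
    else:
        vol = np.moveaxis(array_2d_stack, 0, -1)[:, :, None, :]
    return nib.Nifti1Image(np.asarray(vol, dtype=np.float64), geometry.affine())


def _from_nifti(path) -> np.ndarray:
    vol = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
    vol = np.squeeze(vol)
    if vol.ndim == 2:
        return vol
    if vol.ndim == 3:
        return np.moveaxis(vol, -1, 0)
    raise ConfigurationError(f"unsupported NIfTI dimensionality in {path}")


def write_echo_series(series: EchoSeries, outdir) -> Path:
    """Write magnitude/phase NIfTI pairs per repetition plus the sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for r in range(series.n_reps):
        mag = np.abs(series.data[r])
        pha = np.angle(series.data[r])
        nib.save(_to_nifti(mag, series.geometry), outdir / f"rep{r + 1:02d}_mag.nii")
        nib.save(_to_nifti(pha, series.geometry), outdir / f"rep{r + 1:02d}_phase.nii")
    sidecar = {
        "te_list_us": series.te_list.tolist(),
        "delta_t_us": series.delta_t,
        "n_reps": series.n_reps,
        "geometry": series.geometry.to_dict(),
        "pairs": "magnitude_phase",
    }
    (outdir / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2) + "\n")
    return outdir / SIDECAR_NAME


def read_echo_series(indir) -> EchoSeries:
    """Read an echo series written by :func:`write_echo_series`.

    Also accepts ``repNN_real.nii`` / ``repNN_imag.nii`` pairs when the
    sidecar says ``"pairs": "real_imaginary"``.
    """
    indir = Path(indir)
    sidecar_path = indir / SIDECAR_NAME
    if not sidecar_path.exists():
        raise ConfigurationError(f"missing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    geometry = Geometry2D.from_dict(sidecar["geometry"])
    n_reps = int(sidecar["n_reps"])
    pairs = sidecar.get("pairs", "magnitude_phase")

    reps = []
    for r in range(1, n_reps + 1):
        if pairs == "magnitude_phase":
            a = _find_volume(indir, f"rep{r:02d}_mag")
            b = _find_volume(indir, f"rep{r:02d}_phase")
            reps.append(a * np.exp(1j * b))
        elif pairs == "real_imaginary":
            a = _find_volume(indir, f"rep{r:02d}_real")
            b = _find_volume(indir, f"rep{r:02d}_imag")
            reps.append(a + 1j * b)
        else:
            raise ConfigurationError(f"unknown pair convention {pairs!r}")
    data = np.stack(reps)
    return EchoSeries(
        data=data,
        te_list=np.asarray(sidecar["te_list_us"], dtype=float),
        delta_t=float(sidecar["delta_t_us"]),
        geometry=geometry,
    )


def _find_volume(indir: Path, stem: str) -> np.ndarray:
    for ext in (".nii", ".nii.gz"):
        p = indir / (stem + ext)
        if p.exists():
            return _from_nifti(p)
    raise ConfigurationError(f"missing volume {stem}.nii under {indir}")


def write_map(array: np.ndarray, geometry: Geometry2D, path) -> None:
    """Write a single 2D map (field, mask, precision, ...) as NIfTI."""
    nib.save(_to_nifti(np.asarray(array, dtype=float), geometry), str(path))


def read_map(path) -> np.ndarray:
    return _from_nifti(path)


def write_truth(truth: PhantomTruth, geometry: Geometry2D, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_map(truth.m0_map, geometry, outdir / "truth_m0.nii")
    write_map(truth.t2star_map, geometry, outdir / "truth_t2star_us.nii")
    write_map(truth.nu_map, geometry, outdir / "truth_nu_hz.nii")
    write_map(truth.phi0_map, geometry, outdir / "truth_phi0_rad.nii")
    write_map(truth.lung_mask.astype(float), geometry, outdir / "truth_lung_mask.nii")


def write_fieldmap(fmap: FieldMap, geometry: Geometry2D, outdir, prefix="fieldmap") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_map(fmap.nu_hat, geometry, outdir / f"{prefix}_nu_hz.nii")
    write_map(fmap.phi0_hat, geometry, outdir / f"{prefix}_phi0_rad.nii")
    write_map(fmap.residual_rms, geometry, outdir / f"{prefix}_residual_rms_rad.nii")
    prec = np.where(np.isfinite(fmap.precision_hz), fmap.precision_hz, 0.0)
    write_map(prec, geometry, outdir / f"{prefix}_precision_hz.nii")
    write_map(fmap.valid_mask.astype(float), geometry, outdir / f"{prefix}_valid.nii")
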