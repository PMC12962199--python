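"""Spherical-harmonic shim basis, mask-restricted solve, and config file I/O.

The zeroth-to-second-order basis sampled on the slice at (x, z, y=0), in
the fixed column order

    [1, z, x, y, z^2 - (x^2 + y^2)/2, z*x, z*y, x^2 - y^2, x*y],

has columns 3, 6 and 8 identically zero under the y = 0 convention of a
single coronal slice; those coefficients are excluded from the fit and
pinned to zero.  Coefficients are kept in field units (Hz, Hz/mm,
Hz/mm^2); conversion to hardware currents is a calibration outside scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    EmptyMaskError,
    InvalidGeometryError,
    RankDeficientError,
    ShimConfigParseError,
)
from .fieldmap import FieldMap
from .geometry import Geometry2D

BASIS_NAMES = ("1", "z", "x", "y", "z2-(x2+y2)/2", "zx", "zy", "x2-y2", "xy")
EXCLUDED_DEFAULT = frozenset({3, 6, 8})

#: config-file keys for the retained coefficients, in index order
CONFIG_KEYS = {
    0: "f0_offset_hz",
    1: "c1_z_hz_per_mm",
    2: "c2_x_hz_per_mm",
    4: "c4_z2_hz_per_mm2",
    5: "c5_zx_hz_per_mm2",
    7: "c7_x2y2_hz_per_mm2",
}


@dataclass
class ShimBasis:
    """The nine basis functions sampled on the image grid (y = 0)."""

    functions: np.ndarray              # (9, rows, cols), mm units
    geometry: Geometry2D
    excluded: frozenset = EXCLUDED_DEFAULT
    names: tuple = BASIS_NAMES

    @property
    def n_functions(self) -> int:
        return self.functions.shape[0]

    def design_matrix(self, mask: np.ndarray, excluded=None) -> tuple[np.ndarray, list]:
        """Stack in-mask samples of the retained columns; returns (A, kept)."""
        excluded = self.excluded if excluded is None else frozenset(excluded)
        kept = [k for k in range(self.n_functions) if k not in excluded]
        a = np.stack([self.functions[k][mask] for k in kept], axis=1)
        return a, kept


@dataclass
class ShimSolution:
    """Nine harmonic coefficients with the y-dependent set pinned to zero."""

    coefficients: np.ndarray           # (9,): Hz, Hz/mm, Hz/mm^2
    excluded: frozenset = EXCLUDED_DEFAULT
    residual_ss: float = 0.0           # in-mask residual sum of squares, Hz^2
    unshimmed_ss: float = 0.0
    condition_number: float = 0.0
    n_voxels: int = 0

    @property
    def f0_offset_hz(self) -> float:
        return float(self.coefficients[0])


def build_basis(geometry: Geometry2D, order: int = 2) -> ShimBasis:
    """Sample the spherical-harmonic shim fields on the grid at y = 0."""
    if order > 2 or order < 0:
        raise InvalidGeometryError("only orders 0..2 are supported")
    z, x = geometry.coordinate_grids()
    y = np.zeros_like(x)               # y = 0 convention for the coronal slice
    cols = [
        np.ones_like(x),
        z,
        x,
        y,
        z**2 - (x**2 + y**2) / 2.0,
        z * x,
        z * y,
        x**2 - y**2,
        x * y,
    ]
    n_keep = {0: 1, 1: 4, 2: 9}[order]
    funcs = np.stack(cols[:n_keep])
    excluded = frozenset(k for k in EXCLUDED_DEFAULT if k < n_keep)
    return ShimBasis(
        functions=funcs,
        geometry=geometry,
        excluded=excluded,
        names=BASIS_NAMES[:n_keep],
    )


def solve_shim(
    field: FieldMap,
    mask: np.ndarray,
    basis: ShimBasis,
    excluded=EXCLUDED_DEFAULT,
) -> ShimSolution:
    """Least-squares shim coefficients over the masked field.

    Columns in ``excluded`` are removed from the design and their
    coefficients set to exactly zero.  The solver column-scales internally
    for conditioning and rescales the coefficients on output.
    """
    mask = np.asarray(mask, dtype=bool)
    m = mask & field.valid_mask
    if not np.any(m):
        raise EmptyMaskError("mask contains no valid voxels")
    a_raw, kept = basis.design_matrix(m, excluded=excluded)
    # identically-zero columns (e.g. y terms retained by the caller) carry no
    # signal; pin their coefficients to zero instead of failing the rank check
    nonzero = np.any(a_raw != 0, axis=0)
    a_raw = a_raw[:, nonzero]
    kept = [k for k, keep in zip(kept, nonzero) if keep]
    b = field.nu_hat[m]
    if b.size < len(kept):
        raise EmptyMaskError(
            f"only {b.size} in-mask voxels for {len(kept)} unknowns"
        )

    col_scale = np.max(np.abs(a_raw), axis=0)
    col_scale[col_scale == 0] = 1.0
    a = a_raw / col_scale

    u_svals = np.linalg.svd(a, compute_uv=False)
    tol = max(a.shape) * np.finfo(float).eps * u_svals[0]
    rank = int(np.sum(u_svals > tol))
    if rank < len(kept):
        _, _, vt = np.linalg.svd(a, full_matrices=False)
        null = vt[rank:]
        deficient = sorted(
            {kept[j] for row in null for j in np.nonzero(np.abs(row) > 0.3)[0]}
        )
        names = [BASIS_NAMES[k] for k in deficient]
        raise RankDeficientError(
            f"shim design is rank deficient over this mask; "
            f"undetermined directions: {names}",
            deficient_columns=deficient,
        )

    sol, _, _, _ = np.linalg.lstsq(a, b, rcond=None)
    coeffs = np.zeros(9)
    coeffs[kept] = sol / col_scale

    fit = a_raw @ (coeffs[kept])
    residual_ss = float(np.sum((b - fit) ** 2))
    return ShimSolution(
        coefficients=coeffs,
        excluded=frozenset(excluded),
        residual_ss=residual_ss,
        unshimmed_ss=float(np.sum(b**2)),
        condition_number=float(u_svals[0] / u_svals[-1]),
        n_voxels=int(b.size),
    )


def predict_residual(field: FieldMap, solution: ShimSolution, basis: ShimBasis) -> FieldMap:
    """Residual field nu_hat - a . c_hat after applying the shim."""
    if field.nu_hat.shape != basis.functions.shape[1:]:
        raise InvalidGeometryError("field and basis geometries differ")
    correction = np.tensordot(solution.coefficients, basis.functions, axes=1)
    return FieldMap(
        nu_hat=field.nu_hat - correction,
        phi0_hat=field.phi0_hat.copy(),
        residual_rms=field.residual_rms.copy(),
        precision_hz=field.precision_hz.copy(),
        valid_mask=field.valid_mask.copy(),
        wrap_suspect=None if field.wrap_suspect is None else field.wrap_suspect.copy(),
        geometry=field.geometry,
    )


# ---------------------------------------------------------------------------
# plain-text shim configuration file
# ---------------------------------------------------------------------------

def write_shim_config(
    path, solution: ShimSolution, geometry: Geometry2D | None = None
) -> None:
    """Write the structured plain-text shim configuration file.

    Fixed key names, floats with 6 decimals; deterministic output so that a
    write -> read -> write round trip is byte-identical.
    """
    lines = ["# lungshim shim configuration", "# format_version = 1"]
    if geometry is not None:
        lines += [
            "",
            "# geometry",
            f"matrix_rows = {geometry.matrix[0]}",
            f"matrix_cols = {geometry.matrix[1]}",
            f"fov_z_mm = {geometry.fov_mm[0]:.6f}",
            f"fov_x_mm = {geometry.fov_mm[1]:.6f}",
            f"slice_y_mm = {geometry.slice_y_mm:.6f}",
        ]
    lines += ["", "# shim coefficients"]
    for idx in sorted(CONFIG_KEYS):
        lines.append(f"{CONFIG_KEYS[idx]} = {solution.coefficients[idx]:.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_shim_config(path) -> ShimSolution:
    """Parse a shim configuration file back into a :class:`ShimSolution`.

    Raises :class:`ShimConfigParseError` listing missing keys or malformed
    lines.
    """
    path = Path(path)
    values: dict[str, float] = {}
    bad_lines = []
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            bad_lines.append(f"line {ln}: {raw!r}")
            continue
        key, _, val = line.partition("=")
        try:
            values[key.strip()] = float(val.strip())
        except ValueError:
            bad_lines.append(f"line {ln}: {raw!r}")
    missing = [CONFIG_KEYS[i] for i in sorted(CONFIG_KEYS) if CONFIG_KEYS[i] not in values]
    if missing or bad_lines:
        raise ShimConfigParseError(
            "invalid shim configuration: "
            + (f"missing keys {missing}" if missing else "")
            + ("; " if missing and bad_lines else "")
            + (f"malformed lines {bad_lines}" if bad_lines else ""),
            missing_keys=missing,
            bad_lines=bad_lines,
        )
    coeffs = np.zeros(9)
    for idx, key in CONFIG_KEYS.items():
        coeffs[idx] = values[key]
    return ShimSolution(coefficients=coeffs)
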