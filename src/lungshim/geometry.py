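"""Image geometry for 2D coronal slices.

Rows index the head-foot (z) direction with superior at the top, columns
index left-right (x).  Physical coordinates are in millimetres with the
image centre at isocenter: x increases with column index, z decreases with
row index.  The anterior-posterior (y) position of the slice is carried as
metadata; shim basis functions are evaluated at y = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError


@dataclass(frozen=True)
class Geometry2D:
    """Matrix size, field of view and slice offset of a coronal 2D image."""

    matrix: tuple[int, int]          # (rows, cols) = (z, x)
    fov_mm: tuple[float, float]      # (z extent, x extent) in mm
    slice_y_mm: float = 0.0

    def __post_init__(self):
        rows, cols = self.matrix
        fz, fx = self.fov_mm
        if rows <= 0 or cols <= 0:
            raise InvalidGeometryError(f"matrix must be positive, got {self.matrix}")
        if fz <= 0 or fx <= 0:
            raise InvalidGeometryError(f"fov_mm must be positive, got {self.fov_mm}")

    @property
    def pixel_mm(self) -> tuple[float, float]:
        """Pixel size (row spacing, col spacing) in mm."""
        return (self.fov_mm[0] / self.matrix[0], self.fov_mm[1] / self.matrix[1])

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix

    def coordinate_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (z_mm, x_mm) arrays of shape ``matrix``.

        The image centre (pixel index (rows-1)/2, (cols-1)/2) maps to
        (z, x) = (0, 0).
        """
        rows, cols = self.matrix
        dz, dx = self.pixel_mm
        r = np.arange(rows)[:, None].astype(float)
        c = np.arange(cols)[None, :].astype(float)
        z = ((rows - 1) / 2.0 - r) * dz * np.ones((1, cols))
        x = (c - (cols - 1) / 2.0) * dx * np.ones((rows, 1))
        return z, x

    def affine(self) -> np.ndarray:
        """NIfTI-style 4x4 affine mapping (row, col, 0) voxel indices to mm.

        Axis order in world space is (x, y, z) with y fixed at slice_y_mm.
        """
        rows, cols = self.matrix
        dz, dx = self.pixel_mm
        aff = np.zeros((4, 4))
        aff[0, 1] = dx                       # x grows with column
        aff[1, 2] = 1.0                      # unit scale for the singleton y axis
        aff[2, 0] = -dz                      # z shrinks with row
        aff[0, 3] = -(cols - 1) / 2.0 * dx
        aff[1, 3] = self.slice_y_mm
        aff[2, 3] = (rows - 1) / 2.0 * dz
        aff[3, 3] = 1.0
        return aff

    def to_dict(self) -> dict:
        return {
            "matrix": list(self.matrix),
            "fov_mm": list(self.fov_mm),
            "slice_y_mm": self.slice_y_mm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Geometry2D":
        return cls(
            matrix=tuple(int(v) for v in d["matrix"]),
            fov_mm=tuple(float(v) for v in d["fov_mm"]),
            slice_y_mm=float(d.get("slice_y_mm", 0.0)),
        )


def check_same_geometry(a: Geometry2D, b: Geometry2D) -> None:
    if a.matrix != b.matrix or not np.allclose(a.fov_mm, b.fov_mm):
        raise InvalidGeometryError(f"geometry mismatch: {a} vs {b}")
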