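"""Lung segmentation from the first-echo magnitude image.

A deterministic classical pipeline stands in for a learned segmenter with
the same contract: threshold the body, find low-intensity candidate
regions inside it, clean them up morphologically, and keep the two largest
components that pass area, border and centrality constraints.  An external
mask can always be supplied instead (see the pipeline's mask override).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field
from scipy import ndimage
from skimage import filters, morphology

from .errors import DegenerateInputError, EmptyMaskError
from .geometry import Geometry2D


class SegmentationSettings(BaseModel):
    """Tuning knobs of the classical lung segmenter."""

    min_area_frac: float = Field(0.005, gt=0)     # of image area
    opening_radius: int = Field(2, ge=0)
    closing_radius: int = Field(2, ge=0)
    central_column_frac: float = Field(0.08, ge=0)  # trachea rejection half-width
    max_components: int = 2


@dataclass
class LungMask:
    """Binary lung region used to restrict the shim fit."""

    mask: np.ndarray
    component_count: int
    geometry: Geometry2D | None = None


def segment_lungs(
    magnitude: np.ndarray,
    settings: SegmentationSettings | None = None,
    geometry: Geometry2D | None = None,
) -> LungMask:
    """Segment the lungs as the two largest dark regions inside the body.

    Thresholds are derived from the image itself (Otsu on normalized
    intensities), so the output is invariant under global intensity
    scaling.  Raises :class:`DegenerateInputError` for a constant image and
    :class:`EmptyMaskError` when no candidate region survives.
    """
    settings = settings or SegmentationSettings()
    img = np.asarray(magnitude, dtype=float)
    if img.ndim != 2:
        raise DegenerateInputError("expected a 2D magnitude image")
    if np.ptp(img) == 0:
        raise DegenerateInputError("constant image cannot be segmented")
    img = img / np.percentile(img, 99)

    body_thr = filters.threshold_otsu(img)
    bright = img > body_thr
    bright = morphology.closing(bright, morphology.disk(settings.closing_radius))
    body = ndimage.binary_fill_holes(bright)
    lab, n = ndimage.label(body)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
        body = lab == (1 + int(np.argmax(sizes)))

    inside = body & ~bright
    if not inside.any():
        raise EmptyMaskError("no low-intensity candidate regions inside the body")
    lung_thr = filters.threshold_otsu(img[body])
    candidates = body & (img < lung_thr)
    if settings.opening_radius:
        candidates = morphology.opening(
            candidates, morphology.disk(settings.opening_radius)
        )
    candidates &= ~_border_components(candidates)

    lab, n = ndimage.label(candidates)
    if n == 0:
        raise EmptyMaskError("no lung candidate components found")
    rows, cols = img.shape
    min_area = settings.min_area_frac * rows * cols
    center_col = (cols - 1) / 2.0
    half_width = settings.central_column_frac * cols

    comps = []
    for k in range(1, n + 1):
        comp = lab == k
        area = comp.sum()
        if area < min_area:
            continue
        centroid_col = np.nonzero(comp)[1].mean()
        if abs(centroid_col - center_col) < half_width:
            continue  # central airway / trachea
        comps.append((area, k))
    if not comps:
        raise EmptyMaskError(
            "all candidate components rejected by area/centrality constraints"
        )
    comps.sort(reverse=True)
    keep = [k for _, k in comps[: settings.max_components]]
    mask = np.isin(lab, keep)
    if settings.closing_radius:
        mask = morphology.closing(mask, morphology.disk(settings.closing_radius))
        mask &= body
    _, count = ndimage.label(mask)
    return LungMask(mask=mask, component_count=int(count), geometry=geometry)


def _border_components(binary: np.ndarray) -> np.ndarray:
    """Mask of connected components touching the image border."""
    lab, n = ndimage.label(binary)
    if n == 0:
        return np.zeros_like(binary)
    border_labels = np.unique(
        np.concatenate([lab[0], lab[-1], lab[:, 0], lab[:, -1]])
    )
    border_labels = border_labels[border_labels > 0]
    return np.isin(lab, border_labels)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap between two binary masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
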