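"""Field-of-view intensity quantification with 3x-background thresholding."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage


@dataclass
class FieldIntensity:
    """Above-threshold statistics of one field of view."""

    mean_intensity: float        # mean over the mask; NaN if empty mask
    integrated_intensity: float
    area_px: int
    threshold: float
    n_cells: Optional[int] = None

    @property
    def rfu_per_cell(self) -> float:
        if self.n_cells is None or self.n_cells < 1:
            raise ValueError("n_cells must be >= 1 to report RFU per cell")
        return self.integrated_intensity / self.n_cells


def threshold_stats(image: np.ndarray, background: float,
                    multiplier: float = 3.0) -> FieldIntensity:
    """Mask pixels >= multiplier x background; report mean/sum/area over it."""
    if background <= 0:
        raise ValueError("background estimate must be positive")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    image = np.asarray(image, dtype=float)
    threshold = multiplier * background
    mask = image >= threshold
    area = int(mask.sum())
    integrated = float(image[mask].sum()) if area else 0.0
    mean = float(image[mask].mean()) if area else math.nan
    return FieldIntensity(mean_intensity=mean, integrated_intensity=integrated,
                          area_px=area, threshold=threshold)


def per_cell_rfu(field: FieldIntensity, n_cells: int) -> float:
    """Integrated above-threshold intensity normalized by counted cells."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    return field.integrated_intensity / n_cells


def estimate_background(image: np.ndarray, roi_mask: Optional[np.ndarray] = None) -> float:
    """Median of a cell-free ROI; falls back to the image mode (histogram peak)."""
    image = np.asarray(image, dtype=float)
    if roi_mask is not None:
        vals = image[np.asarray(roi_mask, dtype=bool)]
        if vals.size == 0:
            raise ValueError("background ROI is empty")
        return float(np.median(vals))
    hist, edges = np.histogram(image, bins=256)
    peak = int(np.argmax(hist))
    return float((edges[peak] + edges[peak + 1]) / 2.0)


def _plane_sharpness(plane: np.ndarray) -> float:
    return float(ndimage.laplace(plane.astype(float)).var())


def best_focus_projection(stack: np.ndarray, method: str = "plane",
                          window: int = 9) -> np.ndarray:
    """Project a Z-stack to its sharpest content.

    ``method='plane'`` returns the single plane with the highest variance
    of the Laplacian; ``method='pixel'`` picks, per pixel, the plane with
    the largest local Laplacian energy.  Both stand in for proprietary
    best-focus projections.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (planes, y, x)")
    if method == "plane":
        scores = [_plane_sharpness(p) for p in stack]
        return stack[int(np.argmax(scores))]
    if method == "pixel":
        energy = np.stack([
            ndimage.uniform_filter(ndimage.laplace(p) ** 2, size=window)
            for p in stack
        ])
        choice = np.argmax(energy, axis=0)
        rows, cols = np.indices(choice.shape)
        return stack[choice, rows, cols]
    raise ValueError("method must be 'plane' or 'pixel'")
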