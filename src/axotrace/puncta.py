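"""Spot detection and two-channel colocalization with per-cell rupture metrics.

Detection approximates threshold-based spot finders: a robust background
(median) plus ``intensity_threshold`` robust SDs (MAD-based) defines the
foreground, connected components are filtered by minimum size, and spot
centers are intensity-weighted centroids.  Colocalization is a one-to-one
greedy matching by ascending center distance with a hard maximum
distance; the same three parameters (minimum size, intensity threshold,
colocalization maximum distance) are held fixed across all images of an
experiment.  Marker puncta that do not colocalize with the reference
channel are treated as background and removed before per-cell reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy import ndimage
from scipy.spatial.distance import cdist

from .errors import ConfigurationError, QualityError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DetectionConfig:
    """Spot-detection and colocalization parameters, fixed per experiment."""

    min_size: int = 4                  # pixels
    intensity_threshold: float = 5.0   # robust SDs above background
    coloc_max_distance: float = 4.0    # pixels, center-to-center

    def __post_init__(self) -> None:
        if self.min_size <= 0 or self.intensity_threshold <= 0 or self.coloc_max_distance <= 0:
            raise ConfigurationError("all detection parameters must be strictly positive")


@dataclass
class Punctum:
    channel: int
    x: float
    y: float
    area_px: int
    integrated_intensity: float   # background-subtracted sum
    mean_intensity: float

    @property
    def center(self) -> Tuple[float, float]:
        return (self.x, self.y)


def detect_puncta(image: np.ndarray, config: DetectionConfig, channel: int = 0) -> List[Punctum]:
    """Connected components above a robust local-background threshold."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ConfigurationError("detect_puncta expects a single-channel 2-D image")
    vmax = float(image.max())
    if vmax > float(image.min()) and float((image == vmax).mean()) > 0.5:
        raise QualityError("image saturated: majority of pixels pinned at the maximum")
    bg = float(np.median(image))
    mad = float(np.median(np.abs(image - bg)))
    threshold = bg + config.intensity_threshold * 1.4826 * mad
    mask = image > threshold
    labeled, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    puncta: List[Punctum] = []
    for lbl in range(1, n + 1):
        ys, xs = np.nonzero(labeled == lbl)
        area = len(ys)
        if area < config.min_size:
            continue
        weights = np.maximum(image[ys, xs] - bg, 1e-12)
        cx = float(np.average(xs, weights=weights))
        cy = float(np.average(ys, weights=weights))
        integrated = float((image[ys, xs] - bg).sum())
        puncta.append(Punctum(channel=channel, x=cx, y=cy, area_px=area,
                              integrated_intensity=integrated,
                              mean_intensity=float(image[ys, xs].mean())))
    return puncta


def colocalize(a: Sequence[Punctum], b: Sequence[Punctum],
               max_distance: float) -> List[Tuple[int, int, float]]:
    """One-to-one greedy matching by ascending center distance.

    Returns (index into a, index into b, distance) triples; a pair is
    admissible iff its center distance is <= ``max_distance`` and each
    punctum appears in at most one pair.
    """
    if max_distance <= 0:
        raise ConfigurationError("max_distance must be positive")
    if not a or not b:
        return []
    ca = np.array([p.center for p in a], dtype=float)
    cb = np.array([p.center for p in b], dtype=float)
    d = cdist(ca, cb)
    order = np.argsort(d, axis=None, kind="stable")
    used_a: set = set()
    used_b: set = set()
    pairs: List[Tuple[int, int, float]] = []
    for flat in order:
        i, j = divmod(int(flat), d.shape[1])
        if d[i, j] > max_distance:
            break
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j, float(d[i, j])))
        used_a.add(i)
        used_b.add(j)
    return pairs


@dataclass
class CellColocResult:
    cell_id: int
    n_lamp1: int
    n_marker: int
    n_colocalized: int
    percent_lamp1_colocalized: float
    marker_rfu: float     # sum of colocalized-marker integrated intensities

    def to_dict(self) -> dict:
        return {
            "cell_id": self.cell_id,
            "n_lamp1": self.n_lamp1,
            "n_marker": self.n_marker,
            "n_coloc": self.n_colocalized,
            "percent": self.percent_lamp1_colocalized,
            "rfu": self.marker_rfu,
        }


def _assign_to_rois(puncta: Sequence[Punctum], rois: Sequence[np.ndarray]) -> List[Optional[int]]:
    """Centroid-in-polygon; ties to the first ROI in file order."""
    paths = [MplPath(np.asarray(roi, dtype=float)) for roi in rois]
    assignment: List[Optional[int]] = []
    for p in puncta:
        hit = None
        for k, path in enumerate(paths):
            if path.contains_point(p.center):
                hit = k
                break
        if hit is None:
            log.info("punctum at (%.1f, %.1f) outside all ROIs; excluded", p.x, p.y)
        assignment.append(hit)
    return assignment


def rupture_metrics(rois: Sequence[np.ndarray], lamp1: Sequence[Punctum],
                    marker: Sequence[Punctum],
                    config: DetectionConfig) -> List[CellColocResult]:
    """Per-cell colocalization fraction and colocalized-marker RFU.

    Marker puncta that do not pair with a reference (LAMP1) punctum within
    ``coloc_max_distance`` are considered background/artifacts and dropped.
    """
    lamp1_roi = _assign_to_rois(lamp1, rois)
    marker_roi = _assign_to_rois(marker, rois)
    results: List[CellColocResult] = []
    for cell in range(len(rois)):
        l_cell = [p for p, r in zip(lamp1, lamp1_roi) if r == cell]
        m_cell = [p for p, r in zip(marker, marker_roi) if r == cell]
        pairs = colocalize(l_cell, m_cell, config.coloc_max_distance)
        n_coloc = len(pairs)
        rfu = float(sum(m_cell[j].integrated_intensity for _, j, _ in pairs))
        percent = 100.0 * n_coloc / len(l_cell) if l_cell else 0.0
        results.append(CellColocResult(
            cell_id=cell, n_lamp1=len(l_cell), n_marker=len(m_cell),
            n_colocalized=n_coloc, percent_lamp1_colocalized=percent,
            marker_rfu=rfu,
        ))
    return results


def results_table(results: Sequence[CellColocResult]) -> pd.DataFrame:
    columns = ["cell_id", "n_lamp1", "n_marker", "n_coloc", "percent", "rfu"]
    return pd.DataFrame([r.to_dict() for r in results], columns=columns)
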