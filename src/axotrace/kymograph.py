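"""Kymograph construction from a time-lapse stack and an axon path.

Rows are frames, columns are positions along the path sampled at 1-pixel
arc-length steps; a maximum projection over ``sampling_width`` pixels
perpendicular to the path makes punctate cargo robust to small path
annotation errors.  Column order is normalized so that increasing column
index always points away from the soma (anterograde).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import BoundsError, ConfigurationError
from .simulate import MovieStack

#: pixel calibration at 630x magnification (um per pixel)
PIXEL_SIZE_630X = 0.160508


def calibrate_distance(pixels: float, pixel_size: float = PIXEL_SIZE_630X) -> float:
    """Convert a pixel distance to micrometers (default 630x calibration)."""
    if pixels < 0:
        raise ValueError(f"pixel distance must be non-negative, got {pixels!r}")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    return pixels * pixel_size


@dataclass
class AxonPath:
    """Ordered polyline (x, y pixel coordinates) with soma orientation."""

    vertices: np.ndarray
    soma_end: str = "start"          # which polyline end faces the cell body
    sampling_width: int = 5          # pixels perpendicular to the path

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ConfigurationError("path vertices must be an (N, 2) array of x, y")
        if self.vertices.shape[0] < 2:
            raise ConfigurationError("path needs at least 2 vertices")
        if self.soma_end not in ("start", "end"):
            raise ConfigurationError("soma_end must be 'start' or 'end'")
        if self.sampling_width < 1:
            raise ConfigurationError("sampling_width must be >= 1")
        if self.arc_length_px() <= 0:
            raise ConfigurationError("path arc length must be positive")

    def arc_length_px(self) -> float:
        seg = np.diff(self.vertices, axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def reversed(self) -> "AxonPath":
        other_end = "end" if self.soma_end == "start" else "start"
        return AxonPath(self.vertices[::-1].copy(), other_end, self.sampling_width)


@dataclass
class Kymograph:
    """2-D array: rows = frames, columns = positions along the axon."""

    data: np.ndarray
    pixel_size: float        # um / pixel (column spacing)
    frame_interval: float    # s (row spacing)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ConfigurationError("kymograph data must be 2-D")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_positions(self) -> int:
        return self.data.shape[1]

    @property
    def length_um(self) -> float:
        return self.n_positions * self.pixel_size

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval

    def column_to_um(self, column) -> np.ndarray:
        """Physical position of a column center (columns sample arc midpoints)."""
        return (np.asarray(column, dtype=float) + 0.5) * self.pixel_size

    def um_to_column(self, position_um) -> np.ndarray:
        return np.asarray(position_um, dtype=float) / self.pixel_size - 0.5


def _resample_path(path: AxonPath) -> tuple:
    """Sample the polyline at 1-px arc steps; returns centers and normals."""
    v = path.vertices
    seg = np.diff(v, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    total = cum[-1]
    n_cols = int(round(total))
    if n_cols < 1:
        raise ConfigurationError("path shorter than one pixel")
    # midpoint sampling of the half-open [0, L): mirror-symmetric for
    # integer arc lengths, so flipping soma_end mirrors columns exactly
    s = np.arange(n_cols, dtype=float) + 0.5
    xs = np.interp(s, cum, v[:, 0])
    ys = np.interp(s, cum, v[:, 1])
    tx = np.gradient(xs)
    ty = np.gradient(ys)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    nx, ny = -ty / norm, tx / norm
    return xs, ys, nx, ny


def build_kymograph(stack, path: AxonPath, *, pixel_size: float = None,
                    frame_interval: float = None) -> Kymograph:
    """Build a calibrated, orientation-normalized kymograph.

    ``stack`` may be a :class:`MovieStack` (calibration taken from it) or a
    raw ``(frames, y, x)`` array with explicit ``pixel_size`` /
    ``frame_interval``.
    """
    if isinstance(stack, MovieStack):
        frames = stack.data
        pixel_size = stack.pixel_size if pixel_size is None else pixel_size
        frame_interval = stack.frame_interval if frame_interval is None else frame_interval
    else:
        frames = np.asarray(stack)
        if pixel_size is None or frame_interval is None:
            raise ConfigurationError(
                "pixel_size and frame_interval are required for a raw array stack"
            )
    if frames.ndim != 3:
        raise ConfigurationError("stack must be (frames, y, x)")

    n_frames, height, width = frames.shape
    v = path.vertices
    if (v[:, 0].min() < 0 or v[:, 0].max() > width - 1
            or v[:, 1].min() < 0 or v[:, 1].max() > height - 1):
        raise BoundsError("axon path falls outside the image bounds")

    xs, ys, nx, ny = _resample_path(path)
    w = path.sampling_width
    offsets = np.arange(w, dtype=float) - (w - 1) / 2.0
    # (width, n_cols) sample grids; rows are perpendicular offsets
    sample_x = xs[None, :] + offsets[:, None] * nx[None, :]
    sample_y = ys[None, :] + offsets[:, None] * ny[None, :]

    kymo = np.empty((n_frames, xs.size), dtype=float)
    for f in range(n_frames):
        vals = map_coordinates(frames[f].astype(float), [sample_y, sample_x],
                               order=1, mode="nearest")
        kymo[f] = vals.max(axis=0)
    if path.soma_end == "end":
        kymo = kymo[:, ::-1]
    return Kymograph(kymo, pixel_size, frame_interval)
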