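"""Synthetic microscopy data with exact ground truth.

Three generators back the analysis pipeline:

* :func:`simulate_transport` — bidirectional two-state (run/pause) cargo
  motion along a straight 1-D axon, plus diffusing stationary particles,
  optionally rendered as diffraction-limited spots over Poisson noise.
* :func:`simulate_puncta_field` — two-channel still images with a planted
  per-cell colocalization fraction and square cell ROIs.
* :func:`simulate_intensity_field` — flat-background fields with planted
  bright objects of known area and integrated intensity.

Every generator is driven by a single :class:`numpy.random.Generator`
seeded from the config, so identical seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError

STATE_RUN = "run"
STATE_PAUSE = "pause"
STATE_STATIONARY = "stationary"

#: pixel calibration at 630x magnification (um per pixel)
DEFAULT_PIXEL_SIZE = 0.160508


# ---------------------------------------------------------------------------
# transport simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransportSimConfig:
    """Parameters of the two-state cargo-motion simulation.

    The motion model is a continuous-time run/pause process discretized at
    the frame interval: run and pause durations are drawn from the
    continuous model and quantized to whole frames (minimum one frame), so
    that within any frame a particle either runs at its current speed or
    holds position.  Runs terminate when their exponential travel distance
    is exhausted or an exponential pause hazard (``pause_rate``) fires;
    after each pause the direction reverses with ``reversal_prob``.
    Particles reaching either axon end are reflected, which keeps the
    particle density stationary over time while leaving every trajectory
    continuous (a reflection reads as a direction reversal on the
    kymograph, terminating the current run in truth and analysis alike).
    """

    axon_length: float = 60.0            # um
    pixel_size: float = DEFAULT_PIXEL_SIZE  # um / pixel
    frame_interval: float = 0.75         # s (0.75 s x 120 s regime default)
    n_frames: int = 160
    n_particles: int = 12
    stationary_fraction: float = 0.4
    run_speed_anterograde: float = 1.2   # um/s, truncated-normal mean
    run_speed_retrograde: float = 1.4    # um/s
    run_speed_sd: float = 0.2            # um/s
    run_length_mean: float = 8.0         # um, exponential
    pause_rate: float = 0.02             # 1/s, mid-run pause hazard
    pause_duration_mean: float = 4.0     # s, exponential
    reversal_prob: float = 0.3           # per run end
    diffusion_coeff: float = 0.01        # um^2/s, stationary jitter
    anterograde_fraction: float = 0.5    # initial direction split
    psf_sigma: float = 1.3               # pixels
    snr: float = 8.0                     # peak amplitude / background noise SD
    background_level: float = 100.0      # photons
    image_height: int = 15               # pixels
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "axon_length": self.axon_length,
            "pixel_size": self.pixel_size,
            "frame_interval": self.frame_interval,
            "run_speed_anterograde": self.run_speed_anterograde,
            "run_speed_retrograde": self.run_speed_retrograde,
            "run_length_mean": self.run_length_mean,
            "pause_rate": self.pause_rate,
            "pause_duration_mean": self.pause_duration_mean,
            "psf_sigma": self.psf_sigma,
            "snr": self.snr,
            "background_level": self.background_level,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ConfigurationError(f"{name} must be strictly positive, got {value!r}")
        for name, value in {
            "run_speed_sd": self.run_speed_sd,
            "diffusion_coeff": self.diffusion_coeff,
        }.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be non-negative, got {value!r}")
        for name, value in {
            "stationary_fraction": self.stationary_fraction,
            "reversal_prob": self.reversal_prob,
            "anterograde_fraction": self.anterograde_fraction,
        }.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {value!r}")
        if self.n_frames < 2:
            raise ConfigurationError("n_frames must be >= 2")
        if self.n_particles < 0:
            raise ConfigurationError("n_particles must be >= 0")
        if self.image_height < 3:
            raise ConfigurationError("image_height must be >= 3 pixels")

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class MovieStack:
    """Time-ordered image frames with physical calibration."""

    data: np.ndarray                 # (n_frames, height, width)
    pixel_size: float                # um / pixel
    frame_interval: float            # s

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ConfigurationError("MovieStack data must be (frames, y, x)")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.frame_interval

    def axon_path_vertices(self) -> np.ndarray:
        """Default horizontal axon path through the image center, (x, y)."""
        y0 = (self.data.shape[1] - 1) / 2.0
        return np.array([[0.0, y0], [self.data.shape[2] - 1.0, y0]])


@dataclass
class GroundTruth:
    """Exact trajectory table used to render a movie.

    ``trajectories`` has one row per (particle, frame) with the wrapped
    position in um and the motion state during the following frame
    interval.  ``labels`` maps particle id to its motile/stationary class.
    """

    trajectories: pd.DataFrame
    labels: pd.DataFrame
    config: TransportSimConfig

    def positions(self, particle_id: int) -> np.ndarray:
        sub = self.trajectories[self.trajectories["particle_id"] == particle_id]
        return sub.sort_values("frame")["position_um"].to_numpy()

    def particle_ids(self) -> np.ndarray:
        return self.labels["particle_id"].to_numpy()

    def stationary_fraction_true(self) -> float:
        return float((~self.labels["motile"]).mean())

    def tracks(self, split_wraps: bool = True) -> list:
        """Noiseless tracks for the segmentation pipeline.

        Reflecting boundaries keep trajectories continuous, so normally
        one track per particle results; any residual near-full-axon jump
        (e.g. from externally supplied wrapped trajectories) still starts
        a new track, as it would for any tracker.
        """
        from .tracking import Track  # local import avoids a cycle

        out = []
        tid = 0
        L = self.config.axon_length
        for pid in self.particle_ids():
            sub = self.trajectories[self.trajectories["particle_id"] == pid]
            sub = sub.sort_values("frame")
            pos = sub["position_um"].to_numpy()
            frames = sub["frame"].to_numpy()
            if split_wraps:
                cuts = np.flatnonzero(np.abs(np.diff(pos)) > L / 2.0) + 1
            else:
                cuts = np.array([], dtype=int)
            for piece_f, piece_x in zip(np.split(frames, cuts), np.split(pos, cuts)):
                if len(piece_f) >= 2:
                    out.append(Track(tid, piece_f, piece_x))
                    tid += 1
        return out

    def run_table(self, pause_min_frames: int = 4) -> pd.DataFrame:
        """Derive the true run events from states (not positions).

        A run event is a maximal stretch of same-direction moving steps
        not interrupted by a stall of >= ``pause_min_frames`` consecutive
        frames at one position (i.e. >= pause_min_frames - 1 consecutive
        non-moving steps) or by a boundary respawn.  This is the
        event-level truth a kymograph tracer operating under the same
        stall rule would see; shorter generative pauses are invisible to
        that rule by construction.
        """
        L = self.config.axon_length
        dt = self.config.frame_interval
        min_stall_steps = pause_min_frames - 1
        records = []
        for pid, sub in self.trajectories.groupby("particle_id", sort=True):
            if not bool(self.labels.loc[self.labels["particle_id"] == pid, "motile"].iloc[0]):
                continue
            sub = sub.sort_values("frame")
            pos = sub["position_um"].to_numpy()
            frames = sub["frame"].to_numpy()
            states = sub["state"].to_numpy()
            dx = np.diff(pos)
            wrap = np.abs(dx) > L / 2.0           # boundary respawn
            moving = (states[:-1] == STATE_RUN) & ~wrap

            cur: Optional[dict] = None
            stall = 0

            def close() -> None:
                nonlocal cur
                if cur is not None and cur["n"] > 0:
                    records.append(
                        {
                            "particle_id": pid,
                            "direction": "anterograde" if cur["sign"] > 0 else "retrograde",
                            "start_frame": cur["start"],
                            "end_frame": cur["end"],
                            "displacement_um": cur["disp"],
                            "duration_s": cur["n"] * dt,
                            "mean_speed_um_s": cur["disp"] / (cur["n"] * dt),
                        }
                    )
                cur = None

            for k in range(len(dx)):
                if wrap[k]:
                    close()
                    stall = 0
                    continue
                if not moving[k]:
                    stall += 1
                    if stall >= min_stall_steps:
                        close()
                    continue
                stall = 0
                sign = 1 if dx[k] > 0 else -1
                if cur is not None and sign != cur["sign"]:
                    close()
                if cur is None:
                    cur = {"sign": sign, "start": int(frames[k]), "end": int(frames[k + 1]),
                           "disp": 0.0, "n": 0}
                cur["disp"] += abs(dx[k])
                cur["end"] = int(frames[k + 1])
                cur["n"] += 1
            close()
        return pd.DataFrame.from_records(
            records,
            columns=["particle_id", "direction", "start_frame", "end_frame",
                     "displacement_um", "duration_s", "mean_speed_um_s"],
        )

    def summary(self, run_threshold: float = 5.0, pause_min_frames: int = 4) -> dict:
        """Planted per-movie values for directed runs >= ``run_threshold``."""
        runs = self.run_table(pause_min_frames=pause_min_frames)
        directed = runs[runs["displacement_um"] >= run_threshold]
        duration_min = self.config.duration_s / 60.0
        out = {"stationary_fraction": self.stationary_fraction_true()}
        for direction in ("anterograde", "retrograde"):
            sub = directed[directed["direction"] == direction]
            out[f"{direction}_n_runs"] = int(len(sub))
            out[f"{direction}_mean_speed"] = (
                float(sub["mean_speed_um_s"].mean()) if len(sub) else math.nan
            )
            out[f"{direction}_mean_run_length"] = (
                float(sub["displacement_um"].mean()) if len(sub) else math.nan
            )
            out[f"{direction}_flux"] = float(
                sub["displacement_um"].sum() / (self.config.axon_length * duration_min)
            )
        return out


def _reflect(x: np.ndarray, L: float) -> np.ndarray:
    """Fold unbounded 1-D positions into [0, L] by mirror reflection."""
    z = np.mod(x, 2.0 * L)
    return np.where(z > L, 2.0 * L - z, z)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd == 0:
        return mean
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return v
    raise GenerationError("could not draw a positive run speed; check speed mean/sd")


def _motile_steps(rng: np.random.Generator, cfg: TransportSimConfig) -> tuple:
    """Per-step signed velocities (um/s) and states for one motile particle."""
    dt = cfg.frame_interval
    n_steps = cfg.n_frames - 1
    v = np.empty(n_steps)
    states = np.empty(n_steps, dtype=object)
    direction = 1 if rng.random() < cfg.anterograde_fraction else -1
    k = 0
    while k < n_steps:
        mean = cfg.run_speed_anterograde if direction > 0 else cfg.run_speed_retrograde
        speed = _truncated_normal(rng, mean, cfg.run_speed_sd)
        run_time = rng.exponential(cfg.run_length_mean) / speed
        run_time = min(run_time, rng.exponential(1.0 / cfg.pause_rate))
        run_frames = max(1, int(round(run_time / dt)))
        take = min(run_frames, n_steps - k)
        v[k:k + take] = direction * speed
        states[k:k + take] = STATE_RUN
        k += take
        if k >= n_steps:
            break
        pause_frames = max(1, int(round(rng.exponential(cfg.pause_duration_mean) / dt)))
        take = min(pause_frames, n_steps - k)
        v[k:k + take] = 0.0
        states[k:k + take] = STATE_PAUSE
        k += take
        if rng.random() < cfg.reversal_prob:
            direction = -direction
    return v, states


def _render_stack(per_frame_positions_um: np.ndarray, cfg: TransportSimConfig,
                  rng: np.random.Generator) -> MovieStack:
    """Render particle positions as Gaussian spots over Poisson background."""
    width = int(round(cfg.axon_length / cfg.pixel_size))
    height = cfg.image_height
    y0 = (height - 1) / 2.0
    amplitude = cfg.snr * math.sqrt(cfg.background_level)
    sigma = cfg.psf_sigma
    half = max(1, int(math.ceil(4 * sigma)))
    yy = np.arange(height)
    stack = np.empty((cfg.n_frames, height, width), dtype=np.uint16)
    for f in range(cfg.n_frames):
        lam = np.full((height, width), cfg.background_level)
        for x_um in per_frame_positions_um[:, f]:
            x_px = x_um / cfg.pixel_size
            x_lo = max(0, int(math.floor(x_px)) - half)
            x_hi = min(width, int(math.ceil(x_px)) + half + 1)
            if x_hi <= x_lo:
                continue
            xs = np.arange(x_lo, x_hi)
            gx = np.exp(-0.5 * ((xs - x_px) / sigma) ** 2)
            gy = np.exp(-0.5 * ((yy - y0) / sigma) ** 2)
            lam[:, x_lo:x_hi] += amplitude * gy[:, None] * gx[None, :]
        stack[f] = np.minimum(rng.poisson(lam), 65535).astype(np.uint16)
    return MovieStack(stack, cfg.pixel_size, cfg.frame_interval)


def simulate_transport(config: TransportSimConfig, render: bool = True):
    """Simulate one movie; returns ``(MovieStack | None, GroundTruth)``.

    With ``render=False`` only the trajectory table is produced, which is
    orders of magnitude faster and sufficient for statistical studies on
    noiseless tracks.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    L = cfg.axon_length
    dt = cfg.frame_interval
    n_stationary = int(round(cfg.stationary_fraction * cfg.n_particles))

    rows = []
    labels = []
    positions = np.empty((cfg.n_particles, cfg.n_frames))
    for pid in range(cfg.n_particles):
        x0 = rng.uniform(0.0, L)
        if pid < n_stationary:
            if cfg.diffusion_coeff > 0:
                steps = rng.normal(0.0, math.sqrt(2 * cfg.diffusion_coeff * dt),
                                   cfg.n_frames - 1)
            else:
                steps = np.zeros(cfg.n_frames - 1)
            states = np.full(cfg.n_frames - 1, STATE_STATIONARY, dtype=object)
            motile = False
        else:
            v, states = _motile_steps(rng, cfg)
            steps = v * dt
            motile = True
        x = _reflect(np.concatenate([[x0], x0 + np.cumsum(steps)]), L)
        positions[pid] = x
        labels.append({"particle_id": pid, "motile": motile})
        frame_states = np.concatenate([states, states[-1:]])
        for f in range(cfg.n_frames):
            rows.append((pid, f, x[f], frame_states[f]))

    trajectories = pd.DataFrame(rows, columns=["particle_id", "frame", "position_um", "state"])
    truth = GroundTruth(trajectories, pd.DataFrame(labels, columns=["particle_id", "motile"]),
                        cfg)
    if cfg.n_particles == 0:
        truth.labels = pd.DataFrame(columns=["particle_id", "motile"])
    stack = _render_stack(positions, cfg, rng) if render else None
    return stack, truth


# ---------------------------------------------------------------------------
# two-channel puncta fields
# ---------------------------------------------------------------------------

@dataclass
class PunctaField:
    """Two-channel rendered field, per-cell ROIs and planted spot table."""

    image: np.ndarray             # (2, height, width)
    rois: list                    # list of (n_vertices, 2) float arrays, (x, y)
    truth: pd.DataFrame           # cell, channel, spot_id, x, y, pair_id
    n_planted_pairs_per_cell: int


def _place_points(rng: np.random.Generator, n: int, lo: np.ndarray, hi: np.ndarray,
                  min_spacing: float, avoid: Sequence[np.ndarray] = (),
                  avoid_distance: float = 0.0, max_attempts: int = 20000) -> np.ndarray:
    """Rejection-sample n points in a box with mutual and external spacing."""
    pts: list = []
    avoid_arr = np.array(avoid, dtype=float).reshape(-1, 2)
    attempts = 0
    while len(pts) < n:
        if attempts >= max_attempts:
            raise GenerationError(
                "could not place spots under the requested spacing; "
                "reduce density or spacing constraints"
            )
        attempts += 1
        p = rng.uniform(lo, hi)
        if pts and np.min(np.hypot(*(np.array(pts) - p).T)) < min_spacing:
            continue
        if len(avoid_arr) and np.min(np.hypot(*(avoid_arr - p).T)) < avoid_distance:
            continue
        pts.append(p)
    return np.array(pts).reshape(-1, 2)


def _render_spots(shape: tuple, centers: np.ndarray, amplitude: float, sigma: float,
                  background: float, rng: np.random.Generator,
                  noise: bool = True) -> np.ndarray:
    h, w = shape
    lam = np.full((h, w), background, dtype=float)
    half = max(1, int(math.ceil(4 * sigma)))
    for cx, cy in centers:
        x_lo, x_hi = max(0, int(cx) - half), min(w, int(cx) + half + 1)
        y_lo, y_hi = max(0, int(cy) - half), min(h, int(cy) + half + 1)
        xs = np.arange(x_lo, x_hi)
        ys = np.arange(y_lo, y_hi)
        gx = np.exp(-0.5 * ((xs - cx) / sigma) ** 2)
        gy = np.exp(-0.5 * ((ys - cy) / sigma) ** 2)
        lam[y_lo:y_hi, x_lo:x_hi] += amplitude * gy[:, None] * gx[None, :]
    if noise:
        return np.minimum(rng.poisson(lam), 65535).astype(np.uint16)
    return lam


def simulate_puncta_field(
    n_cells: int = 4,
    n_lamp1_per_cell: int = 20,
    coloc_fraction: float = 0.4,
    max_offset: float = 2.0,
    *,
    min_spacing: float = 14.0,
    cell_size: int = 140,
    margin: int = 14,
    psf_sigma: float = 1.5,
    snr: float = 10.0,
    background_level: float = 100.0,
    noise: bool = True,
    seed: int = 0,
) -> PunctaField:
    """Plant a known per-cell colocalization fraction in a two-channel field.

    Channel 0 carries ``n_lamp1_per_cell`` reference spots per cell;
    channel 1 carries the same number of marker spots of which exactly
    ``round(coloc_fraction * n_lamp1_per_cell)`` are placed within
    ``max_offset`` pixels of a distinct reference spot, and the remainder
    at least ``3 * max_offset`` (and ``min_spacing``) away from every
    reference spot.
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ConfigurationError("coloc_fraction must lie in [0, 1]")
    if n_cells < 1 or n_lamp1_per_cell < 1:
        raise ConfigurationError("need at least one cell and one spot per cell")
    if max_offset <= 0:
        raise ConfigurationError("max_offset must be positive")
    if min_spacing < 4 * max_offset:
        raise ConfigurationError("min_spacing must be >= 4 * max_offset")

    rng = np.random.default_rng(seed)
    grid = int(math.ceil(math.sqrt(n_cells)))
    h = w = grid * cell_size
    n_pairs = int(round(coloc_fraction * n_lamp1_per_cell))

    rois = []
    records = []
    lamp1_all = []
    marker_all = []
    for cell in range(n_cells):
        gy, gx = divmod(cell, grid)
        x0, y0 = gx * cell_size, gy * cell_size
        roi = np.array([
            [x0 + 4.0, y0 + 4.0],
            [x0 + cell_size - 4.0, y0 + 4.0],
            [x0 + cell_size - 4.0, y0 + cell_size - 4.0],
            [x0 + 4.0, y0 + cell_size - 4.0],
        ])
        rois.append(roi)
        lo = np.array([x0 + margin, y0 + margin], dtype=float)
        hi = np.array([x0 + cell_size - margin, y0 + cell_size - margin], dtype=float)
        lamp1 = _place_points(rng, n_lamp1_per_cell, lo, hi, min_spacing)
        pair_ids = rng.permutation(n_lamp1_per_cell)[:n_pairs]
        markers = np.empty((n_lamp1_per_cell, 2))
        for j, ref_idx in enumerate(pair_ids):
            r = max_offset * math.sqrt(rng.uniform(0.0, 0.9))
            theta = rng.uniform(0, 2 * math.pi)
            markers[j] = lamp1[ref_idx] + [r * math.cos(theta), r * math.sin(theta)]
        n_free = n_lamp1_per_cell - n_pairs
        if n_free:
            markers[n_pairs:] = _place_points(
                rng, n_free, lo, hi, min_spacing,
                avoid=lamp1, avoid_distance=max(3 * max_offset, min_spacing),
            )
        for j, (x, y) in enumerate(lamp1):
            pair = int(np.where(pair_ids == j)[0][0]) if j in pair_ids else -1
            records.append({"cell": cell, "channel": 0, "spot_id": j,
                            "x": x, "y": y, "pair_id": pair})
        for j, (x, y) in enumerate(markers):
            records.append({"cell": cell, "channel": 1, "spot_id": j,
                            "x": x, "y": y, "pair_id": j if j < n_pairs else -1})
        lamp1_all.append(lamp1)
        marker_all.append(markers)

    amplitude = snr * math.sqrt(background_level)
    ch0 = _render_spots((h, w), np.vstack(lamp1_all), amplitude, psf_sigma,
                        background_level, rng, noise)
    ch1 = _render_spots((h, w), np.vstack(marker_all), amplitude, psf_sigma,
                        background_level, rng, noise)
    image = np.stack([ch0, ch1])
    truth = pd.DataFrame.from_records(records)
    return PunctaField(image, rois, truth, n_pairs)


# ---------------------------------------------------------------------------
# field-intensity images
# ---------------------------------------------------------------------------

@dataclass
class IntensityFieldTruth:
    mask: np.ndarray
    area: int
    integrated: float
    object_boxes: list = field(default_factory=list)


def simulate_intensity_field(
    background_level: float = 50.0,
    n_objects: int = 5,
    object_intensity: Optional[float] = None,
    *,
    object_size: int = 10,
    shape: tuple = (256, 256),
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Flat background with planted square objects; returns (image, truth).

    ``object_intensity`` defaults to 10x background and must exceed 3x
    background so planted objects survive the threshold rule.
    """
    if background_level <= 0:
        raise ConfigurationError("background_level must be positive")
    if object_intensity is None:
        object_intensity = 10.0 * background_level
    if object_intensity <= 3.0 * background_level:
        raise ConfigurationError("object_intensity must exceed 3x background")
    if n_objects < 0:
        raise ConfigurationError("n_objects must be >= 0")

    rng = np.random.default_rng(seed)
    h, w = shape
    image = np.full((h, w), float(background_level))
    mask = np.zeros((h, w), dtype=bool)
    boxes = []
    attempts = 0
    while len(boxes) < n_objects:
        if attempts > 10000:
            raise GenerationError("could not place non-overlapping objects")
        attempts += 1
        y = int(rng.integers(1, h - object_size - 1))
        x = int(rng.integers(1, w - object_size - 1))
        # one-pixel gap keeps objects disjoint after labeling
        if mask[max(0, y - 1):y + object_size + 1, max(0, x - 1):x + object_size + 1].any():
            continue
        mask[y:y + object_size, x:x + object_size] = True
        boxes.append((y, x, object_size))
    image[mask] = object_intensity
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, image.shape)
    truth = IntensityFieldTruth(mask=mask, area=int(mask.sum()),
                                integrated=float(image[mask].sum()),
                                object_boxes=boxes)
    return image, truth
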