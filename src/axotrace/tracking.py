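"""Particle tracks on kymographs and their run/pause segmentation.

Segmentation follows three rules, all configurable through
:class:`RunRuleConfig`:

* a candidate run is a maximal unidirectional stretch of motion;
* it terminates when the particle remains in the same position for at
  least ``pause_min_frames`` consecutive frames (a stall) or when the
  direction of motion reverses;
* only candidates whose displacement reaches ``run_threshold`` (default
  5 um) are emitted as directed runs — the threshold is chosen to exceed
  the 1-D diffusion bound sqrt(2 D t), so directed transport cannot be
  confused with diffusion.

"Same position" is quantified by ``same_position_tol``: a frame-to-frame
step of magnitude <= tol counts as no movement.  ``pause_min_frames``
consecutive frames at one position correspond to ``pause_min_frames - 1``
consecutive no-movement steps.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .errors import ConfigurationError
from .kymograph import Kymograph, PIXEL_SIZE_630X

log = logging.getLogger(__name__)

ANTEROGRADE = "anterograde"
RETROGRADE = "retrograde"


def diffusion_bound(D: float, t: float) -> float:
    """Root-mean-squared 1-D diffusive displacement sqrt(2 * D * t)."""
    if D < 0 or t < 0:
        raise ValueError("diffusion coefficient and time must be non-negative")
    return math.sqrt(2.0 * D * t)


@dataclass(frozen=True)
class RunRuleConfig:
    """Thresholds governing run/pause/stationary classification."""

    run_threshold: float = 5.0             # um, directed-run cutoff
    diffusion_coeff: float = 0.01          # um^2/s
    diffusion_horizon: float = 50.0        # s
    pause_min_frames: int = 4              # frames defining a terminating stall
    same_position_tol: float = 2 * PIXEL_SIZE_630X  # um, localization jitter
    stationary_threshold: float = 5.0      # um, whole-movie excursion cutoff

    def __post_init__(self) -> None:
        if self.run_threshold <= 0 or self.stationary_threshold <= 0:
            raise ConfigurationError("thresholds must be positive")
        if self.pause_min_frames < 2:
            raise ConfigurationError("pause_min_frames must be >= 2")
        if self.same_position_tol < 0:
            raise ConfigurationError("same_position_tol must be non-negative")
        bound = diffusion_bound(self.diffusion_coeff, self.diffusion_horizon)
        if self.run_threshold < bound:
            raise ConfigurationError(
                f"run_threshold ({self.run_threshold}) must dominate the diffusion "
                f"bound sqrt(2 D t) = {bound:.3g}"
            )


@dataclass
class Track:
    """One particle's (frame, position) sequence on a kymograph."""

    track_id: int
    frames: np.ndarray          # strictly increasing frame indices
    positions_um: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.positions_um = np.asarray(self.positions_um, dtype=float)
        if self.frames.shape != self.positions_um.shape:
            raise ConfigurationError("frames and positions must align")
        if len(self.frames) and np.any(np.diff(self.frames) <= 0):
            raise ConfigurationError("track frames must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class Run:
    direction: str
    start_frame: int
    end_frame: int
    displacement_um: float      # unsigned
    duration_s: float           # pause frames excluded

    def __post_init__(self) -> None:
        if self.direction not in (ANTEROGRADE, RETROGRADE):
            raise ConfigurationError(f"bad direction {self.direction!r}")
        if self.duration_s <= 0:
            raise ConfigurationError("run duration must be positive")

    @property
    def mean_speed_um_s(self) -> float:
        return self.displacement_um / self.duration_s


@dataclass
class Pause:
    start_frame: int
    end_frame: int
    duration_s: float
    direction: Optional[str] = None   # direction of the preceding run, if any


def assign_direction(signed_displacement: float, away_from_soma_positive: bool = True) -> str:
    """Label motion relative to the soma on an oriented kymograph.

    On a normalized kymograph increasing position points away from the
    soma; pass ``away_from_soma_positive=False`` for a mirrored coordinate.
    """
    if signed_displacement == 0:
        raise ValueError("a directed run cannot have zero net displacement")
    positive = signed_displacement > 0
    return ANTEROGRADE if positive == away_from_soma_positive else RETROGRADE


def _interpolate_gaps(frames: np.ndarray, x: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    full = np.arange(frames[0], frames[-1] + 1)
    return full, np.interp(full, frames, x)


def _split_on_gaps(track: Track, max_gap: int):
    """Split at frame gaps larger than max_gap; interpolate smaller gaps."""
    frames, x = track.frames, track.positions_um
    gaps = np.diff(frames)
    cut = np.where(gaps > max_gap)[0]
    pieces = []
    start = 0
    for c in cut:
        pieces.append((frames[start:c + 1], x[start:c + 1]))
        start = c + 1
    pieces.append((frames[start:], x[start:]))
    if cut.size:
        log.warning("track %d split into %d pieces at frame gaps > %d",
                    track.track_id, len(pieces), max_gap)
    return [_interpolate_gaps(f, p) for f, p in pieces if len(f) >= 2]


def segment_track(track: Track, rules: RunRuleConfig,
                  frame_interval: float) -> Tuple[List[Run], List[Pause]]:
    """Segment a track into directed runs and terminating pauses.

    Frame gaps up to ``pause_min_frames`` are linearly interpolated; larger
    gaps split the track (with a warning) and each piece is segmented
    independently.
    """
    if len(track) < 2:
        raise ValueError("segment_track requires a track with >= 2 points")
    if frame_interval <= 0:
        raise ConfigurationError("frame_interval must be positive")

    runs: List[Run] = []
    pauses: List[Pause] = []
    for frames, x in _split_on_gaps(track, rules.pause_min_frames):
        _segment_contiguous(frames, x, rules, frame_interval, runs, pauses)

    # pauses inherit the direction of the run that precedes them in time
    events = sorted(runs, key=lambda r: r.start_frame)
    for pause in pauses:
        preceding = [r for r in events if r.end_frame <= pause.start_frame]
        pause.direction = preceding[-1].direction if preceding else None
    runs.sort(key=lambda r: r.start_frame)
    pauses.sort(key=lambda p: p.start_frame)
    return runs, pauses


def _segment_contiguous(frames: np.ndarray, x: np.ndarray, rules: RunRuleConfig,
                        dt: float, runs: List[Run], pauses: List[Pause]) -> None:
    dx = np.diff(x)
    moving = np.abs(dx) > rules.same_position_tol
    n_steps = len(dx)
    min_stall_steps = rules.pause_min_frames - 1

    # maximal stretches of consecutive non-moving steps of qualifying length
    stall_step = np.zeros(n_steps, dtype=bool)
    k = 0
    while k < n_steps:
        if moving[k]:
            k += 1
            continue
        j = k
        while j < n_steps and not moving[j]:
            j += 1
        if j - k >= min_stall_steps:
            stall_step[k:j] = True
            pauses.append(Pause(start_frame=int(frames[k]), end_frame=int(frames[j]),
                                duration_s=(j - k) * dt))
        k = j

    # group moving steps by direction within each inter-stall segment
    boundaries = np.flatnonzero(stall_step)
    segment_id = np.cumsum(stall_step)  # steps sharing an id lie between stalls
    current: Optional[dict] = None

    def close(cur) -> None:
        disp = abs(x[cur["last"] + 1] - x[cur["first"]])
        if disp >= rules.run_threshold:
            runs.append(Run(
                direction=assign_direction(cur["sign"]),
                start_frame=int(frames[cur["first"]]),
                end_frame=int(frames[cur["last"] + 1]),
                displacement_um=disp,
                duration_s=cur["n_moving"] * dt,
            ))

    for k in range(n_steps):
        if stall_step[k] or not moving[k]:
            continue
        sign = 1 if dx[k] > 0 else -1
        if current is not None and (sign != current["sign"]
                                    or segment_id[k] != current["segment"]):
            close(current)
            current = None
        if current is None:
            current = {"sign": sign, "first": k, "last": k,
                       "n_moving": 0, "segment": segment_id[k]}
        current["last"] = k
        current["n_moving"] += 1
    if current is not None:
        close(current)


MOTILE = "motile"
STATIONARY = "stationary"
UNCLASSIFIED = "unclassified"


def classify_stationary(track: Track, rules: RunRuleConfig, movie_duration_s: float,
                        frame_interval: float) -> str:
    """Stationary iff the whole-movie positional excursion is < threshold.

    Motility is decided as soon as the excursion reaches the threshold,
    however short the observation; the stationary call, by contrast, needs
    the track to span at least half the movie — a briefly-seen immobile
    track is unclassifiable and excluded (logged).
    """
    if len(track) == 0:
        return UNCLASSIFIED
    excursion = float(track.positions_um.max() - track.positions_um.min())
    if excursion >= rules.stationary_threshold:
        return MOTILE
    span = (track.frames[-1] - track.frames[0]) * frame_interval
    if span < movie_duration_s / 2.0:
        log.info("track %d spans %.1f s < half of %.1f s movie; unclassified",
                 track.track_id, span, movie_duration_s)
        return UNCLASSIFIED
    return STATIONARY


# ---------------------------------------------------------------------------
# kymograph -> tracks
# ---------------------------------------------------------------------------

def _detect_row(row: np.ndarray, threshold: float, min_separation: int) -> np.ndarray:
    """Local maxima above threshold with sub-pixel parabolic refinement."""
    from scipy.signal import find_peaks

    peaks, _ = find_peaks(row, height=threshold, distance=min_separation)
    refined = []
    for p in peaks:
        if 0 < p < len(row) - 1:
            l, c, r = row[p - 1], row[p], row[p + 1]
            denom = l - 2 * c + r
            delta = 0.5 * (l - r) / denom if denom != 0 else 0.0
            refined.append(p + float(np.clip(delta, -0.5, 0.5)))
        else:
            refined.append(float(p))
    return np.asarray(refined)


def _find_anchors(detections: List[np.ndarray], length_um: float, *,
                  window_um: float, min_presence: float,
                  min_separation_um: float) -> np.ndarray:
    """Positions occupied by a detection for most of the movie.

    These are the vertical lines a human reading the kymograph would mark
    as stationary vesicles; claiming them first keeps passing cargo from
    stealing their identity.  Presence at a grid point is the fraction of
    frames with a detection within ``window_um``.
    """
    n_frames = len(detections)
    if n_frames == 0:
        return np.empty(0)
    grid = np.arange(0.0, length_um, 0.25)
    presence = np.zeros_like(grid)
    for det in detections:
        if det.size:
            presence += (np.abs(grid[:, None] - det[None, :]) <= window_um).any(axis=1)
    presence /= n_frames
    from scipy.signal import find_peaks

    min_sep_pts = max(1, int(round(min_separation_um / 0.25)))
    peaks, _ = find_peaks(np.concatenate([[0.0], presence, [0.0]]),
                          height=min_presence, distance=min_sep_pts)
    return grid[peaks - 1]


def extract_tracks(kym: Kymograph, *, threshold_sd: float = 4.0,
                   smooth_px: float = 1.0, min_separation_px: int = 3,
                   max_speed_um_s: float = 3.0, max_gap: int = 8,
                   stitch_max_gap: int = 30, stitch_radius_um: float = 1.0,
                   anchor_window_um: float = 1.0, anchor_min_presence: float = 0.55,
                   min_frames: int = 10) -> List[Track]:
    """Detect per-row intensity maxima and link them into tracks.

    Rows are Gaussian-smoothed by ``smooth_px`` along the position axis
    (suppresses shot noise without shifting peaks), then thresholded at
    median + ``threshold_sd`` robust SDs of the smoothed kymograph.

    Linking proceeds in two passes.  Stationary anchors — positions with
    a detection present in more than ``anchor_min_presence`` of frames —
    claim their nearby detections first, so that passing cargo cannot
    hijack a stationary line during a crossing.  The remaining detections
    are linked greedily by nearest neighbor against a constant-velocity
    prediction with a per-frame jump limit of ``max_speed_um_s *
    frame_interval``; detections missing for up to ``max_gap`` frames
    (e.g. during a crossing occlusion) are bridged by linear
    interpolation, and fragments separated by longer occlusions are
    stitched when positions line up.  Tracks shorter than ``min_frames``
    are discarded.  Crossing particles of similar speed may still swap
    identity; only separable cases are guaranteed.
    """
    from scipy.ndimage import gaussian_filter1d

    data = kym.data
    if data.size == 0:
        return []
    if smooth_px > 0:
        data = gaussian_filter1d(data.astype(float), smooth_px, axis=1)
    bg = float(np.median(data))
    mad = float(np.median(np.abs(data - bg)))
    threshold = bg + threshold_sd * 1.4826 * mad
    max_jump_um = max_speed_um_s * kym.frame_interval + 2 * kym.pixel_size

    detections = [kym.column_to_um(_detect_row(data[f], threshold, min_separation_px))
                  for f in range(data.shape[0])]
    anchors = _find_anchors(detections, kym.length_um, window_um=anchor_window_um,
                            min_presence=anchor_min_presence,
                            min_separation_um=2 * anchor_window_um)
    anchor_tracks = [{"frames": [], "positions": []} for _ in anchors]

    def _velocity(tr: dict) -> float:
        frames_, pos_ = tr["frames"], tr["positions"]
        if len(frames_) < 2:
            return 0.0
        k = min(3, len(frames_) - 1)
        dt_frames = frames_[-1] - frames_[-1 - k]
        return (pos_[-1] - pos_[-1 - k]) / (dt_frames * kym.frame_interval)

    active: List[dict] = []
    finished: List[dict] = []
    for f, det_um in enumerate(detections):
        unmatched = set(range(len(det_um)))
        # anchors claim their detections first, nearest first
        anchor_claims = sorted(
            (abs(det_um[di] - a), ai, di)
            for ai, a in enumerate(anchors) for di in unmatched
            if abs(det_um[di] - a) <= 1.5 * anchor_window_um
        )
        claimed_anchors = set()
        for d, ai, di in anchor_claims:
            if ai in claimed_anchors or di not in unmatched:
                continue
            anchor_tracks[ai]["frames"].append(f)
            anchor_tracks[ai]["positions"].append(float(det_um[di]))
            claimed_anchors.add(ai)
            unmatched.discard(di)
        candidates = []
        for ti, tr in enumerate(active):
            gap = f - tr["frames"][-1]
            predicted = tr["positions"][-1] + _velocity(tr) * gap * kym.frame_interval
            for di in unmatched:
                d = abs(det_um[di] - predicted)
                if d <= max_jump_um * gap:
                    candidates.append((d, ti, di))
        candidates.sort()
        used_tracks = set()
        for d, ti, di in candidates:
            if ti in used_tracks or di not in unmatched:
                continue
            active[ti]["frames"].append(f)
            active[ti]["positions"].append(float(det_um[di]))
            used_tracks.add(ti)
            unmatched.discard(di)
        still_active = []
        for ti, tr in enumerate(active):
            if f - tr["frames"][-1] > max_gap:
                finished.append(tr)
            else:
                still_active.append(tr)
        active = still_active
        for di in sorted(unmatched):
            active.append({"frames": [f], "positions": [float(det_um[di])]})
    finished.extend(active)
    finished = _stitch_fragments(finished, kym.frame_interval,
                                 stitch_max_gap=stitch_max_gap,
                                 stitch_radius_um=stitch_radius_um)
    finished.extend(tr for tr in anchor_tracks if tr["frames"])

    tracks: List[Track] = []
    next_id = 0
    for tr in sorted(finished, key=lambda t: (t["frames"][0], t["positions"][0])):
        frames = np.asarray(tr["frames"])
        if len(frames) < min_frames:
            continue
        full, pos = _interpolate_gaps(frames, np.asarray(tr["positions"]))
        tracks.append(Track(next_id, full, pos))
        next_id += 1
    return tracks


def _stitch_fragments(fragments: List[dict], frame_interval: float, *,
                      stitch_max_gap: int, stitch_radius_um: float) -> List[dict]:
    """Rejoin track pieces separated by long occlusions.

    A fragment ending at frame f may continue as one starting at f + g
    (1 <= g <= stitch_max_gap) if the start position lies within
    ``stitch_radius_um`` (plus a small per-frame allowance) of the
    constant-velocity extrapolation of the earlier piece.  Pairs are
    joined greedily by ascending mismatch.
    """
    if stitch_max_gap < 1:
        return fragments

    def _end_velocity(tr: dict) -> float:
        if len(tr["frames"]) < 2:
            return 0.0
        k = min(3, len(tr["frames"]) - 1)
        df = tr["frames"][-1] - tr["frames"][-1 - k]
        return (tr["positions"][-1] - tr["positions"][-1 - k]) / (df * frame_interval)

    merged = True
    while merged:
        merged = False
        candidates = []
        for i, a in enumerate(fragments):
            for j, b in enumerate(fragments):
                if i == j:
                    continue
                gap = b["frames"][0] - a["frames"][-1]
                if not 1 <= gap <= stitch_max_gap:
                    continue
                predicted = a["positions"][-1] + _end_velocity(a) * gap * frame_interval
                # a particle may have kept moving or paused while occluded
                score = min(abs(b["positions"][0] - predicted),
                            abs(b["positions"][0] - a["positions"][-1]))
                if score <= stitch_radius_um + 0.05 * gap:
                    candidates.append((score, i, j))
        if not candidates:
            break
        candidates.sort()
        score, i, j = candidates[0]
        a, b = fragments[i], fragments[j]
        a["frames"].extend(b["frames"])
        a["positions"].extend(b["positions"])
        fragments = [t for k, t in enumerate(fragments) if k != j]
        merged = True
    return fragments
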