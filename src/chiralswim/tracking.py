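"""Cell detection, track linking and biased-random-walk statistics.

This mirrors a dark-field motility analysis pipeline: subtract the
per-pixel minimum projection (static background), blur each frame with a
2 px Gaussian, take local maxima as cell detections, and link detections
frame-to-frame by nearest neighbour to a motion-predicted position
within a maximum connection radius (default 15 px).  Tracks terminate
permanently when no detection falls within range (no gap closing).

From each track at least 5 s long, velocities over an evaluation window
δt (default 2 s) give the mean swimming speed s̄ = ⟨|v_t|⟩ and the
directional persistence d = ⟨v_t·v_{t+δt}/(|v_t||v_{t+δt}|)⟩ — the mean
cosine of the change in travel direction, from −1 (oscillating) through
0 (uncorrelated) to 1 (straight).  Population summaries are weighted by
track duration to avoid bias toward behaviours that fragment tracks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max

from .video import ImageStack

__all__ = [
    "Track",
    "TrackStatistics",
    "PopulationSummary",
    "subtract_background",
    "detect_cells",
    "link_tracks",
    "track_stack",
    "track_statistics",
    "population_summary",
    "persistence_autocorrelation",
]


@dataclass
class Track:
    """Linked 2-D path: uniformly spaced times (s) and positions (μm)."""

    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    track_id: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times, x, y must have equal length")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or np.ptp(steps) > 1e-9 * max(steps[0], 1.0):
                raise ValueError("track times must be uniform and increasing")

    @property
    def n_points(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def frame_interval(self) -> float:
        if self.n_points < 2:
            raise ValueError("track too short for a frame interval")
        return float(self.times[1] - self.times[0])

    def positions(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class TrackStatistics:
    """Per-track biased-random-walk statistics.

    weight is the track duration in seconds, used for population
    averaging.
    """

    track_id: int
    mean_speed: float
    persistence: float
    weight: float
    n_velocity_samples: int


@dataclass
class PopulationSummary:
    """Duration-weighted population statistics."""

    per_track: pd.DataFrame
    mean_speed: float
    mean_persistence: float
    persistence_fractions: dict  # {threshold: weighted fraction above}
    speed_conditional_persistence: dict  # {speed threshold: weighted mean}
    n_tracks: int


def subtract_background(stack: ImageStack) -> ImageStack:
    """Subtract the per-pixel minimum projection over time; clip at 0.

    Removes static background structures; requires ≥ 2 frames.
    """
    if stack.n_frames < 2:
        raise ValueError("background subtraction needs at least 2 frames")
    background = stack.frames.min(axis=0)
    frames = stack.frames.astype(np.int32) - background.astype(np.int32)
    return ImageStack(
        frames=np.clip(frames, 0, None).astype(np.uint16), optics=stack.optics
    )


def detect_cells(
    frame: np.ndarray,
    blur_sigma: float = 2.0,
    min_prominence: Optional[float] = None,
) -> np.ndarray:
    """Detect cells in one background-subtracted frame.

    Gaussian blur (sigma in px) then local maxima
    above ``min_prominence`` (default: 5 × the sd of the blurred frame).
    Returns an (M, 2) array of (x, y) pixel coordinates, sorted by
    (x, y) so downstream processing is independent of detector ordering.
    """
    blurred = ndimage.gaussian_filter(frame.astype(float), blur_sigma)
    if min_prominence is None:
        min_prominence = 5.0 * float(blurred.std())
    # suppress maxima closer than the blur scale: spots merged by the
    # blur (near-plateaus) must yield a single detection
    peaks = peak_local_max(
        blurred,
        min_distance=max(1, int(round(blur_sigma))),
        threshold_abs=min_prominence,
        exclude_border=False,
    )
    if peaks.size == 0:
        return np.empty((0, 2))
    xy = peaks[:, ::-1].astype(float)  # (row, col) -> (x, y)
    order = np.lexsort((xy[:, 1], xy[:, 0]))
    return xy[order]


class _LiveTrack:
    __slots__ = ("track_id", "start_frame", "frames", "points")

    def __init__(self, track_id: int, frame: int, point: np.ndarray):
        self.track_id = track_id
        self.start_frame = frame
        self.frames = [frame]
        self.points = [point]

    def predict(self) -> np.ndarray:
        """Linear extrapolation from the last two points (last point alone
        if the track has a single point)."""
        if len(self.points) >= 2:
            return 2.0 * self.points[-1] - self.points[-2]
        return self.points[-1]


def link_tracks(
    detections_per_frame: Sequence[np.ndarray],
    max_link: float = 15.0,
    pixel_size: float = 1.0,
    frame_rate: float = 1.0,
    min_points: int = 2,
) -> list[Track]:
    """Link per-frame detections (pixel coordinates) into tracks.

    Each live track predicts its next position by linear extrapolation
    and claims the nearest detection within ``max_link`` px.  Conflicts
    are resolved greedily in ascending predicted-distance order (ties
    broken by detection coordinates, then track seniority), so the
    outcome does not depend on detection ordering within a frame.
    Unclaimed detections seed new tracks; tracks with no match terminate
    permanently.  Coordinates are converted to μm via ``pixel_size`` and
    frame indices to seconds via ``frame_rate``.
    """
    live: list[_LiveTrack] = []
    finished: list[_LiveTrack] = []
    next_id = 0
    for f, dets in enumerate(detections_per_frame):
        dets = np.asarray(dets, dtype=float).reshape(-1, 2)
        candidates = []
        for order, trk in enumerate(live):
            pred = trk.predict()
            if len(dets):
                dists = np.hypot(dets[:, 0] - pred[0], dets[:, 1] - pred[1])
                for j in np.flatnonzero(dists <= max_link):
                    candidates.append(
                        (dists[j], dets[j, 0], dets[j, 1], trk.start_frame, trk.track_id, order, j)
                    )
        candidates.sort(key=lambda c: (c[0], c[1], c[2], c[3], c[4]))
        claimed_dets: set[int] = set()
        matched_tracks: set[int] = set()
        for dist, _x, _y, _sf, _tid, order, j in candidates:
            if order in matched_tracks or j in claimed_dets:
                continue
            live[order].frames.append(f)
            live[order].points.append(dets[j])
            matched_tracks.add(order)
            claimed_dets.add(j)
        still_live = [trk for o, trk in enumerate(live) if o in matched_tracks]
        finished.extend(trk for o, trk in enumerate(live) if o not in matched_tracks)
        live = still_live
        unclaimed = [j for j in range(len(dets)) if j not in claimed_dets]
        # seed new tracks in coordinate order for determinism
        unclaimed.sort(key=lambda j: (dets[j, 0], dets[j, 1]))
        for j in unclaimed:
            live.append(_LiveTrack(next_id, f, dets[j]))
            next_id += 1
    finished.extend(live)
    finished.sort(key=lambda trk: trk.track_id)
    tracks = []
    for trk in finished:
        if len(trk.frames) < min_points:
            continue
        pts = np.asarray(trk.points)
        tracks.append(
            Track(
                times=np.asarray(trk.frames, dtype=float) / frame_rate,
                x=pts[:, 0] * pixel_size,
                y=pts[:, 1] * pixel_size,
                track_id=trk.track_id,
            )
        )
    return tracks


def track_stack(
    stack: ImageStack,
    blur_sigma: float = 2.0,
    min_prominence: Optional[float] = None,
    max_link: float = 15.0,
) -> list[Track]:
    """Full pipeline on an image stack: background-subtract, detect, link."""
    clean = subtract_background(stack)
    detections = [
        detect_cells(frame, blur_sigma=blur_sigma, min_prominence=min_prominence)
        for frame in clean.frames
    ]
    return link_tracks(
        detections,
        max_link=max_link,
        pixel_size=stack.optics.pixel_size,
        frame_rate=stack.optics.frame_rate,
    )


def _velocities(track: Track, eval_dt: float) -> tuple[np.ndarray, int, float]:
    """Overlapping-window velocities: v_t = (r_{t+δt} − r_t)/δt.

    The window is rounded to a whole number of frames (≥ 1) and the
    actual window duration is used in the denominator.  Stride is one
    frame.  Returns (velocities (M, 2), window frames, actual δt).
    """
    interval = track.frame_interval
    window = max(1, int(round(eval_dt / interval)))
    actual_dt = window * interval
    pos = track.positions()
    if len(pos) <= window:
        return np.empty((0, 2)), window, actual_dt
    v = (pos[window:] - pos[:-window]) / actual_dt
    return v, window, actual_dt


def track_statistics(
    track: Track, eval_dt: float = 2.0, min_duration: float = 5.0
) -> Optional[TrackStatistics]:
    """Mean speed and directional persistence of one track.

    Tracks shorter than ``min_duration`` seconds, or with fewer than two
    velocity samples separated by the evaluation window, are excluded
    (returns None).  Zero-length velocity vectors are skipped in the
    persistence average.
    """
    if track.n_points < 2 or track.duration < min_duration:
        return None
    v, window, _ = _velocities(track, eval_dt)
    if len(v) < window + 1:
        return None
    speeds = np.linalg.norm(v, axis=1)
    v0, v1 = v[:-window], v[window:]
    n0 = np.linalg.norm(v0, axis=1)
    n1 = np.linalg.norm(v1, axis=1)
    ok = (n0 > 0) & (n1 > 0)
    if not np.any(ok):
        return None
    cosines = np.sum(v0[ok] * v1[ok], axis=1) / (n0[ok] * n1[ok])
    return TrackStatistics(
        track_id=track.track_id,
        mean_speed=float(speeds.mean()),
        persistence=float(cosines.mean()),
        weight=track.duration,
        n_velocity_samples=len(v),
    )


def population_summary(
    tracks: Sequence[Track],
    eval_dt: float = 2.0,
    min_duration: float = 5.0,
    persistence_thresholds: Sequence[float] = (0.80, 0.90, 0.95),
    speed_thresholds: Sequence[float] = (5.0, 8.0, 10.0),
) -> PopulationSummary:
    """Duration-weighted population statistics over eligible tracks.

    Includes the duration-weighted fraction of tracks above each
    persistence threshold and the weighted mean persistence of tracks
    faster than each speed threshold (NaN when no track qualifies).
    """
    stats = [
        s
        for s in (track_statistics(t, eval_dt, min_duration) for t in tracks)
        if s is not None
    ]
    if not stats:
        empty = pd.DataFrame(
            columns=["track_id", "duration_s", "mean_speed", "persistence"]
        )
        return PopulationSummary(
            per_track=empty,
            mean_speed=float("nan"),
            mean_persistence=float("nan"),
            persistence_fractions={t: float("nan") for t in persistence_thresholds},
            speed_conditional_persistence={t: float("nan") for t in speed_thresholds},
            n_tracks=0,
        )
    df = pd.DataFrame(
        {
            "track_id": [s.track_id for s in stats],
            "duration_s": [s.weight for s in stats],
            "mean_speed": [s.mean_speed for s in stats],
            "persistence": [s.persistence for s in stats],
        }
    )
    w = df["duration_s"].to_numpy()
    speed = df["mean_speed"].to_numpy()
    pers = df["persistence"].to_numpy()
    fractions = {
        thr: float(w[pers > thr].sum() / w.sum()) for thr in persistence_thresholds
    }
    conditional = {}
    for thr in speed_thresholds:
        sel = speed > thr
        conditional[thr] = (
            float(np.average(pers[sel], weights=w[sel])) if np.any(sel) else float("nan")
        )
    return PopulationSummary(
        per_track=df,
        mean_speed=float(np.average(speed, weights=w)),
        mean_persistence=float(np.average(pers, weights=w)),
        persistence_fractions=fractions,
        speed_conditional_persistence=conditional,
        n_tracks=len(df),
    )


def persistence_autocorrelation(
    tracks: Sequence[Track],
    base_dt: float = 0.5,
    lags: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Directional autocorrelation curve across evaluation intervals.

    Velocities are computed with the short window ``base_dt``; for each
    lag the population mean cosine between v_t and v_{t+lag} is taken
    over every track long enough to contribute.  Used to choose the
    statistics evaluation interval (where the fast beat/rotation
    oscillation has decayed but the path direction has not).
    """
    if lags is None:
        lags = np.arange(0.0, 10.5, 0.5)
    rows = []
    for lag in lags:
        num = 0.0
        count = 0
        for track in tracks:
            if track.n_points < 2:
                continue
            v, _, _ = _velocities(track, base_dt)
            if len(v) == 0:
                continue
            shift = int(round(lag / track.frame_interval))
            if shift == 0:
                pairs = (v, v)
            elif len(v) > shift:
                pairs = (v[:-shift], v[shift:])
            else:
                continue
            v0, v1 = pairs
            n0 = np.linalg.norm(v0, axis=1)
            n1 = np.linalg.norm(v1, axis=1)
            ok = (n0 > 0) & (n1 > 0)
            if np.any(ok):
                num += float(
                    np.sum(np.sum(v0[ok] * v1[ok], axis=1) / (n0[ok] * n1[ok]))
                )
                count += int(ok.sum())
        rows.append((lag, num / count if count else float("nan"), count))
    return pd.DataFrame(rows, columns=["lag_s", "autocorrelation", "n_pairs"])
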