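"""Spot linking and per-track motion metrics.

Tracks are built by greedy global-nearest-neighbour linking with gap
closing, then summarized by the standard single-particle statistics:
net displacement, path length, linearity of forward progression (net
displacement speed over path-length speed), mean speed, time-averaged
mean square displacement and velocity autocorrelation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import Spot, Track

logger = logging.getLogger(__name__)


@dataclass
class TrackMetrics:
    """Per-track motion summary. Curves are sampled at integer frame lags."""

    track_id: int
    n_frames: int
    duration: float  # s
    displacement: float  # µm, first-to-last distance
    path_length: float  # µm, sum of step lengths
    linearity: float  # displacement / path_length, in [0, 1]
    mean_speed: float  # µm/s, path_length / duration
    msd_lags: np.ndarray = field(repr=False, default=None)  # s
    msd: np.ndarray = field(repr=False, default=None)  # µm²
    vac_lags: np.ndarray = field(repr=False, default=None)  # s
    vac: np.ndarray = field(repr=False, default=None)  # dimensionless
    msd_at_max_lag: float = 0.0  # µm², equals displacement² (single window)


def link_spots(
    spots_by_frame: list[list[Spot]],
    max_link_dist: float,
    max_gap: int = 0,
    frame_interval: float = 1.0,
) -> list[Track]:
    """Link per-frame spot lists into tracks.

    Greedy nearest-neighbour assignment: at each frame, all candidate
    (active track end, new spot) pairs within ``max_link_dist`` are sorted
    by ascending distance (ties by track id, then spot order) and assigned
    greedily; a track stays linkable for up to ``max_gap`` missed frames,
    and closed gaps are filled with linearly interpolated virtual spots
    flagged as interpolated. Unlinked spots seed new tracks; singletons are
    dropped.
    """
    if max_link_dist <= 0:
        raise ValueError("max_link_dist must be > 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")

    # active track: dict with lists of (frame, x, y, intensity, interp)
    active: list[dict] = []
    finished: list[dict] = []
    next_id = 0

    for f, spots in enumerate(spots_by_frame):
        # expire tracks whose last spot is too old to link across the gap
        still = []
        for tr in active:
            if f - tr["frames"][-1] > max_gap + 1:
                finished.append(tr)
            else:
                still.append(tr)
        active = still

        candidates = []
        for ti, tr in enumerate(active):
            lx, ly = tr["x"][-1], tr["y"][-1]
            for si, sp in enumerate(spots):
                d = np.hypot(sp.x - lx, sp.y - ly)
                if d <= max_link_dist:
                    candidates.append((d, tr["id"], si, ti))
        candidates.sort()

        used_tracks: set[int] = set()
        used_spots: set[int] = set()
        for d, tid, si, ti in candidates:
            if ti in used_tracks or si in used_spots:
                continue
            used_tracks.add(ti)
            used_spots.add(si)
            tr = active[ti]
            sp = spots[si]
            gap = f - tr["frames"][-1]
            if gap > 1:  # close the gap with interpolated virtual spots
                x0, y0 = tr["x"][-1], tr["y"][-1]
                for g in range(1, gap):
                    a = g / gap
                    tr["frames"].append(tr["frames"][-1] + 1)
                    tr["x"].append(x0 + a * (sp.x - x0))
                    tr["y"].append(y0 + a * (sp.y - y0))
                    tr["intensity"].append(np.nan)
                    tr["interp"].append(True)
            tr["frames"].append(f)
            tr["x"].append(sp.x)
            tr["y"].append(sp.y)
            tr["intensity"].append(sp.intensity)
            tr["interp"].append(False)

        for si, sp in enumerate(spots):
            if si not in used_spots:
                active.append({"id": next_id, "frames": [f], "x": [sp.x], "y": [sp.y],
                               "intensity": [sp.intensity], "interp": [False],
                               "channel": sp.channel})
                next_id += 1

    finished.extend(active)
    finished.sort(key=lambda tr: tr["id"])
    tracks = []
    for tr in finished:
        if len(tr["frames"]) < 2:
            continue
        tracks.append(Track(
            track_id=tr["id"],
            frames=np.array(tr["frames"]),
            xy=np.column_stack([tr["x"], tr["y"]]),
            frame_interval=frame_interval,
            intensity=np.array(tr["intensity"], dtype=float),
            interpolated=np.array(tr["interp"], dtype=bool),
            channel=tr.get("channel", 0),
        ))
    return tracks


def track_displacement(track: Track) -> float:
    """Euclidean distance from the first to the last spot, in µm."""
    return float(np.linalg.norm(track.xy[-1] - track.xy[0]))


def path_length(track: Track) -> float:
    """Total path length: the sum of inter-spot step lengths, in µm."""
    return float(np.linalg.norm(np.diff(track.xy, axis=0), axis=1).sum())


def mean_speed(track: Track) -> float:
    """Mean speed: path length divided by track duration, in µm/s."""
    dur = track.duration
    if dur <= 0:
        raise ValueError("track duration must be > 0")
    return path_length(track) / dur


def track_linearity(track: Track) -> float:
    """Linearity of forward progression.

    The mean straight-line speed (net displacement over total time) divided
    by the mean speed (path length over total time); algebraically the net
    displacement divided by the path length. 1 for perfectly straight
    motion, 0 for a closed loop. A stationary track (zero path length) is
    defined to have linearity 0.
    """
    pl = path_length(track)
    if pl == 0.0:
        logger.info("track %d is stationary; linearity defined as 0", track.track_id)
        return 0.0
    return track_displacement(track) / pl


def compute_msd(track: Track, max_lag: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged mean square displacement over integer frame lags.

    MSD(τ) = mean_i |r(i+τ) − r(i)|² with overlapping windows, for
    τ = 0 … max_lag (default: the track's maximal lag n−1, whose single
    window makes MSD equal the squared net displacement). Returns
    (lags in seconds, MSD in µm²). Assumes contiguous frames (gap-closed).
    """
    n = len(track)
    if max_lag is None:
        max_lag = n - 1
    if not 0 < max_lag <= n - 1:
        raise ValueError("max_lag must be in [1, n_frames - 1]")
    msd = np.zeros(max_lag + 1)
    for lag in range(1, max_lag + 1):
        disp = track.xy[lag:] - track.xy[:-lag]
        msd[lag] = float(np.mean(np.sum(disp**2, axis=1)))
    lags = np.arange(max_lag + 1) * track.frame_interval
    return lags, msd


def velocity_autocorrelation(
    track: Track, max_lag: int | None = None, normalized: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Velocity autocorrelation over integer frame lags.

    Frame-to-frame velocities v_i = (r_{i+1} − r_i)/dt; VAC(τ) =
    mean_i(v_i · v_{i+τ}), normalized by mean_i |v_i|² so VAC(0) = 1
    (set ``normalized=False`` for the raw second moment in µm²/s²).
    ≈0 at τ ≥ 1 for Brownian motion, positive for persistent directed runs.
    A stationary track gives a zero curve with VAC(0) defined as 1.
    """
    n = len(track)
    if max_lag is None:
        max_lag = n - 2
    if not 0 <= max_lag <= n - 2:
        raise ValueError("track length must be >= max_lag + 2")
    v = np.diff(track.xy, axis=0) / track.frame_interval
    norm = float(np.mean(np.sum(v**2, axis=1)))
    vac = np.zeros(max_lag + 1)
    if norm == 0.0:
        logger.info("track %d has zero velocity; VAC(0) defined as 1", track.track_id)
        vac[0] = 1.0
    else:
        for lag in range(max_lag + 1):
            dots = np.sum(v[: len(v) - lag] * v[lag:], axis=1)
            vac[lag] = float(np.mean(dots))
        vac = vac / norm if normalized else vac
    lags = np.arange(max_lag + 1) * track.frame_interval
    return lags, vac


def compute_metrics(track: Track, max_lag: int | None = None) -> TrackMetrics:
    """Compute the full per-track motion summary."""
    disp = track_displacement(track)
    pl = path_length(track)
    dur = track.duration
    msd_lags, msd = compute_msd(track)
    vac_max = max_lag if max_lag is not None else len(track) - 2
    vac_lags, vac = velocity_autocorrelation(track, max_lag=vac_max)
    return TrackMetrics(
        track_id=track.track_id,
        n_frames=len(track),
        duration=dur,
        displacement=disp,
        path_length=pl,
        linearity=track_linearity(track),
        mean_speed=pl / dur,
        msd_lags=msd_lags if max_lag is None else msd_lags[: max_lag + 1],
        msd=msd if max_lag is None else msd[: max_lag + 1],
        vac_lags=vac_lags,
        vac=vac,
        msd_at_max_lag=float(msd[-1]),
    )


def ensemble_msd(tracks: list[Track], max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble MSD: per-track time-averaged curves averaged with equal weight."""
    curves = [compute_msd(t, max_lag=min(max_lag, len(t) - 1))[1] for t in tracks]
    out = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1)
    for c in curves:
        out[: len(c)] += c
        counts[: len(c)] += 1
    lags = np.arange(max_lag + 1) * tracks[0].frame_interval
    return lags, out / np.maximum(counts, 1)


def ensemble_vac(tracks: list[Track], max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble velocity autocorrelation, averaged with equal weight per track."""
    out = np.zeros(max_lag + 1)
    counts = np.zeros(max_lag + 1)
    for t in tracks:
        ml = min(max_lag, len(t) - 2)
        _, vac = velocity_autocorrelation(t, max_lag=ml)
        out[: ml + 1] += vac
        counts[: ml + 1] += 1
    lags = np.arange(max_lag + 1) * tracks[0].frame_interval
    return lags, out / np.maximum(counts, 1)
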