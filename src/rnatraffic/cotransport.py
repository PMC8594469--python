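"""Two-channel cotransport analysis and kymographs.

A cotransport event is the sustained co-movement of a motor molecule (one
channel) with an mRNA molecule (the other channel): two tracks sharing at
least ``min_overlap`` frames whose mean per-frame separation stays at or
below ``max_sep`` (default 0.3 µm, about the diffraction limit). Traveled
distance and mean speed are measured on the mRNA channel over the overlap
window. Kymographs resample each frame along a polyline path, taking the
maximum across a perpendicular line width, so moving particles appear as
sloped lines (slope = speed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import stats

from .core import ImageStack, Track


@dataclass
class CotransportEvent:
    track_a_id: int  # motor channel
    track_b_id: int  # mRNA channel
    overlap_frames: int
    mean_pair_distance: float  # µm
    traveled_distance: float  # µm, path length of the mRNA track over the overlap
    mean_speed: float  # µm/s, traveled_distance / overlap duration


@dataclass
class Kymograph:
    image: np.ndarray  # (path positions, n_frames)
    path: np.ndarray  # (k, 2) polyline vertices in µm
    line_width: int  # px
    pixel_size: float  # µm/px (sampling step along the path)


def _overlap(a: Track, b: Track) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Common frames of two tracks and the index-aligned positions."""
    common, ia, ib = np.intersect1d(a.frames, b.frames, return_indices=True)
    return common, a.xy[ia], b.xy[ib]


def pair_tracks(
    tracks_a: list[Track],
    tracks_b: list[Track],
    max_sep: float = 0.3,
    min_overlap: int = 10,
) -> list[CotransportEvent]:
    """Match motor-channel tracks (a) with mRNA-channel tracks (b).

    Every (a, b) pair with at least ``min_overlap`` common frames and mean
    per-frame distance ≤ ``max_sep`` is a candidate; candidates are ranked
    by ascending mean distance and assigned greedily so each track joins at
    most one event.
    """
    if max_sep <= 0 or min_overlap < 1:
        raise ValueError("max_sep must be > 0 and min_overlap >= 1")
    candidates = []
    for ai, a in enumerate(tracks_a):
        for bi, b in enumerate(tracks_b):
            common, xa, xb = _overlap(a, b)
            if len(common) < min_overlap:
                continue
            mean_d = float(np.mean(np.linalg.norm(xa - xb, axis=1)))
            if mean_d <= max_sep:
                candidates.append((mean_d, ai, bi, len(common)))
    candidates.sort()

    events: list[CotransportEvent] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    for mean_d, ai, bi, n_common in candidates:
        if ai in used_a or bi in used_b:
            continue
        used_a.add(ai)
        used_b.add(bi)
        a, b = tracks_a[ai], tracks_b[bi]
        dist = event_distance_tracks(a, b)
        dur = _overlap_duration(a, b)
        events.append(CotransportEvent(
            track_a_id=a.track_id, track_b_id=b.track_id,
            overlap_frames=n_common, mean_pair_distance=mean_d,
            traveled_distance=dist,
            mean_speed=dist / dur if dur > 0 else 0.0,
        ))
    return events


def _overlap_duration(a: Track, b: Track) -> float:
    common, _, _ = _overlap(a, b)
    return float((common[-1] - common[0]) * b.frame_interval)


def event_distance_tracks(a: Track, b: Track) -> float:
    """Path length (µm) of the mRNA-channel track ``b`` over the overlap window."""
    common, _, xb = _overlap(a, b)
    if len(common) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(xb, axis=0), axis=1).sum())


def event_distance(event: CotransportEvent, tracks_a: list[Track],
                   tracks_b: list[Track]) -> float:
    a = _by_id(tracks_a, event.track_a_id)
    b = _by_id(tracks_b, event.track_b_id)
    return event_distance_tracks(a, b)


def event_mean_speed(event: CotransportEvent, tracks_a: list[Track],
                     tracks_b: list[Track]) -> float:
    """Traveled distance over the overlap divided by the overlap duration, µm/s."""
    a = _by_id(tracks_a, event.track_a_id)
    b = _by_id(tracks_b, event.track_b_id)
    dur = _overlap_duration(a, b)
    if dur <= 0:
        raise ValueError("overlap duration must be > 0")
    return event_distance_tracks(a, b) / dur


def _by_id(tracks: list[Track], track_id: int) -> Track:
    for t in tracks:
        if t.track_id == track_id:
            return t
    raise KeyError(f"no track with id {track_id}")


def cohort_summary(events: list[CotransportEvent], confidence: float = 0.95
                   ) -> dict:
    """Cohort mean speed and distance with t-interval confidence bounds."""
    if not events:
        raise ValueError("no events to summarize")
    speeds = np.array([e.mean_speed for e in events])
    dists = np.array([e.traveled_distance for e in events])

    def ci(x: np.ndarray) -> tuple[float, float]:
        if len(x) < 2 or x.std(ddof=1) == 0:
            return (float(x.mean()), float(x.mean()))
        lo, hi = stats.t.interval(confidence, len(x) - 1, loc=x.mean(),
                                  scale=stats.sem(x))
        return float(lo), float(hi)

    return {
        "n_events": len(events),
        "mean_speed_um_s": float(speeds.mean()),
        "speed_ci": ci(speeds),
        "mean_distance_um": float(dists.mean()),
        "distance_ci": ci(dists),
    }


def kymograph(stack: ImageStack, path: np.ndarray, line_width: int = 3) -> Kymograph:
    """Build a position-along-path × time kymograph.

    The polyline ``path`` (vertices in µm) is discretized at one-pixel
    steps; for each frame the intensity at each path position is the
    maximum over ``line_width`` samples along the local perpendicular.
    """
    path = np.asarray(path, float).reshape(-1, 2)
    if len(path) < 2:
        raise ValueError("path needs at least 2 vertices")
    px = stack.pixel_size
    h, w = stack.shape
    if np.any(path[:, 0] < 0) or np.any(path[:, 1] < 0) \
            or np.any(path[:, 0] > (w - 1) * px) or np.any(path[:, 1] > (h - 1) * px):
        raise ValueError("path extends outside the image bounds")

    # discretize the polyline at pixel_size steps
    seg_len = np.linalg.norm(np.diff(path, axis=0), axis=1)
    total = seg_len.sum()
    n_samples = max(int(math.floor(total / px)) + 1, 2)
    s = np.linspace(0.0, total, n_samples)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    xs = np.interp(s, cum, path[:, 0])
    ys = np.interp(s, cum, path[:, 1])

    # unit tangents -> perpendiculars for the width sampling
    tx = np.gradient(xs)
    ty = np.gradient(ys)
    norm = np.hypot(tx, ty)
    norm[norm == 0] = 1.0
    nx, ny = -ty / norm, tx / norm

    offsets = (np.arange(line_width) - (line_width - 1) / 2.0) * px
    img = np.zeros((n_samples, stack.n_frames))
    for f in range(stack.n_frames):
        frame = stack.frames[f]
        best = np.full(n_samples, -np.inf)
        for off in offsets:
            cols = (xs + off * nx) / px
            rows = (ys + off * ny) / px
            vals = ndimage.map_coordinates(frame, [rows, cols], order=1,
                                           mode="nearest")
            best = np.maximum(best, vals)
        img[:, f] = best
    return Kymograph(image=img, path=path, line_width=line_width, pixel_size=px)
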