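"""Seeded generator of ground-truth trajectories, cell geometries and movies.

The generator emulates the statistical structure of live-cell single-mRNA
imaging experiments: a large pool of particles undergoing Brownian diffusion,
a small minority (a few percent) moving in persistent directed runs at motor
speeds of ~2.6 µm/s, acquisition at ~6.66–7.36 frames per second, and
diffraction-limited spots of unimodal single-molecule intensity with
occasional brighter multi-molecule clusters. Drug perturbations are modelled
at the level of their known effect on motion modes: microtubule
depolymerization (nocodazole) removes the directed population entirely,
while actin disruption (cytochalasin D) and vehicle (DMSO) leave it intact.

Every operation takes an explicit seed and is deterministic given it.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import polygon2mask

from .core import CellGeometry, ImageStack, Track

DEFAULT_FRAME_RATE = 6.66  # fps, single-color mRNA tracking acquisition
TWO_COLOR_FRAME_RATE = 7.36  # fps, sequential two-color acquisition
DEFAULT_DIRECTED_SPEED = 2.6  # µm/s, motor-driven run speed
DEFAULT_DIFFUSION = 0.1  # µm²/s, cytoplasmic mRNP mobility
DEFAULT_LOCALIZATION_NOISE = 0.03  # µm, centroid localization error


@dataclass(frozen=True)
class MotionParams:
    """Parameters of the two-mode particle motion model.

    ``directed_fraction`` is the proportion of tracks undergoing persistent
    directed runs; the remainder diffuse. ``direction_jitter`` is the s.d.
    of the per-step heading change of directed runs (radians/step).
    """

    diffusion_coefficient: float = DEFAULT_DIFFUSION  # µm²/s
    directed_speed: float = DEFAULT_DIRECTED_SPEED  # µm/s
    directed_fraction: float = 0.05
    direction_jitter: float = 0.1  # rad/step
    frame_interval: float = 1.0 / DEFAULT_FRAME_RATE  # s
    n_frames: int = 100
    localization_noise: float = DEFAULT_LOCALIZATION_NOISE  # µm

    def __post_init__(self) -> None:
        if self.diffusion_coefficient < 0:
            raise ValueError("diffusion_coefficient must be >= 0")
        if self.directed_speed < 0:
            raise ValueError("directed_speed must be >= 0")
        if not 0.0 <= self.directed_fraction <= 1.0:
            raise ValueError("directed_fraction must lie in [0, 1]")
        if self.direction_jitter < 0:
            raise ValueError("direction_jitter must be >= 0")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.localization_noise < 0:
            raise ValueError("localization_noise must be >= 0")


class Perturbation(enum.Enum):
    """Simulated drug treatment, acting on the motion-mode mixture only."""

    NONE = "none"
    NOCODAZOLE = "nocodazole"  # microtubule depolymerization: no directed runs
    CYTOCHALASIN_D = "cytochalasinD"  # actin disruption: directed runs intact
    DMSO = "dmso"  # vehicle control: no effect

    @property
    def abolishes_directed(self) -> bool:
        return self is Perturbation.NOCODAZOLE


@dataclass(frozen=True)
class RenderParams:
    """Rendering parameters for synthetic movies.

    Each emitter is drawn as an integrable 2D Gaussian whose total integral
    equals its molecular intensity; a cluster of multiplicity *m* has
    expected intensity m × the single-molecule mean.
    """

    psf_sigma: float = 0.15  # µm (diffraction-limited width at ~100x)
    single_molecule_intensity: tuple[float, float] = (1000.0, 100.0)  # mean, sd (a.u.)
    cluster_multiplicity: int = 6
    background_level: float = 100.0  # a.u.
    noise_sd: float = 10.0  # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.cluster_multiplicity < 2:
            raise ValueError("cluster_multiplicity must be >= 2")
        if self.noise_sd < 0 or self.background_level < 0:
            raise ValueError("background_level and noise_sd must be >= 0")


def simulate_brownian_track(
    params: MotionParams,
    origin: tuple[float, float] = (0.0, 0.0),
    seed: int = 0,
    track_id: int = 0,
) -> Track:
    """Simulate an isotropic 2D Brownian trajectory.

    Each per-axis step increment is drawn N(0, 2·D·dt) so the ensemble mean
    square displacement grows as 4·D·τ. Independent Gaussian localization
    noise of s.d. ``localization_noise`` is added to every observed position.
    """
    rng = np.random.default_rng(seed)
    dt = params.frame_interval
    n = params.n_frames
    step_sd = math.sqrt(2.0 * params.diffusion_coefficient * dt)
    steps = rng.normal(0.0, step_sd, size=(n - 1, 2))
    xy = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)]) + np.asarray(origin, float)
    if params.localization_noise > 0:
        xy = xy + rng.normal(0.0, params.localization_noise, size=xy.shape)
    return Track(track_id=track_id, frames=np.arange(n), xy=xy,
                 frame_interval=dt, label="diffusive")


def simulate_directed_track(
    params: MotionParams,
    heading: float = 0.0,
    seed: int = 0,
    origin: tuple[float, float] = (0.0, 0.0),
    track_id: int = 0,
) -> Track:
    """Simulate a persistent directed run at constant speed.

    The particle advances ``directed_speed * frame_interval`` per step along
    a heading that performs a random walk with per-step s.d.
    ``direction_jitter``; localization noise is added as for Brownian tracks.
    No pausing: the run persists for the full track (the simplest kinetics
    that reproduce the long/linear phenotype the classifier targets).
    """
    if params.directed_speed <= 0:
        raise ValueError("directed_speed must be > 0 for a directed track")
    rng = np.random.default_rng(seed)
    dt = params.frame_interval
    n = params.n_frames
    step_len = params.directed_speed * dt
    if params.direction_jitter > 0:
        headings = heading + np.cumsum(rng.normal(0.0, params.direction_jitter, size=n - 1))
    else:
        headings = np.full(n - 1, heading)
    steps = step_len * np.column_stack([np.cos(headings), np.sin(headings)])
    xy = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)]) + np.asarray(origin, float)
    if params.localization_noise > 0:
        xy = xy + rng.normal(0.0, params.localization_noise, size=xy.shape)
    return Track(track_id=track_id, frames=np.arange(n), xy=xy,
                 frame_interval=dt, label="directed")


def simulate_population(
    params: MotionParams,
    n_tracks: int,
    perturbation: Perturbation = Perturbation.NONE,
    seed: int = 0,
    geometry: CellGeometry | None = None,
) -> tuple[list[Track], list[str]]:
    """Simulate a mixed population of directed and diffusive tracks.

    Exactly ``round(directed_fraction * n_tracks)`` tracks are directed
    (zero under nocodazole, whatever the fraction). When a ``geometry`` is
    given, origins are sampled uniformly over the cytoplasm and directed
    runs head outward from the nucleus centroid (anterograde, toward the
    cell edge); otherwise origins are spread on a loose grid and directed
    headings are drawn uniformly.

    Returns the tracks and their ground-truth labels, index-aligned.
    """
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    rng = np.random.default_rng(seed)
    fraction = 0.0 if perturbation.abolishes_directed else params.directed_fraction
    n_directed = int(round(fraction * n_tracks))
    # directed tracks drawn first; placement below does not depend on order
    kinds = ["directed"] * n_directed + ["diffusive"] * (n_tracks - n_directed)

    if geometry is not None:
        origins = sample_spot_positions(geometry, "uniform", n_tracks,
                                        seed=int(rng.integers(2**31)))
        cx, cy = geometry.nucleus_centroid
    else:
        # loose grid spacing keeps unrelated tracks well separated for linking
        side = math.ceil(math.sqrt(n_tracks))
        spacing = 40.0
        idx = np.arange(n_tracks)
        origins = np.column_stack([(idx % side) * spacing, (idx // side) * spacing])

    tracks: list[Track] = []
    labels: list[str] = []
    for i, kind in enumerate(kinds):
        sub_seed = int(rng.integers(2**31))
        origin = tuple(origins[i])
        if kind == "directed":
            if geometry is not None:
                heading = math.atan2(origin[1] - cy, origin[0] - cx)
            else:
                heading = float(rng.uniform(0, 2 * math.pi))
            tr = simulate_directed_track(params, heading=heading, seed=sub_seed,
                                         origin=origin, track_id=i)
        else:
            tr = simulate_brownian_track(params, origin=origin, seed=sub_seed, track_id=i)
        tracks.append(tr)
        labels.append(kind)
    return tracks, labels


def make_cell_geometry(
    width_px: int = 256,
    height_px: int = 256,
    pixel_size: float = 0.1,
    nucleus_radius_fraction: float = 0.3,
    irregularity: float = 0.15,
    seed: int = 0,
) -> CellGeometry:
    """Generate a single-cell geometry: an irregular cell outline with a
    round nucleus at its centre.

    ``irregularity`` scales smooth low-order radial perturbations of the
    cell boundary (0 gives concentric discs). The nucleus radius is
    ``nucleus_radius_fraction`` of the mean cell radius and always fits
    strictly inside the cell.
    """
    if not 0.0 < nucleus_radius_fraction < 0.9:
        raise ValueError("nucleus_radius_fraction must lie in (0, 0.9)")
    if irregularity < 0:
        raise ValueError("irregularity must be >= 0")
    rng = np.random.default_rng(seed)
    cy, cx = (height_px - 1) / 2.0, (width_px - 1) / 2.0
    base_r = 0.42 * min(width_px, height_px)

    theta = np.linspace(0, 2 * math.pi, 720, endpoint=False)
    radial = np.ones_like(theta)
    if irregularity > 0:
        for k in range(2, 6):  # low-order harmonics: smooth, blob-like outline
            amp = irregularity * rng.uniform(0.2, 1.0) / k
            phase = rng.uniform(0, 2 * math.pi)
            radial += amp * np.cos(k * theta + phase)
    # cap deformation so the nucleus disc is guaranteed to fit
    min_rel = max(nucleus_radius_fraction + 0.08, 0.35)
    radial = np.clip(radial, min_rel, 1.35)
    r = base_r * radial
    rows = cy + r * np.sin(theta)
    cols = cx + r * np.cos(theta)
    cell_mask = polygon2mask((height_px, width_px), np.column_stack([rows, cols]))

    nuc_r = nucleus_radius_fraction * base_r
    if nuc_r >= r.min():
        raise ValueError("nucleus does not fit inside the cell boundary")
    yy, xx = np.mgrid[0:height_px, 0:width_px]
    nucleus_mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= nuc_r**2
    nucleus_mask &= cell_mask
    return CellGeometry(cell_mask=cell_mask, nucleus_mask=nucleus_mask,
                        pixel_size=pixel_size,
                        nucleus_centroid=(cx * pixel_size, cy * pixel_size))


def sample_spot_positions(
    geometry: CellGeometry,
    pattern: str,
    n: int,
    seed: int = 0,
    decay_um: float = 2.0,
) -> np.ndarray:
    """Sample ``n`` positions (µm) from a spatial pattern over the cytoplasm.

    Patterns
    --------
    uniform
        Uniform over cytoplasm pixels (uniform jitter within each pixel).
    perinuclear
        Density decaying exponentially with distance from the nucleus
        boundary (length scale ``decay_um``).
    peripheral
        Density concentrated in a rim near the cell edge, decaying with
        distance from the boundary inward.
    centroid
        All positions at the nucleus centroid (degenerate reference).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if pattern == "centroid":
        return np.tile(np.asarray(geometry.nucleus_centroid, float), (n, 1))

    cyto = geometry.cytoplasm_mask
    ys, xs = np.nonzero(cyto)
    if len(xs) == 0:
        raise ValueError("geometry has an empty cytoplasm")
    rng = np.random.default_rng(seed)
    px = geometry.pixel_size

    if pattern == "uniform":
        weights = None
    elif pattern == "perinuclear":
        d_nuc = ndimage.distance_transform_edt(~geometry.nucleus_mask) * px
        weights = np.exp(-d_nuc[ys, xs] / decay_um)
    elif pattern == "peripheral":
        d_edge = ndimage.distance_transform_edt(geometry.cell_mask) * px
        weights = np.exp(-d_edge[ys, xs] / decay_um)
    else:
        raise ValueError(f"unknown pattern: {pattern!r}")

    if weights is not None:
        weights = weights / weights.sum()
    idx = rng.choice(len(xs), size=n, p=weights)
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2))
    return np.column_stack([(xs[idx] + jitter[:, 0]) * px,
                            (ys[idx] + jitter[:, 1]) * px])


def _add_gaussian(frame: np.ndarray, x_px: float, y_px: float,
                  integral: float, sigma_px: float) -> None:
    """Accumulate a 2D Gaussian of given total integral onto ``frame`` in place."""
    h, w = frame.shape
    half = int(math.ceil(5 * sigma_px))
    x0, x1 = max(0, int(x_px) - half), min(w, int(x_px) + half + 1)
    y0, y1 = max(0, int(y_px) - half), min(h, int(y_px) + half + 1)
    if x0 >= x1 or y0 >= y1:
        return
    xs = np.arange(x0, x1)
    ys = np.arange(y0, y1)
    gx = np.exp(-0.5 * ((xs - x_px) / sigma_px) ** 2)
    gy = np.exp(-0.5 * ((ys - y_px) / sigma_px) ** 2)
    amp = integral / (2 * math.pi * sigma_px**2)
    frame[y0:y1, x0:x1] += amp * np.outer(gy, gx)


def render_stack(
    tracks: list[Track],
    static_spots: list[tuple[tuple[float, float], int]] | None = None,
    geometry: CellGeometry | None = None,
    render: RenderParams = RenderParams(),
    shape: tuple[int, int] | None = None,
    pixel_size: float = 0.1,
    frame_interval: float | None = None,
    n_frames: int | None = None,
) -> ImageStack:
    """Render tracks and static emitters into a noisy movie.

    Each frame is ``background + Σ Gaussian(emitter)`` plus i.i.d. Gaussian
    read noise. A moving emitter keeps one intensity (drawn once from the
    single-molecule distribution) for its whole lifetime; a static spot of
    multiplicity *m* is drawn with m times the single-molecule mean.
    """
    if geometry is not None:
        shape = geometry.shape
        pixel_size = geometry.pixel_size
    if shape is None:
        raise ValueError("provide either a geometry or an explicit shape")
    static_spots = static_spots or []

    if frame_interval is None:
        frame_interval = tracks[0].frame_interval if tracks else 1.0 / DEFAULT_FRAME_RATE
    if n_frames is None:
        n_frames = max((int(t.frames[-1]) + 1 for t in tracks), default=1)

    rng = np.random.default_rng(render.seed)
    mean_i, sd_i = render.single_molecule_intensity
    sigma_px = render.psf_sigma / pixel_size

    track_intensity = {t.track_id: max(rng.normal(mean_i, sd_i), 0.0) for t in tracks}
    static_intensity = [max(rng.normal(m * mean_i, sd_i * math.sqrt(m)), 0.0)
                        for _, m in static_spots]

    frames = np.full((n_frames, *shape), float(render.background_level))
    for t in tracks:
        for f, (x, y) in zip(t.frames, t.xy):
            if 0 <= f < n_frames:
                _add_gaussian(frames[f], x / pixel_size, y / pixel_size,
                              track_intensity[t.track_id], sigma_px)
    for ((x, y), _m), integral in zip(static_spots, static_intensity):
        for f in range(n_frames):
            _add_gaussian(frames[f], x / pixel_size, y / pixel_size, integral, sigma_px)

    if render.noise_sd > 0:
        frames += rng.normal(0.0, render.noise_sd, size=frames.shape)
        np.clip(frames, 0.0, None, out=frames)
    return ImageStack(frames=frames, pixel_size=pixel_size, frame_interval=frame_interval)
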