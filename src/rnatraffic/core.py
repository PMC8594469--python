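"""Core in-memory containers shared across the pipeline.

All physical coordinates are in micrometres (µm), time in seconds. Pixel
coordinates use the raster convention: origin at the top-left pixel centre,
x increasing rightward (columns), y increasing downward (rows). Conversion
between pixel and physical coordinates is always ``x_um = x_px * pixel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Spot:
    """A detected point emitter in one frame.

    Attributes
    ----------
    x, y : float
        Position in µm.
    frame : int
        Zero-based frame index.
    intensity : float
        Background-subtracted integrated intensity (arbitrary units, >= 0).
    channel : int
        Acquisition channel index.
    """

    x: float
    y: float
    frame: int
    intensity: float = 0.0
    channel: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.intensity) or self.intensity < 0:
            raise ValueError(f"spot intensity must be finite and >= 0, got {self.intensity}")


@dataclass
class Track:
    """An ordered single-particle trajectory; the unit of all motion metrics.

    Positions are stored as arrays rather than ``Spot`` objects so that
    metric computations vectorize; :meth:`spots` materializes the per-frame
    view when needed.

    Attributes
    ----------
    track_id : int
    frames : ndarray of int, shape (n,)
        Strictly increasing frame indices.
    xy : ndarray of float, shape (n, 2)
        Positions in µm, columns (x, y).
    frame_interval : float
        Seconds per frame.
    intensity : ndarray or None
        Per-spot integrated intensities (a.u.).
    interpolated : ndarray of bool or None
        True for virtual spots inserted by gap closing; such spots carry
        no measured intensity and are excluded from intensity statistics.
    channel : int
    label : str or None
        Ground-truth motion label when the track comes from the simulator
        ("directed" or "diffusive").
    """

    track_id: int
    frames: np.ndarray
    xy: np.ndarray
    frame_interval: float
    intensity: np.ndarray | None = None
    interpolated: np.ndarray | None = None
    channel: int = 0
    label: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValueError("xy must have shape (n, 2)")
        if len(self.frames) != len(self.xy):
            raise ValueError("frames and xy length mismatch")
        if len(self.frames) < 2:
            raise ValueError("a track needs at least 2 spots")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def t(self) -> np.ndarray:
        """Time of each spot in seconds."""
        return self.frames * self.frame_interval

    @property
    def duration(self) -> float:
        """Elapsed time from first to last spot, in seconds."""
        return float((self.frames[-1] - self.frames[0]) * self.frame_interval)

    def spots(self) -> list[Spot]:
        inten = self.intensity if self.intensity is not None else np.zeros(len(self))
        return [
            Spot(x=float(x), y=float(y), frame=int(f), intensity=float(max(i, 0.0)),
                 channel=self.channel)
            for (x, y), f, i in zip(self.xy, self.frames, inten)
        ]


@dataclass
class ImageStack:
    """A time-ordered stack of 2D intensity frames with physical calibration."""

    frames: np.ndarray  # (t, h, w) float
    pixel_size: float  # µm per pixel
    frame_interval: float  # seconds per frame

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (t, h, w)")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass
class CellGeometry:
    """Cell and nucleus masks plus the nucleus centroid, in one frame of reference.

    Masks are boolean rasters of identical shape; the nucleus must be strictly
    inside the cell. The cytoplasm is ``cell_mask & ~nucleus_mask``.
    """

    cell_mask: np.ndarray
    nucleus_mask: np.ndarray
    pixel_size: float  # µm per pixel
    nucleus_centroid: tuple[float, float] = field(default=None)  # (x, y) in µm

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        self.nucleus_mask = np.asarray(self.nucleus_mask, dtype=bool)
        if self.cell_mask.shape != self.nucleus_mask.shape:
            raise ValueError("cell and nucleus masks must share a shape")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if np.any(self.nucleus_mask & ~self.cell_mask):
            raise ValueError("nucleus_mask must lie inside cell_mask")
        if self.nucleus_centroid is None:
            ys, xs = np.nonzero(self.nucleus_mask)
            if len(xs) == 0:
                raise ValueError("empty nucleus mask")
            self.nucleus_centroid = (float(xs.mean()) * self.pixel_size,
                                     float(ys.mean()) * self.pixel_size)

    @property
    def cytoplasm_mask(self) -> np.ndarray:
        return self.cell_mask & ~self.nucleus_mask

    @property
    def shape(self) -> tuple[int, int]:
        return self.cell_mask.shape
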