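"""Directed-versus-diffusive track classification.

Tracks surviving a minimum-duration filter are split into "long/directed"
and "short/diffuse" classes by strict thresholds on net displacement and
linearity of forward progression (defaults: >4 µm and >0.7, established by
comparing motion before and after microtubule depolymerization). Thresholds
can also be derived from a depolymerized control population as joint
marginal quantiles at a chosen false-positive rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .core import Track
from .tracking import TrackMetrics

LONG_DIRECTED = "long_directed"
SHORT_DIFFUSE = "short_diffuse"


@dataclass(frozen=True)
class ClassifierThresholds:
    """Strict lower bounds defining the long/directed class."""

    min_duration: float = 2.5  # s
    min_displacement: float = 4.0  # µm
    min_linearity: float = 0.7

    def __post_init__(self) -> None:
        if self.min_duration <= 0 or self.min_displacement <= 0 or self.min_linearity <= 0:
            raise ValueError("thresholds must be strictly positive")
        if self.min_linearity > 1:
            raise ValueError("min_linearity must be <= 1")


@dataclass
class ClassifiedTrack:
    track_id: int
    metrics: TrackMetrics
    motion_class: str  # LONG_DIRECTED or SHORT_DIFFUSE


def filter_by_duration(tracks: list[Track], min_duration: float = 2.5) -> list[Track]:
    """Keep tracks whose duration strictly exceeds ``min_duration`` seconds."""
    return [t for t in tracks if t.duration > min_duration]


def min_frames(min_duration: float, frame_rate: float) -> int:
    """Smallest frame count n with n/frame_rate strictly above ``min_duration``.

    Counting each frame as one exposure interval, n frames cover
    n/frame_rate seconds, so the answer is ceil(min_duration·frame_rate),
    bumped by one when the product is an exact integer (the coverage must
    strictly exceed the cutoff). At 2.5 s and 6.66 fps this gives the
    canonical 17 consecutive frames.
    """
    if min_duration <= 0 or frame_rate <= 0:
        raise ValueError("min_duration and frame_rate must be > 0")
    product = min_duration * frame_rate
    n = math.ceil(product)
    if math.isclose(n, product):
        n += 1
    return n


def classify_track(metrics: TrackMetrics,
                   thresholds: ClassifierThresholds = ClassifierThresholds()) -> str:
    """long/directed iff displacement AND linearity strictly exceed thresholds."""
    if (metrics.displacement > thresholds.min_displacement
            and metrics.linearity > thresholds.min_linearity):
        return LONG_DIRECTED
    return SHORT_DIFFUSE


def classify_tracks(metrics_list: list[TrackMetrics],
                    thresholds: ClassifierThresholds = ClassifierThresholds()
                    ) -> list[ClassifiedTrack]:
    return [ClassifiedTrack(m.track_id, m, classify_track(m, thresholds))
            for m in metrics_list]


def directed_fraction(classified: list[ClassifiedTrack]) -> float:
    """Percentage of tracks classified long/directed (0–100)."""
    if not classified:
        raise ValueError("directed_fraction is undefined for an empty track list")
    n_dir = sum(1 for c in classified if c.motion_class == LONG_DIRECTED)
    return 100.0 * n_dir / len(classified)


def derive_thresholds(
    control_metrics: list[TrackMetrics],
    target_fpr: float = 0.0,
    min_duration: float = 2.5,
) -> ClassifierThresholds:
    """Derive displacement/linearity thresholds from a depolymerized control.

    Each threshold is the (1 − target_fpr) quantile of the control
    (microtubule-depolymerized, hence purely diffusive) distribution of
    that metric, so at most ~target_fpr of control tracks exceed both. A
    degenerate control distribution (zero spread) falls back to the default
    thresholds with a warning.
    """
    if not control_metrics:
        raise ValueError("control set must be non-empty")
    if not 0.0 <= target_fpr < 1.0:
        raise ValueError("target_fpr must lie in [0, 1)")
    disp = np.array([m.displacement for m in control_metrics])
    lin = np.array([m.linearity for m in control_metrics])
    if disp.std() == 0.0 or lin.std() == 0.0:
        warnings.warn("degenerate control distribution; falling back to default thresholds")
        return ClassifierThresholds(min_duration=min_duration)
    q = 1.0 - target_fpr
    return ClassifierThresholds(
        min_duration=min_duration,
        min_displacement=float(np.quantile(disp, q)),
        min_linearity=min(float(np.quantile(lin, q)), 1.0),
    )
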