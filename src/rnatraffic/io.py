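"""File formats, configuration and the end-to-end pipeline driver.

Interchange formats are deliberately plain: CSV for spots, tracks, metrics
and summaries (positions in µm, times in seconds, pixel coordinates
alongside where useful), 8-bit 0/255 single-channel images for masks,
multi-page TIFF plus a sidecar JSON ({"pixel_size_um", "frame_interval_s"})
for movies, YAML or JSON for configuration. ``run_pipeline`` chains
simulate → metrics → classify → pdi → clusters deterministically under one
seed and writes a manifest with SHA-256 hashes of every output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import classification, clusters as clu, pdi as pdi_mod, synthetic, tracking
from .core import CellGeometry, ImageStack, Spot, Track

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]


def write_tracks_csv(tracks: list[Track], path: str | Path) -> Path:
    """Write tracks in long format, sorted by (track_id, frame)."""
    rows = []
    for t in tracks:
        inten = t.intensity if t.intensity is not None else np.full(len(t), np.nan)
        interp = t.interpolated if t.interpolated is not None else np.zeros(len(t), bool)
        for i in range(len(t)):
            rows.append({
                "track_id": t.track_id, "frame": int(t.frames[i]),
                "t_s": float(t.frames[i] * t.frame_interval),
                "x_um": float(t.xy[i, 0]), "y_um": float(t.xy[i, 1]),
                "intensity": float(inten[i]), "channel": t.channel,
                "interpolated": bool(interp[i]),
                "label": t.label if t.label is not None else "",
            })
    df = pd.DataFrame(rows).sort_values(["track_id", "frame"])
    path = Path(path)
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_tracks_csv(path: str | Path, frame_interval: float | None = None
                    ) -> list[Track]:
    """Read a tracks CSV back into :class:`Track` objects.

    The frame interval is recovered from the t_s column when possible
    (or passed explicitly). Duplicated (track_id, frame) rows and
    non-monotone frames raise a validation error.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tracks CSV is missing column(s): {', '.join(missing)}")
    if df.duplicated(subset=["track_id", "frame"]).any():
        raise ValueError("duplicated (track_id, frame) row in tracks CSV")
    if df.empty:
        return []
    if frame_interval is None:
        steps = df.sort_values(["track_id", "frame"]).groupby("track_id")
        dts = []
        for _, g in steps:
            df_t = np.diff(g["t_s"].to_numpy())
            df_f = np.diff(g["frame"].to_numpy())
            good = df_f > 0
            if good.any():
                dts.extend(df_t[good] / df_f[good])
        frame_interval = float(np.median(dts)) if dts else 1.0

    tracks = []
    for tid, g in df.sort_values(["track_id", "frame"]).groupby("track_id"):
        frames = g["frame"].to_numpy(int)
        if np.any(np.diff(frames) <= 0):
            raise ValueError(f"non-monotone frames within track {tid}")
        if len(frames) < 2:
            continue
        label = None
        if "label" in g.columns:
            lab = g["label"].iloc[0]
            label = str(lab) if isinstance(lab, str) and lab else None
        tracks.append(Track(
            track_id=int(tid), frames=frames,
            xy=g[["x_um", "y_um"]].to_numpy(float),
            frame_interval=frame_interval,
            intensity=g["intensity"].to_numpy(float) if "intensity" in g.columns else None,
            interpolated=g["interpolated"].to_numpy(bool) if "interpolated" in g.columns else None,
            channel=int(g["channel"].iloc[0]) if "channel" in g.columns else 0,
            label=label,
        ))
    return tracks


def write_spots_csv(spots: list[Spot], path: str | Path,
                    pixel_size: float | None = None,
                    frame_interval: float = 1.0,
                    cell_ids: list | None = None) -> Path:
    rows = []
    for i, s in enumerate(spots):
        row = {"channel": s.channel, "frame": s.frame,
               "t_s": s.frame * frame_interval,
               "x_um": s.x, "y_um": s.y, "intensity": s.intensity}
        if pixel_size:
            row["x_px"] = s.x / pixel_size
            row["y_px"] = s.y / pixel_size
        if cell_ids is not None:
            row["cell_id"] = cell_ids[i]
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.9g")
    return path


def read_spots_csv(path: str | Path) -> list[Spot]:
    df = pd.read_csv(path)
    for col in ("frame", "x_um", "y_um"):
        if col not in df.columns:
            raise ValueError(f"spots CSV is missing column: {col}")
    return [Spot(x=float(r.x_um), y=float(r.y_um), frame=int(r.frame),
                 intensity=float(getattr(r, "intensity", 0.0) or 0.0),
                 channel=int(getattr(r, "channel", 0) or 0))
            for r in df.itertuples()]


def metrics_to_frame(metrics: list[tracking.TrackMetrics]) -> pd.DataFrame:
    return pd.DataFrame([{
        "track_id": m.track_id, "n_frames": m.n_frames, "duration_s": m.duration,
        "displacement_um": m.displacement, "path_um": m.path_length,
        "linearity": m.linearity, "mean_speed_um_s": m.mean_speed,
        "msd_max_um2": m.msd_at_max_lag,
    } for m in metrics])


def curves_to_frame(metrics: list[tracking.TrackMetrics], which: str = "msd"
                    ) -> pd.DataFrame:
    """Long-format MSD or VAC curves: (track_id, lag_s, value)."""
    rows = []
    for m in metrics:
        lags = m.msd_lags if which == "msd" else m.vac_lags
        vals = m.msd if which == "msd" else m.vac
        rows.extend({"track_id": m.track_id, "lag_s": float(l), "value": float(v)}
                    for l, v in zip(lags, vals))
    return pd.DataFrame(rows)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(path) > 127


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Multi-page TIFF plus a calibration sidecar JSON next to it."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"pixel_size_um": stack.pixel_size,
                                   "frame_interval_s": stack.frame_interval}))
    return path


def read_stack(path: str | Path) -> ImageStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    sidecar = path.with_suffix(path.suffix + ".json")
    cal = json.loads(sidecar.read_text())
    return ImageStack(frames=frames, pixel_size=cal["pixel_size_um"],
                      frame_interval=cal["frame_interval_s"])


@dataclass
class PipelineConfig:
    """Configuration of the end-to-end synthetic run.

    Validated in full before any stage executes so a bad parameter fails
    fast with the offending stage and field named.
    """

    seed: int = 0
    outdir: str = "rnatraffic_out"
    motion: dict = field(default_factory=dict)  # MotionParams overrides
    n_tracks: int = 200
    perturbation: str = "none"
    thresholds: dict = field(default_factory=dict)  # ClassifierThresholds overrides
    geometry: dict = field(default_factory=dict)  # make_cell_geometry overrides
    pdi_pattern: str = "uniform"
    pdi_n_spots: int = 2000
    cluster_n_singles: int = 95
    cluster_n_clusters: int = 5
    cluster_multiplicity: int = 6
    single_molecule_intensity: float = 1000.0
    stages: tuple = ("simulate", "metrics", "classify", "pdi", "clusters")

    def validate(self) -> None:
        synthetic.MotionParams(**self.motion)  # raises on bad values
        classification.ClassifierThresholds(**self.thresholds)
        if self.n_tracks < 1:
            raise ValueError("simulate: n_tracks must be >= 1")
        synthetic.Perturbation(self.perturbation)
        if self.pdi_pattern not in ("uniform", "perinuclear", "peripheral", "centroid"):
            raise ValueError(f"pdi: unknown pattern {self.pdi_pattern!r}")
        if self.pdi_n_spots < 1:
            raise ValueError("pdi: n_spots must be >= 1")
        if self.cluster_n_singles < 0 or self.cluster_n_clusters < 0:
            raise ValueError("clusters: counts must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        cfg = cls(**data)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        return cfg

    def to_file(self, path: str | Path) -> Path:
        path = Path(path)
        data = asdict(self)
        data["stages"] = list(self.stages)
        path.write_text(yaml.safe_dump(data, sort_keys=True))
        return path


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages in dependency order; return the manifest.

    Identical config and seed give byte-identical CSV outputs. Any stage
    failure aborts with the stage name in the error message.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"seed": config.seed, "parameters": asdict(config), "outputs": {}}
    manifest["parameters"]["stages"] = list(config.stages)
    outputs: dict[str, Path] = {}

    params = synthetic.MotionParams(**config.motion)
    thresholds = classification.ClassifierThresholds(**config.thresholds)
    tracks: list[Track] = []
    metrics: list[tracking.TrackMetrics] = []

    for stage in config.stages:
        t0 = time.perf_counter()
        try:
            if stage == "simulate":
                tracks, labels = synthetic.simulate_population(
                    params, config.n_tracks,
                    perturbation=synthetic.Perturbation(config.perturbation),
                    seed=int(rng.integers(2**31)))
                outputs["tracks"] = write_tracks_csv(tracks, outdir / "tracks.csv")
            elif stage == "metrics":
                kept = classification.filter_by_duration(tracks, thresholds.min_duration)
                metrics = [tracking.compute_metrics(t) for t in kept]
                metrics_to_frame(metrics).to_csv(outdir / "metrics.csv", index=False,
                                                 float_format="%.9g")
                outputs["metrics"] = outdir / "metrics.csv"
            elif stage == "classify":
                classified = classification.classify_tracks(metrics, thresholds)
                df = metrics_to_frame(metrics)
                df["motion_class"] = [c.motion_class for c in classified]
                df.to_csv(outdir / "classified.csv", index=False, float_format="%.9g")
                pct = (classification.directed_fraction(classified)
                       if classified else float("nan"))
                pd.DataFrame([{"cell_id": 0, "n_tracks": len(classified),
                               "n_directed": sum(c.motion_class == classification.LONG_DIRECTED
                                                 for c in classified),
                               "pct_directed": pct}]).to_csv(
                    outdir / "directed_summary.csv", index=False, float_format="%.9g")
                outputs["classified"] = outdir / "classified.csv"
                outputs["directed_summary"] = outdir / "directed_summary.csv"
            elif stage == "pdi":
                geom = synthetic.make_cell_geometry(
                    seed=int(rng.integers(2**31)), **config.geometry)
                pos = synthetic.sample_spot_positions(
                    geom, config.pdi_pattern, config.pdi_n_spots,
                    seed=int(rng.integers(2**31)))
                res = pdi_mod.compute_pdi(pos, geom)
                pd.DataFrame([{"cell_id": res.cell_id, "n_spots": res.n_spots,
                               "pdi": res.pdi}]).to_csv(
                    outdir / "pdi.csv", index=False, float_format="%.9g")
                outputs["pdi"] = outdir / "pdi.csv"
                outputs["cell_mask"] = write_mask(geom.cell_mask, outdir / "cell_mask.tif")
                outputs["nucleus_mask"] = write_mask(geom.nucleus_mask,
                                                     outdir / "nucleus_mask.tif")
            elif stage == "clusters":
                sub = np.random.default_rng(int(rng.integers(2**31)))
                ref = config.single_molecule_intensity
                singles = sub.normal(ref, 0.1 * ref, size=config.cluster_n_singles)
                multis = sub.normal(config.cluster_multiplicity * ref,
                                    0.1 * ref * np.sqrt(config.cluster_multiplicity),
                                    size=config.cluster_n_clusters)
                inten = np.clip(np.concatenate([singles, multis]), 0, None)
                spots = [Spot(x=0.0, y=0.0, frame=0, intensity=float(v)) for v in inten]
                thr = clu.calibrate_threshold(inten, k=3.0)
                calls = clu.call_clusters(spots, thr, ref)
                summaries, mean, stderr = clu.cluster_frequency({0: calls},
                                                                reference_intensity=ref)
                pd.DataFrame([{"cell_id": s.cell_id, "n_spots": s.n_spots,
                               "n_clusters": s.n_clusters} for s in summaries]).to_csv(
                    outdir / "clusters.csv", index=False, float_format="%.9g")
                outputs["clusters"] = outdir / "clusters.csv"
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        logger.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)

    manifest["outputs"] = {k: {"path": str(p), "sha256": _sha256(p)}
                           for k, p in outputs.items()}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
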