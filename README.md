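# rnatraffic

Quantification of single-molecule mRNA trafficking in fluorescence
microscopy: smFISH-style spot detection, single-particle tracking and
motion metrics, directed-versus-diffusive track classification, the
Peripheral Distribution Index (PDI), RNA-cluster intensity analysis, and
two-color motor–mRNA cotransport detection — together with a seeded
synthetic-movie generator used to validate every stage against ground
truth.

It is written for cell biologists analyzing live imaging of MS2/MCP-tagged
reporter mRNAs (or smFISH images of endogenous transcripts) who need the
standard motion and localization statistics of motor-driven RNA transport
without assembling them from half a dozen tools.

## The statistics at the core

For a trajectory r(t₀), …, r(t_{n−1}) sampled at frame interval Δt:

- **Track displacement** — |r(t_{n−1}) − r(t₀)|, the net first-to-last distance.
- **Linearity of forward progression** — mean straight-line speed divided by
  mean speed, which reduces to net displacement / path length ∈ [0, 1].
- **Mean speed** — path length / track duration.
- **MSD(τ)** — time-averaged ⟨|r(t+τ) − r(t)|²⟩ over overlapping windows;
  4Dτ for 2D diffusion, (vτ)² for directed runs.
- **Velocity autocorrelation VAC(τ)** — ⟨v_t · v_{t+τ}⟩ / ⟨|v_t|²⟩ for
  frame-to-frame velocities; ≈0 at τ ≥ 1 for Brownian motion, positive for
  persistent transport.
- **Classification** — tracks lasting more than 2.5 s (17 frames at
  6.66 fps) are "long/directed" when displacement > 4 µm **and**
  linearity > 0.7, otherwise "short/diffuse"; microtubule depolymerization
  (simulated nocodazole) must reduce the directed class to zero.
- **PDI** — Σwᵢdᵢ²/Σwᵢ normalized by the mean squared distance of cytoplasm
  pixels from the nucleus centroid: 1 for a uniform cytoplasmic signal,
  <1 perinuclear, >1 peripheral.
- **Cluster calling** — spots whose integrated intensity strictly exceeds a
  threshold (fixed, or calibrated as k× the single-molecule modal
  intensity) are multimeric RNA clusters.
- **Cotransport** — two-channel track pairs sharing ≥ min_overlap frames at
  mean separation ≤ max_sep (default 0.3 µm); traveled distance and mean
  speed are measured on the mRNA channel over the overlap.

## Worked example

```python
import rnatraffic as rt
from rnatraffic.classification import classify_tracks, filter_by_duration
from rnatraffic.tracking import compute_metrics

params = rt.MotionParams(directed_fraction=0.05, directed_speed=2.6,
                         frame_interval=1/6.66, n_frames=100)
tracks, labels = rt.simulate_population(params, 400, seed=1)
kept = filter_by_duration(tracks, min_duration=2.5)
metrics = [compute_metrics(t) for t in kept]
classified = classify_tracks(metrics)
pct = rt.directed_fraction(classified)
print(f"{len(kept)} tracks pass the duration filter; "
      f"{pct:.1f}% classify long/directed (ground truth 5.0%)")

geometry = rt.make_cell_geometry(seed=1)
for pattern in ("uniform", "perinuclear", "peripheral"):
    pos = rt.sample_spot_positions(geometry, pattern, 10_000, seed=2)
    print(f"PDI {pattern:12s} {rt.compute_pdi(pos, geometry).pdi:.3f}")
```

prints

```
400 tracks pass the duration filter; 5.0% classify long/directed (ground truth 5.0%)
PDI uniform      1.002
PDI perinuclear  0.542
PDI peripheral   1.369
```

The classifier recovers the planted 5% directed population exactly, and
the PDI lands on its three anchor behaviours: ~1 for a uniform signal,
below 1 for perinuclear enrichment, above 1 for peripheral enrichment.

A command-line interface mirrors the library
(`rnatraffic simulate|detect|track|metrics|classify|derive-thresholds|pdi|clusters|cotransport|kymograph|run`);
`rnatraffic run --seed 0 --outdir out/` executes the full synthetic
pipeline and writes a manifest with SHA-256 hashes of every output.

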