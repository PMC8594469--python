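# Methods

## Motion model

Particles move in 2D in one of two modes. **Diffusive** tracks take i.i.d.
Gaussian steps with per-axis variance 2·D·Δt, so the ensemble MSD is 4Dτ.
The default D = 0.1 µm²/s is a typical cytoplasmic mobility for an
mRNA–protein particle of this size; it is a modelling choice, not a fitted
value. **Directed** tracks advance at constant speed v (default 2.6 µm/s,
the measured speed of motor-driven cotransport) along a heading that
performs a random walk with s.d. 0.1 rad/step. Run/pause kinetics are not
modelled: a directed track runs for its whole lifetime. This is the
simplest kinetics that reproduces the long/linear phenotype the classifier
targets; real motor trajectories pause and reverse, so classifier recall
on real data will be somewhat lower than on these simulations.

Localization noise (default 0.03 µm, roughly the centroid precision of a
well-sampled diffraction-limited spot) is added independently to every
observed position. It biases mean speed upward — a property the tests
assert rather than correct for, since the same bias affects real tracking.

A population mixes the two modes with `directed_fraction` (default 0.05,
the middle of the observed 3–6% range). Perturbations act only on this
mixture: `nocodazole` forces the directed count to zero (microtubule
depolymerization abolishes transport), while `cytochalasinD` and `dmso`
change nothing (actin disruption and vehicle leave it intact). Frame rates
default to 6.66 fps for single-color tracking and 7.36 fps for two-color
imaging, the two acquisition settings the analysis is calibrated for.

## Geometry and rendering

Cell outlines are low-order Fourier perturbations of a disc (smooth,
blob-like; `irregularity` scales the harmonics), with a circular nucleus
concentric at the image centre. Spot placement patterns: `uniform` over
cytoplasm pixels with sub-pixel jitter; `perinuclear` and `peripheral`
weight pixels by exp(−d/2 µm) of the distance from the nucleus boundary or
from the cell edge respectively (the 2 µm decay gives clearly non-uniform
but not degenerate patterns).

Rendering draws each emitter as an integrable 2D Gaussian whose total
integral equals its molecular intensity (single molecules ~N(1000, 100)
a.u.; a cluster of multiplicity m has mean m×1000 and s.d. 100·√m),
over a flat background with i.i.d. Gaussian read noise. Not modelled, and
therefore untested here: photobleaching, blinking, EMCCD gain noise, 3D
defocus, and autofluorescence texture. Passing detection tests show the
detector works at the stated SNR on clean PSFs, not that it is robust to
those artefacts.

## Detection

Frames are smoothed with a Gaussian of the PSF scale and passed through
the exact 5-point discrete Laplacian, negated and σ²-normalized — a LoG
that annihilates constant backgrounds identically. Local maxima above
threshold are kept with non-maximum suppression at `min_separation`
(plateau ties resolved to the lowest (row, column)), refined by 3×3
quadratic interpolation (clamped to ±0.5 px), and integrated in a disc of
3·σ with the median of a 1–2 radius annulus as local background (a 3σ disc
holds ~98.9% of a Gaussian's mass, hence the 5% tolerance on intensity
recovery). The default threshold, mean + 5·sd of the filtered image, is a
robust starting point for sparse fields; dense fields need an explicit
threshold. No numeric threshold is portable across cameras, so none is
hard-coded.

## Linking

Greedy global-nearest-neighbour: per frame transition, candidate pairs
within `max_link_dist` are sorted by ascending distance and assigned
greedily; tracks survive up to `max_gap` missing frames and closed gaps
are filled with linearly interpolated spots flagged `interpolated`
(excluded from intensity statistics, included in geometry metrics).
Deterministic and adequate for the sparse fields simulated here; it is not
a multi-hypothesis tracker and will switch identities in dense crossings.

## Metrics and classification

MSD uses overlapping time averages; at a track's maximal lag there is a
single window, so MSD equals the squared net displacement — which is why
every track passing the >4 µm displacement threshold necessarily has
full-lag MSD > 16 µm². VAC normalizes by the mean squared frame-to-frame
velocity so VAC(0) = 1; the unnormalized variant is available via
`normalized=False`. Ensemble curves average per-track curves with equal
weight per track.

Classification applies strict inequalities (displacement > 4 µm AND
linearity > 0.7) after the strict >2.5 s duration filter; boundary ties go
to short/diffuse. `min_frames` counts each frame as one exposure interval,
so 2.5 s at 6.66 fps needs 17 frames. `derive_thresholds` sets each
threshold at the (1−FPR) marginal quantile of a depolymerized-control
population; the joint 2D frontier is deliberately not estimated — marginal
quantiles are conservative (the joint pass rate is at most the marginal
one) and transparent. A zero-spread control falls back to the defaults
with a warning.

## PDI

PDI = (Σwᵢdᵢ²/Σwᵢ) / mean_cytoplasm(d²), distances from the **nucleus**
centroid, cytoplasm = cell ∖ nucleus. The second-moment ratio is adopted
as the normalization because it is the simplest statistic that is exactly
1 for a uniform cytoplasmic signal, below 1 for perinuclear and above 1
for peripheral enrichment, and it is invariant to rigid motions and
uniform dilation. Spot mode uses unit weights by default
(`intensity_weighted=True` switches to brightness weighting); raster mode
always weights by pixel intensity.

## Clusters

Integrated (not peak) intensity is the cluster-calling variable. The
strict cut can be fixed (e.g. a camera-specific value such as 4950 a.u.)
or calibrated as k× the single-molecule modal intensity, located as the
lowest prominent mode (>10% of the density maximum) of a Gaussian KDE;
k = 3 places the cut between a ~10%-CV single-molecule peak and a six-mer
tail. Multiplicity is intensity / reference, rounded, floored at 1.

## Cotransport and kymographs

Candidate pairs need ≥ `min_overlap` common frames at mean per-frame
distance ≤ `max_sep` (default 0.3 µm ≈ the diffraction limit, since two
co-transported molecules cannot be resolved apart); events are assigned
greedily by ascending mean distance, one event per track. Distance and
speed are measured on the mRNA channel over the overlap window; the two
channels are treated as simultaneous (sequential-excitation offsets at
7.36 fps displace a 2.6 µm/s particle by ~0.18 µm between channels, inside
the default `max_sep`). Kymographs resample each frame along the
discretized path at pixel steps, taking the maximum across the
perpendicular `line_width`.

## Problem sizes and determinism

Ensemble statistics in the tests use 500 tracks of 100 frames (Brownian
MSD/VAC), 200–400-track populations over 10 seeds for fraction recovery,
10⁴ spots for PDI anchors, and a 40-event cohort for the cotransport
summary — sizes at which the asserted tolerances (10% on MSD, |VAC| <
0.05, ±0.05 on PDI, ±1.5 points on the directed fraction) hold with
comfortable margin under the generator's defaults. Every stochastic
operation takes an explicit seed; the pipeline driver spawns per-stage
seeds from one global seed, and identical configs give byte-identical CSV
outputs.

## Known limitations

2D only (z-projection is the caller's responsibility); no photophysics in
the renderer; greedy linking and greedy pairing are not globally optimal;
`derive_thresholds` assumes the control population is purely diffusive;
PDI assumes a single connected cytoplasm and one nucleus per cell.
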