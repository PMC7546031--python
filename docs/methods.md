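# Methods

This note documents the models, algorithms and numerical choices behind
`isletmorph`, and what the synthetic-scene tests do and do not establish
about real microscope data.

## Image model and containers

All rasters are `VolumetricImage` objects: a 5-D array in fixed
`(t, c, z, y, x)` order with physical voxel spacing in μm. Confocal stacks
of larval zebrafish pancreas are strongly anisotropic — the default
spacing is (1.0, 0.3, 0.3) μm, z three times coarser than xy — and every
distance, area and volume downstream is computed in μm, never in voxel
units, precisely so that the anisotropy cannot be silently ignored. TIFF
I/O uses ImageJ conventions (xy pixel size in the resolution tags, z step
in the ImageJ `spacing` field).

## Synthetic scenes

The generator exists because the quantitative claims of this kind of
study rest on undeposited imaging data; it renders the features that
matter to the pipeline and records exact ground truth.

**Geometry.** Cell bodies are solid ellipsoids (semi-axes ~2.5–5 μm,
optional rotation), rasterized with an exact voxel-center inside test —
at soma scale the partial-volume error is negligible, and a sharp
boundary keeps the half-maximum surface on the analytic ellipsoid.
Filopodia are straight tapered frusta (default base/tip radius 0.45/0.25
μm) rooted on the body surface, rendered with 2×2×2 subvoxel
supersampling: a ~0.3 μm tube can fall entirely between voxel centers of
a 1 μm z grid, so thin structures *must* be anti-aliased to render at
all grid phases. Filopodia carry a proximal→distal intensity profile of
(2.0, 0.8) × body intensity: actin-targeted labels are enriched in
actin-bundled protrusions relative to cytoplasm, brightest proximally and
fading toward the tapering tip. This enrichment is also what makes
sub-half-micron protrusions segmentable at all after PSF blur — with
cytoplasm-level brightness they would vanish, contradicting the empirical
fact that filopodia are traceable in such data.

**Optics and noise.** Each frame is blurred with an anisotropic Gaussian
PSF (default σ = (0.7, 0.25, 0.25) μm, approximating a high-NA
water-immersion confocal), then background (0.05), Poisson shot noise
(200 photons per intensity unit) and Gaussian read noise (σ = 0.02) are
applied in that order — optics before shot before read. Whole-field
drift is a constant per-frame translation; cumulative drift, per-frame
cell centers and per-frame filopodium lengths are recorded in
`SceneTruth`. All randomness derives from the scene seed; identical
specs render bit-identical stacks.

**Scripted dynamics cohorts.** `make_dynamics_cohort` builds single-cell
11-frame movies (20 min at 2-min intervals) with 5 filopodia per cell on
six fixed directions ≥ 65° apart (crowded bases merge under the PSF and
would test the renderer, not the classifier). Stable filopodia hold a
constant 3.5–4.5 μm; dynamic ones undergo exactly one unambiguous
scripted event — appearance or disappearance of a 3.2–4.2 μm filopodium,
or a ~2.8-fold extension/retraction — at a mid-series frame. Filopodia
readily move several μm within one 2-min interval, so single-step events
are realistic; the magnitudes are chosen inside the automatic tracer's
validated operating range (reliable detection ≥ ~3 μm at the default
noise level) because the recovery tests are about the *event rules*, not
about the tracer's detection floor (a documented limitation, below).
Ground-truth labels are computed from the scripted lengths by the *same*
rule implementation the classifier uses, so recovery tests compare rule
application on measured versus true lengths.

## Preprocessing and drift correction

The cleanup chain mirrors standard confocal practice and is applied with
identical parameters to every frame and channel: 2-D median filter per
z-slice (radius 1 voxel by default; 2-D because speckle is in-plane and
the z step is coarse), rolling-ball background subtraction with the
radius given in μm and converted through the xy pixel size (default 10
μm), then linear rescaling with percentile clipping (default 0.1/99.9 —
the source workflow gives no numbers, so the limits are configuration
with logged defaults).

Drift is estimated per frame against frame 0 by 3-D phase correlation on
one reference channel, at integer-voxel resolution (the tooling this
replaces is translation-based; subvoxel refinement would imply a
resampling step the rest of the pipeline does not assume). The inverse
shift is applied to all channels with zero fill. Recovery is exact to
≤ 1 voxel per axis for drifts of several voxels per frame at default
noise.

## Segmentation

Hysteresis thresholding keeps voxels above the low threshold iff their
26-connected component contains a voxel above the high threshold;
background connectivity is the complementary 6. (The 26/6 pair is the
standard choice; the skimage built-in uses 6-connected flood fill, hence
the thin reimplementation.) Auto mode sets the high threshold by Otsu on
the analyzed volume and the low threshold to half of it; the values used
are recorded in the mask's provenance. Refinement fills internal
cavities, dilates by a voxel-isotropic ball and smooths by morphological
opening + closing (whether the original "3-D smoothing" was Gaussian or
morphological is unrecorded; opening+closing is used and flagged).
`purify` keeps the largest 26-connected component, breaking exact ties
deterministically toward the smallest flattened voxel index. Manual
slice-wise trimming of touching neighbours is replaced by serialized
exclusion masks so every measurement is re-derivable.

## Morphometry

- **Volume**: voxel count × voxel volume.
- **Surface area**: marching-cubes isosurface of the padded binary mask
  at level 0.5 in physical coordinates, then 4 iterations of Taubin
  smoothing (λ = 0.5, ν = −0.53). Raw voxel-face counting overestimates
  the area of a sphere by ~50 % and would cap sphericity near 0.62; raw
  binary marching cubes still overestimates by ~16 %; the
  volume-preserving Taubin pass brings a 10 μm digitized sphere to within
  ~1 % of 4πr², at the cost of a few-percent bias for cells under ~5 μm.
- **Sphericity**: Ψ = π^(1/3) (6V)^(2/3) / A, using the voxel-count
  volume and mesh area; 1 for a perfect sphere, up to ~1.02 permitted by
  mesh tolerance on digitized shapes ≥ 8 μm.
- **Feret diameter**: exact maximum pairwise distance over convex-hull
  vertices of the boundary voxels (the brute-force all-pairs computation
  is retained as a test oracle and agrees to machine precision).
- **Best-fit ellipsoid**: the inertia-equivalent ellipsoid from second
  central moments of the voxel positions, with the per-voxel box moment
  (spacing²/12) added; semi-axes aᵢ = √(5λᵢ). For convex digitized
  shapes V/Vₑ ≈ 1.
- Masks thinner than 2 voxels along any axis are rejected (no meaningful
  isosurface).

Group comparisons are two-tailed two-sample *t*-tests (pooled variance by
default; Welch behind a flag, with Welch–Satterthwaite df). Regressions
are per-group OLS with R²; a constant response is reported as slope 0,
R² 0 rather than NaN.

## Filopodium tracing and dynamics

A filopodium is any traced protrusion ≥ `min_length` (default 1.0 μm).

**Single-frame tracing** (`trace_filopodia`): the whole cell is segmented
with permissive hysteresis thresholds (low = 0.25 × Otsu); the soma is
recovered from that mask by morphological opening with a physical 2 μm
ball — wider than any blurred filopodium, narrower than the soma, and
leaving the soma's outer boundary intact so no halo shell survives the
subtraction — plus a one-voxel z dilation to re-absorb pole caps shaved
off by anisotropic erosion. One path per protrusion is then extracted by
*geodesic peeling* of the protrusion voxels: multi-source Dijkstra on the
26-neighbour voxel graph, seeded from the voxels adjacent to the soma
with per-source offsets equal to their distance to a tight
(high-threshold) soma surface, so geodesic depth means "length from the
soma surface" and the deepest route to a tip follows the shaft axis
rather than a blur-halo detour. The deepest voxel is a tip; its
backtraced path is recorded, voxels within 1.2 μm of the path are
consumed, and peeling repeats down to one voxel diagonal. Paths are
smoothed with a 7-point moving average (a single spurious one-voxel z
step in a raw voxel chain costs two ~1 μm diagonals and would wreck
lengths), extended proximally to the tight soma surface by a densely
sampled stem, and extended past the last voxel by the local protrusion
radius (the unresolved tip cap). Shadow ridges in a shaft's z halo are
removed by keeping the longest trace per base neighbourhood
(< 1.3 μm lateral, ≤ 2.5 μm in z — genuinely distinct filopodia root much
further apart). An earlier skeletonization-based tracer was abandoned:
3-D skeletons of noisy anisotropic tubes fragment, grow spurs, and
zigzag in z.

**Movie analysis** (`analyze_movie`): thresholds are derived once from
the whole preprocessed series and applied uniformly to every frame —
per-frame thresholds would let threshold jitter masquerade as dynamics.
Reference paths are traced on the temporal maximum-intensity volume,
where each filopodium appears at its fullest extension (the automatic
analogue of a human tracing the movie once and adjusting per frame).
Each frame then re-measures every reference path: local-maximum
intensities are sampled in a 1 μm neighbourhood around each path point
(tolerating ±1 voxel of wander), and the filopodium's length in that
frame is the arc length of the contiguous above-threshold run from the
base, tolerating up to two consecutive sub-threshold points. A
filopodium counts as present only when the run clearly clears the stem
buried in the soma's bright blur halo (stem + 0.3 μm). The per-track
length series is median-filtered over 3 frames — isolated single-frame
flickers at the presence boundary are measurement noise, while genuine
events are persistent steps and survive the median.

**Event rules** (shared by classifier and ground-truth labeller): per
frame relative to the previous frame, an event is an appearance, a
disappearance, or a length change of more than 50 %; a length transition
across `min_length` counts as appearance/disappearance, never
double-counted as a length change. A track is stable iff present at
every frame of the 20-min window and (max − min)/min ≤ 50 % over the
window. The change baseline for events is the previous analyzed frame
and for stability the series minimum — the source description fixes
neither, so both are configurable and logged.

**Linking** (`link_tracks`): greedy frame-to-frame matching by nearest
base point within a 2 μm gate, ties broken by the smaller length
difference; unmatched traces open new tracks. In `analyze_movie` linking
is implicit — one track per reference path.

## Tracking and clustering metrics

Cell identity across frames comes from per-cell masks (sparse mosaic
labeling makes identity unambiguous); centers are binary centroids in
μm. Trajectories can be normalized to a reference cell (which must be
present at every frame and becomes the origin); pairwise distances are
translation-invariant and unaffected. Distance series carry two trend
summaries — last-minus-first delta and Kendall τ versus time — because
plotted distance curves alone do not summarize approach. The clustering
metric is the convex-hull volume of all present centers (Qhull); fewer
than four points or degenerate configurations report volume 0 with an
explicit degeneracy flag.

## Counting

Cells are points in μm per channel, from annotation files or from
automated detection (Gaussian smoothing at ~1 μm then 3-D local maxima
with a physical minimum separation). A reference point is double-positive
iff a second-channel point lies within the match radius (default 3 μm,
about half a nuclear diameter). Points closer than half the match radius
are treated as duplicate annotations and merged with a warning; counting
is invariant to point order. The report builder bundles stage outputs
with provenance (version, seed, config, parameters) into deterministic
JSON; missing stages are flagged, not fatal.

## Known limitations

- The automatic tracer's reliable detection floor at default noise is
  ~3 μm of shaft beyond the soma's blur halo — above the 1 μm definition
  a human tracer can resolve interactively. Protrusions aligned near the
  optical axis are measured with a systematic negative bias of up to
  ~30 % (z-blur buries their proximal stems); the bias is consistent
  across frames, so relative (event) classification is far more robust
  than absolute lengths.
- Scenes contain straight filopodia only by default; curved or branched
  protrusions are a configuration extension, and branched protrusions
  would currently yield one path per peeled tip.
- The synthetic PSF is Gaussian and spatially invariant; no spectral
  bleed-through, no depth-dependent aberration, no duct/exocrine
  background tissue. Passing recovery tests therefore demonstrates
  correctness of the measurement logic under realistic noise/anisotropy,
  not robustness to every real-tissue artifact.
- Drift correction is integer-voxel and rigid; non-rigid deformation
  (e.g. gut peristalsis) is handled only by frame/slice exclusion.
- Problem sizes in the test suite are chosen for fast, deterministic
  runs: single-cell crops of roughly 30 × 30 × 26 μm, 10-cell cohorts,
  11-frame movies. The pipeline itself is O(voxels) per frame apart from
  the convex-hull and Dijkstra steps and scales to full stacks.
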