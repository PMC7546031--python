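# isletmorph

Quantitative 3-D morphometry and protrusion dynamics for sparse
(mosaically labeled) fluorescent cells in confocal stacks — developed for
time-lapse imaging of coalescing pancreatic islet cells in zebrafish
larvae, where single endocrine cells extend actin-rich filopodia, form
cell–cell contacts and cluster into secondary islets.

Mosaic labeling makes single cells separable in dense tissue, and this
package turns such stacks into numbers:

- **Preprocessing** — per-slice median filtering, rolling-ball background
  subtraction, percentile contrast normalization, and rigid drift
  correction of time-lapse series by 3-D phase correlation.
- **Segmentation** — 3-D hysteresis thresholding (voxels above a low
  threshold are kept iff 26-connected to a seed above a high threshold),
  hole filling, dilation/smoothing, and retention of the largest connected
  component; manual trimming is replaced by recorded exclusion masks.
- **Morphometry** — per-cell descriptors in physical units: volume
  `V` (voxel count × voxel volume), surface area `A` from a smoothed
  half-level isosurface mesh, sphericity `Ψ = π^(1/3) (6V)^(2/3) / A`
  (1 for a perfect sphere), Feret's diameter (maximum caliper — the
  largest distance between two surface points), and the volume of the
  inertia-equivalent ellipsoid with the complexity ratio `V / V_e`.
- **Filopodia** — automatic 3-D tracing of protrusions (≥ 1 μm) by
  geodesic path peeling, per-frame length measurement along fixed
  reference paths, track linking, and event classification: a *dynamic
  event* is counted when a filopodium appears, disappears, or changes
  length by more than 50 %; a *stable* filopodium is present at every
  timepoint of a 20-min window (2-min frames) and never varies by more
  than 50 %.
- **Tracking & clustering** — cell-center trajectories (optionally
  normalized to a reference cell), center-to-center distance series, and
  the convex-hull volume of all cell centers as a compaction metric.
- **Counting** — double-positive fractions from per-channel point
  annotations or automated 3-D peak detection.
- **Synthetic scenes** — a first-class generator of 3-D(+T) stacks of
  protrusive cells with anisotropic voxels, PSF blur, Poisson/Gaussian
  noise, whole-field drift and scripted filopodium dynamics, returning
  complete ground truth so every stage is testable without microscope data.

Two-group comparisons use two-sample *t*-tests (Student by default, Welch
behind a flag) and per-group ordinary least squares with R².

## Worked example

Render an 11-frame movie of one cell with a stable 4 μm filopodium and a
second filopodium that retracts from 9 μm to 3 μm at frame 5, then measure
the cell and classify the dynamics:

```python
import numpy as np
from isletmorph import VolumetricImage, hysteresis_segment, purify
from isletmorph.filopodia import analyze_movie
from isletmorph.morphometry import measure_cell
from isletmorph.synthetic import (CellSpec, FilopodiumSpec, NoiseSpec,
                                  SceneSpec, render_scene)

cell = CellSpec(center=(8.0, 15.0, 15.0), semi_axes=(3.0, 3.0, 3.0),
                filopodia=[FilopodiumSpec((0, 1, 0), [4.0] * 11),
                           FilopodiumSpec((0, -1, 0), [9.0] * 5 + [3.0] * 6)])
spec = SceneSpec(grid_shape=(16, 100, 100), cells=[cell],
                 noise=NoiseSpec(), n_frames=11, seed=7)
movie, truth = render_scene(spec)

frame0 = VolumetricImage.from_array(movie.volume(0), movie.voxel_spacing)
m = measure_cell(purify(hysteresis_segment(frame0)))
print(f"volume {m.volume:.1f} um^3  sphericity {m.sphericity:.3f}  "
      f"Feret {m.feret_diameter:.2f} um")

for tr in analyze_movie(movie):
    print(f"track {tr.track_id}: events={tr.dynamic_events} "
          f"stable={bool(tr.stable)} lengths={np.round(tr.length_series(11), 1)}")
```

Output:

```
volume 173.2 um^3  sphericity 0.833  Feret 18.00 um
track 0: events=1 stable=False lengths=[9.3 9.3 9.3 9.3 9.3 3.9 3.9 3.9 3.9 3.9 3.9]
track 1: events=0 stable=True lengths=[4.5 4.5 4.5 4.5 4.5 4.5 4.5 4.5 4.5 4.5 4.5]
```

The frame-0 mask includes both protrusions, so the Feret diameter spans
the two opposing filopodia (18 μm) while sphericity drops well below 1 for
this protrusive shape.  The retraction registers as exactly one dynamic
event (9.3 → 3.9 μm is a > 50 % change); the constant filopodium is
classified stable.  Both labels match the generator's ground truth.

A `isletmorph` command-line tool wraps the same operations
(`simulate`, `preprocess`, `register`, `segment`, `measure`, `stats`,
`filopodia`, `track`, `count`, `report`); see `isletmorph --help`.

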