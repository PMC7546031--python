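"""Cell-center trajectories, pairwise distances and clustering metrics.

Cell identity across frames comes from per-cell masks (mosaic labeling makes
cells sparse enough that identity is unambiguous), so no general multi-object
tracker is involved.  Trajectories can be expressed relative to a reference
cell, pairwise center-to-center distances summarize approach/retreat, and
the convex-hull volume of all centers quantifies cluster compaction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import kendalltau

from .segmentation import CellMask

__all__ = [
    "CellTrack",
    "DistanceSeries",
    "ClusterMetric",
    "extract_centers",
    "normalize_to_reference",
    "distance_series",
    "hull_volume",
]


@dataclass
class CellTrack:
    """One cell's per-frame binary-centroid position in μm (NaN where absent)."""

    cell_id: str | int
    centers: np.ndarray  # (n_frames, 3) μm
    present: np.ndarray  # (n_frames,) bool

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.present = np.asarray(self.present, dtype=bool)
        if self.centers.shape != (len(self.present), 3):
            raise ValueError("centers must be (n_frames, 3) matching the presence flags")


@dataclass
class DistanceSeries:
    """Center-to-center distance of one cell pair over their common frames."""

    pair: tuple
    frames: np.ndarray
    distances: np.ndarray  # μm

    @property
    def delta(self) -> float:
        """Last-minus-first distance (negative = approach)."""
        return float(self.distances[-1] - self.distances[0])

    @property
    def kendall_tau(self) -> float:
        """Kendall rank correlation of distance with time (trend direction)."""
        tau = kendalltau(self.frames, self.distances).statistic
        return float(tau) if np.isfinite(tau) else 0.0


@dataclass
class ClusterMetric:
    """Convex-hull volume of all present cell centers at one frame."""

    frame: int
    hull_volume: float  # μm³
    n_cells: int
    degenerate: bool = False


def extract_centers(masks_per_cell: dict) -> list[CellTrack]:
    """Binary centroids per cell per frame.

    ``masks_per_cell`` maps cell id to a per-frame list of
    :class:`CellMask` or ``None`` (absent).  An empty mask in a
    present-flagged frame is an error.
    """
    tracks = []
    for cell_id, frame_masks in masks_per_cell.items():
        n = len(frame_masks)
        centers = np.full((n, 3), np.nan)
        present = np.zeros(n, dtype=bool)
        for t, mask in enumerate(frame_masks):
            if mask is None:
                continue
            if not mask.data.any():
                raise ValueError(f"cell {cell_id!r}: empty mask in present frame {t}")
            coords = np.argwhere(mask.data)
            centers[t] = coords.mean(axis=0) * np.asarray(mask.voxel_spacing)
            present[t] = True
        tracks.append(CellTrack(cell_id=cell_id, centers=centers, present=present))
    return tracks


def normalize_to_reference(tracks: list[CellTrack], reference_id) -> list[CellTrack]:
    """Express every trajectory relative to one reference cell per frame.

    The reference must be present at every frame; it becomes the origin.
    Distances between cells are unaffected (pure per-frame translation).
    """
    ref = next((t for t in tracks if t.cell_id == reference_id), None)
    if ref is None:
        raise ValueError(f"no track with cell_id {reference_id!r}")
    if not ref.present.all():
        missing = np.flatnonzero(~ref.present).tolist()
        raise ValueError(f"reference cell {reference_id!r} absent at frames {missing}")
    return [
        CellTrack(
            cell_id=t.cell_id,
            centers=t.centers - ref.centers,
            present=t.present.copy(),
        )
        for t in tracks
    ]


def distance_series(tracks: list[CellTrack], pair: tuple) -> DistanceSeries:
    """Euclidean center-to-center distance per common frame (symmetric in pair)."""
    a_id, b_id = pair
    by_id = {t.cell_id: t for t in tracks}
    try:
        a, b = by_id[a_id], by_id[b_id]
    except KeyError as e:
        raise ValueError(f"unknown cell id {e.args[0]!r}") from None
    common = np.flatnonzero(a.present & b.present)
    if len(common) < 2:
        raise ValueError(f"pair {pair} shares fewer than 2 frames")
    d = np.linalg.norm(a.centers[common] - b.centers[common], axis=1)
    return DistanceSeries(pair=tuple(sorted(pair, key=str)), frames=common, distances=d)


def hull_volume(tracks: list[CellTrack], frame: int) -> ClusterMetric:
    """Convex-hull volume (μm³) of all centers present at ``frame``.

    Fewer than 4 points, or coplanar/collinear centers, give volume 0 with
    the degeneracy flag set.
    """
    pts = np.array([t.centers[frame] for t in tracks if t.present[frame]])
    if len(pts) == 0:
        raise ValueError(f"no cell present at frame {frame}")
    if len(pts) < 4:
        return ClusterMetric(frame=frame, hull_volume=0.0, n_cells=len(pts), degenerate=True)
    try:
        hull = ConvexHull(pts)
    except QhullError:
        return ClusterMetric(frame=frame, hull_volume=0.0, n_cells=len(pts), degenerate=True)
    return ClusterMetric(frame=frame, hull_volume=float(hull.volume), n_cells=len(pts))
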