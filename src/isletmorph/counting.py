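"""Point-based cell counting across channels, and run-report assembly.

Counting reproduces the point-annotation workflow used for labeling-
efficiency analyses: every cell is a point in μm per channel (annotated by
hand or detected automatically as local intensity maxima), and a
reference-channel cell is double-positive when a second-channel point lies
within a match radius (default 3 μm, about half a nuclear diameter).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .image import VolumetricImage

__all__ = ["CountRecord", "count_cells", "detect_points", "build_report"]


@dataclass
class CountRecord:
    """Double-positive counting result for one sample."""

    sample_id: str
    n_reference_positive: int
    n_double_positive: int
    source: str = "annotation"

    def __post_init__(self) -> None:
        if not 0 <= self.n_double_positive <= self.n_reference_positive:
            raise ValueError("need 0 <= double-positive <= reference count")

    @property
    def fraction(self) -> float:
        if self.n_reference_positive == 0:
            return 0.0
        return self.n_double_positive / self.n_reference_positive

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "n_reference_positive": self.n_reference_positive,
            "n_double_positive": self.n_double_positive,
            "fraction": self.fraction,
            "source": self.source,
        }


def _merge_close(points: np.ndarray, radius: float) -> np.ndarray:
    """Merge points closer than ``radius`` (duplicate annotations), with a warning."""
    if len(points) == 0:
        return points
    order = np.lexsort(points.T[::-1])  # deterministic regardless of input order
    points = points[order]
    tree = cKDTree(points)
    pairs = tree.query_pairs(radius)
    if not pairs:
        return points
    warnings.warn(f"merging {len(pairs)} point pair(s) closer than {radius:.2f} μm")
    parent = list(range(len(points)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in sorted(pairs):
        parent[find(j)] = find(i)
    groups = {}
    for i in range(len(points)):
        groups.setdefault(find(i), []).append(i)
    return np.array([points[idx].mean(axis=0) for idx in sorted(groups.values())])


def count_cells(
    points_reference,
    points_second,
    match_radius: float = 3.0,
    sample_id: str = "",
    source: str = "annotation",
) -> CountRecord:
    """Count double-positive cells from per-channel point lists (μm).

    A reference point is double-positive iff a second-channel point lies
    within ``match_radius``.  Points within half the match radius of each
    other are treated as duplicate annotations and merged (warned).  Results
    are invariant to point-list order.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be > 0")
    ref = np.asarray(points_reference, dtype=float).reshape(-1, 3)
    sec = np.asarray(points_second, dtype=float).reshape(-1, 3)
    ref = _merge_close(ref, match_radius / 2)
    sec = _merge_close(sec, match_radius / 2)
    if len(ref) == 0:
        return CountRecord(sample_id, 0, 0, source=source)
    if len(sec) == 0:
        n_double = 0
    else:
        d, _ = cKDTree(sec).query(ref)
        n_double = int((d <= match_radius).sum())
    return CountRecord(sample_id, int(len(ref)), n_double, source=source)


def detect_points(
    img: VolumetricImage,
    t: int = 0,
    c: int = 0,
    min_distance_um: float = 3.0,
    threshold_rel: float = 0.3,
) -> np.ndarray:
    """Automated cell-point detection: smoothed local intensity maxima (μm)."""
    vol = img.volume(t, c).astype(np.float64)
    spacing = np.asarray(img.voxel_spacing)
    vol = ndi.gaussian_filter(vol, sigma=1.0 / spacing)  # ~1 μm isotropic smoothing
    min_dist_vox = np.maximum(1, np.round(min_distance_um / spacing)).astype(int)
    footprint = np.ones(2 * min_dist_vox + 1, dtype=bool)
    peaks = peak_local_max(vol, footprint=footprint, threshold_rel=threshold_rel)
    return peaks * spacing


def build_report(
    stages: dict,
    config: dict | None = None,
    seed: int | None = None,
    parameters: dict | None = None,
    expected_stages=("synthetic", "preprocess", "segmentation", "morphometry", "filopodia", "tracking", "counting"),
) -> dict:
    """Assemble module outputs into a single provenance-carrying report.

    ``stages`` maps stage name to a JSON-serializable payload (or a list of
    :class:`CountRecord` / dataclass dicts).  Missing stages are flagged as
    absent rather than failing; conflicting sample ids inside the counting
    stage are an error.  The body contains no timestamps, so identical
    inputs produce byte-identical reports.
    """
    if not stages:
        raise ValueError("at least one module output is required")
    from . import __version__

    body = {
        "provenance": {
            "software": "isletmorph",
            "version": __version__,
            "seed": seed,
            "config": config or {},
            "parameters": parameters or {},
        },
        "stages": {},
    }
    for name in expected_stages:
        payload = stages.get(name)
        if payload is None:
            body["stages"][name] = {"present": False}
            continue
        if name == "counting" and isinstance(payload, (list, tuple)):
            records = [p.as_dict() if isinstance(p, CountRecord) else dict(p) for p in payload]
            ids = [r["sample_id"] for r in records]
            if len(ids) != len(set(ids)):
                raise ValueError(f"conflicting sample ids in counting stage: {ids}")
            payload = records
        body["stages"][name] = {"present": True, "data": payload}
    for name in stages:
        if name not in expected_stages:
            body["stages"][name] = {"present": True, "data": stages[name]}
    return body


def report_to_json(report: dict) -> str:
    """Deterministic JSON serialization of a report bundle."""
    return json.dumps(report, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating, np.bool_)):
        return obj.item()
    if hasattr(obj, "as_dict"):
        return obj.as_dict()
    if hasattr(obj, "to_json_dict"):
        return obj.to_json_dict()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
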