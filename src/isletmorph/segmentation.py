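"""Single-cell 3-D segmentation.

The pipeline mirrors the classic interactive workflow for sparse fluorescent
cells: hysteresis thresholding (seeds above a high threshold grow into the
low-threshold region), hole filling, dilation + morphological smoothing, and
retention of the largest connected component ("purify").  Manual trimming of
touching neighbours is replaced by reproducible exclusion masks.

Foreground connectivity is 26 (full 3-D neighbourhood); background is the
complementary 6-connectivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import ball

from .image import VolumetricImage

__all__ = [
    "CellMask",
    "EmptyMaskError",
    "hysteresis_segment",
    "refine_mask",
    "purify",
    "apply_exclusion",
    "ball_um",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


class EmptyMaskError(ValueError):
    """Raised when a segmentation step would produce an empty mask."""


@dataclass
class CellMask:
    """Binary 3-D mask of one cell, aligned to its source image grid."""

    data: np.ndarray
    voxel_spacing: tuple[float, float, float]
    label: int = 1
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("CellMask data must be 3-D (z, y, x)")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def copy_with(self, data: np.ndarray, **extra_provenance) -> "CellMask":
        return CellMask(
            data,
            self.voxel_spacing,
            label=self.label,
            provenance={**self.provenance, **extra_provenance},
        )


def ball_um(radius_um: float, spacing: tuple[float, float, float]) -> np.ndarray:
    """Ellipsoidal structuring element of physical radius ``radius_um``.

    With anisotropic voxels an isotropic-in-voxels ball is anisotropic in μm;
    this footprint keeps morphology spacing-invariant.
    """
    half = [max(1, int(np.floor(radius_um / s))) for s in spacing]
    grids = np.meshgrid(
        *[np.arange(-h, h + 1) * s for h, s in zip(half, spacing)], indexing="ij"
    )
    return sum(g**2 for g in grids) <= radius_um**2 + 1e-9


def _resolve_volume(img, t: int, c: int, spacing):
    if isinstance(img, VolumetricImage):
        return img.volume(t, c), img.voxel_spacing
    vol = np.asarray(img)
    if vol.ndim != 3:
        raise ValueError("expected a 3-D volume or a VolumetricImage")
    if spacing is None:
        raise ValueError("voxel spacing required when passing a bare array")
    return vol, tuple(float(s) for s in spacing)


def hysteresis_segment(
    img,
    low: float | str = "auto",
    high: float | str = "auto",
    *,
    t: int = 0,
    c: int = 0,
    spacing: tuple[float, float, float] | None = None,
    low_fraction: float = 0.5,
    label: int = 1,
) -> CellMask:
    """Hysteresis threshold: keep low-threshold voxels 26-connected to a seed.

    Voxels ``>= high`` are seeds; voxels ``>= low`` survive iff their
    26-connected component contains a seed.  ``"auto"`` sets ``high`` to the
    Otsu threshold of the volume and ``low = low_fraction * high``; the values
    actually used are recorded in the mask provenance.

    Raises
    ------
    EmptyMaskError
        If no voxel reaches ``high``.
    """
    vol, spacing = _resolve_volume(img, t, c, spacing)
    vol = np.asarray(vol, dtype=np.float64)
    if high == "auto":
        high_val = float(threshold_otsu(vol))
    else:
        high_val = float(high)
    low_val = low_fraction * high_val if low == "auto" else float(low)
    if not (0 <= low_val <= high_val):
        raise ValueError(f"need 0 <= low <= high, got low={low_val}, high={high_val}")

    seeds = vol >= high_val
    if not seeds.any():
        raise EmptyMaskError(f"no voxel reaches the high threshold {high_val}")
    labels, _ = ndi.label(vol >= low_val, structure=_CONN26)
    keep = np.unique(labels[seeds])
    mask = np.isin(labels, keep[keep > 0])
    return CellMask(
        mask,
        spacing,
        label=label,
        provenance={"low": low_val, "high": high_val, "auto": high == "auto"},
    )


def refine_mask(mask: CellMask, dilate_radius: int = 1, smooth_radius: int = 1) -> CellMask:
    """Fill holes, dilate, then smooth (morphological opening + closing).

    Radii are in voxels (isotropic-in-voxels balls, matching the source
    plugins); radius 0 disables a step, so ``refine_mask(m, 0, 0)`` is hole
    filling alone.
    """
    if dilate_radius < 0 or smooth_radius < 0:
        raise ValueError("radii must be >= 0")
    out = ndi.binary_fill_holes(mask.data)
    if dilate_radius > 0:
        out = ndi.binary_dilation(out, structure=ball(dilate_radius))
    if smooth_radius > 0:
        se = ball(smooth_radius)
        out = ndi.binary_opening(out, structure=se)
        out = ndi.binary_closing(out, structure=se)
    return mask.copy_with(out, dilate_radius=dilate_radius, smooth_radius=smooth_radius)


def purify(mask: CellMask) -> CellMask:
    """Keep only the largest 26-connected component.

    Ties are broken deterministically in favour of the component containing
    the smallest linear (flattened) voxel index; the choice is recorded in
    provenance.
    """
    labels, n = ndi.label(mask.data, structure=_CONN26)
    if n == 0:
        raise EmptyMaskError("cannot purify an empty mask")
    if n == 1:
        return mask.copy_with(mask.data, purified=True)
    sizes = np.bincount(labels.ravel())[1:]
    biggest = sizes.max()
    candidates = np.flatnonzero(sizes == biggest) + 1
    if len(candidates) == 1:
        winner = candidates[0]
        tie = False
    else:
        flat = labels.ravel()
        first_idx = {
            lab: int(np.argmax(flat == lab)) for lab in candidates
        }
        winner = min(candidates, key=lambda lab: first_idx[lab])
        tie = True
    return mask.copy_with(labels == winner, purified=True, purify_tie_break=tie)


def apply_exclusion(mask: CellMask, exclusion: np.ndarray) -> CellMask:
    """Remove voxels under a recorded exclusion mask, then re-purify.

    This is the reproducible replacement for slice-by-slice manual trimming
    of signal from adjacent cells: the exclusion raster is serialized so the
    measurement can be re-derived.
    """
    exclusion = np.asarray(exclusion, dtype=bool)
    if exclusion.shape != mask.data.shape:
        raise ValueError(
            f"exclusion shape {exclusion.shape} != mask shape {mask.data.shape}"
        )
    out = mask.data & ~exclusion
    if not out.any():
        raise EmptyMaskError("exclusion mask removed every foreground voxel")
    return purify(mask.copy_with(out, exclusion_applied=True))
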