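"""Preprocessing chain and rigid drift correction for time-lapse stacks.

The chain mirrors the standard confocal cleanup applied uniformly to every
frame and channel before quantification: 2-D median filter per z-slice to
suppress speckle, rolling-ball background subtraction, percentile-clipped
contrast rescaling.  Drift over a time-lapse series is estimated as an
integer-voxel translation per frame by 3-D phase correlation against frame 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk
from skimage.registration import phase_cross_correlation
from skimage.restoration import rolling_ball

from .image import VolumetricImage

__all__ = ["DriftModel", "preprocess", "correct_drift", "exclude_frames"]


@dataclass
class DriftModel:
    """Per-frame integer voxel translation (z, y, x) relative to frame 0."""

    translations: np.ndarray  # (n_frames, 3) int

    def __post_init__(self) -> None:
        self.translations = np.asarray(self.translations, dtype=int)
        if self.translations.ndim != 2 or self.translations.shape[1] != 3:
            raise ValueError("translations must be (n_frames, 3)")
        if self.translations[0].any():
            raise ValueError("frame 0 translation must be (0, 0, 0)")

    def to_json_dict(self) -> dict:
        return {"translations_voxels": self.translations.tolist()}


def preprocess(
    img: VolumetricImage,
    median_radius: int = 1,
    bg_radius: float = 10.0,
    clip_percentiles: tuple[float, float] = (0.1, 99.9),
) -> VolumetricImage:
    """Median filter, background subtraction and contrast normalization.

    Parameters
    ----------
    median_radius
        Disk radius in voxels of the per-z-slice 2-D median filter (0
        disables).  Filtering is 2-D per slice, matching the source tooling.
    bg_radius
        Rolling-ball radius in μm, converted via the xy spacing so the
        result is spacing-invariant (0 disables).
    clip_percentiles
        Lower/upper percentiles over the whole series; intensities are
        clipped there and rescaled linearly to [0, 1].  Must be strictly
        increasing within [0, 100].

    The same parameters are applied uniformly to every frame and channel.
    """
    lo_p, hi_p = clip_percentiles
    if not (0 <= lo_p < hi_p <= 100):
        raise ValueError(f"clip_percentiles must be strictly increasing in [0, 100], got {clip_percentiles}")
    if median_radius < 0 or bg_radius < 0:
        raise ValueError("radii must be >= 0")

    data = img.data.astype(np.float64, copy=True)
    dy = img.voxel_spacing[1]
    bg_px = bg_radius / dy
    footprint = disk(median_radius) if median_radius > 0 else None

    for t in range(data.shape[0]):
        for c in range(data.shape[1]):
            for z in range(data.shape[2]):
                sl = data[t, c, z]
                if footprint is not None:
                    sl = ndi.median_filter(sl, footprint=footprint, mode="nearest")
                if bg_px > 0:
                    sl = sl - rolling_ball(sl, radius=bg_px)
                data[t, c, z] = sl

    lo, hi = np.percentile(data, [lo_p, hi_p])
    if hi > lo:
        data = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    return img.copy_with(data)


def correct_drift(
    series: VolumetricImage, reference_channel: int = 0
) -> tuple[VolumetricImage, DriftModel]:
    """Estimate and remove per-frame rigid drift by 3-D phase correlation.

    The translation of each frame relative to frame 0 is estimated on
    ``reference_channel`` at integer-voxel resolution and the inverse shift
    is applied to every channel (out-of-frame voxels zero-filled).

    Raises
    ------
    ValueError
        On fewer than 2 frames, or if any reference-channel frame is all
        zeros (phase correlation undefined).
    """
    if series.n_frames < 2:
        raise ValueError("drift correction needs at least 2 frames")
    ref = series.volume(0, reference_channel).astype(np.float64)
    if not np.any(ref):
        raise ValueError("frame 0 of the reference channel is all zeros; correlation undefined")

    translations = np.zeros((series.n_frames, 3), dtype=int)
    corrected = series.data.astype(np.float64, copy=True)
    for t in range(1, series.n_frames):
        mov = series.volume(t, reference_channel).astype(np.float64)
        if not np.any(mov):
            raise ValueError(f"frame {t} of the reference channel is all zeros; correlation undefined")
        shift, _, _ = phase_cross_correlation(ref, mov, upsample_factor=1, normalization=None)
        shift = np.round(shift).astype(int)
        translations[t] = -shift  # translation of the frame content relative to frame 0
        for c in range(series.n_channels):
            corrected[t, c] = ndi.shift(
                series.data[t, c].astype(np.float64), shift, order=0, cval=0.0
            )
    return series.copy_with(corrected), DriftModel(translations)


def exclude_frames(series: VolumetricImage, indices, axis: str = "t") -> VolumetricImage:
    """Drop listed timepoints (``axis="t"``) or z-slices (``axis="z"``).

    Indices must be unique and in range, and at least one frame/slice must
    remain; order of the survivors is preserved.
    """
    axis_num = {"t": 0, "z": 2}.get(axis)
    if axis_num is None:
        raise ValueError("axis must be 't' or 'z'")
    indices = list(indices)
    n = series.data.shape[axis_num]
    if len(indices) != len(set(indices)):
        raise ValueError("duplicate exclusion indices")
    if any(i < 0 or i >= n for i in indices):
        raise ValueError(f"exclusion index out of range for axis {axis!r} of size {n}")
    if len(indices) >= n:
        raise ValueError("cannot exclude every frame/slice")
    return series.copy_with(np.delete(series.data, indices, axis=axis_num))
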