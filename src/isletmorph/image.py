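"""Volumetric image container and TIFF input/output.

All rasters in this package travel as :class:`VolumetricImage`: a 5-D array
in fixed ``(t, c, z, y, x)`` axis order with physical voxel spacing in
micrometres.  Confocal stacks are anisotropic (z step typically larger than
the xy pixel size), so every downstream distance, area and volume
computation must go through ``voxel_spacing`` rather than voxel counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["VolumetricImage", "read_stack", "write_stack", "MissingSpacingError"]

_AXES = "tczyx"


class MissingSpacingError(ValueError):
    """Raised when a TIFF carries no voxel-spacing metadata and no override is given."""


@dataclass
class VolumetricImage:
    """Intensity stack with physical voxel spacing.

    Parameters
    ----------
    data
        5-D array ``(t, c, z, y, x)``; singleton time/channel axes are fine.
    voxel_spacing
        Micrometres per voxel along ``(z, y, x)``.
    """

    data: np.ndarray
    voxel_spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(
                f"expected 5-D (t, c, z, y, x) data, got {self.data.ndim}-D; "
                "use VolumetricImage.from_array to promote lower-dimensional arrays"
            )
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be 3 positive values, got {self.voxel_spacing}")

    @classmethod
    def from_array(
        cls,
        data: np.ndarray,
        voxel_spacing: tuple[float, float, float],
        axes: str | None = None,
    ) -> "VolumetricImage":
        """Promote a 3/4/5-D array to the canonical ``(t, c, z, y, x)`` layout.

        ``axes`` names the incoming axes (a substring of ``"tczyx"`` ending in
        ``"zyx"``, e.g. ``"tzyx"``).  When omitted it is inferred from
        dimensionality: 3-D -> ``zyx``, 4-D -> ``tzyx``, 5-D -> ``tczyx``.
        """
        data = np.asarray(data)
        if axes is None:
            axes = {3: "zyx", 4: "tzyx", 5: "tczyx"}.get(data.ndim)
            if axes is None:
                raise ValueError(f"cannot infer axes for {data.ndim}-D data")
        axes = axes.lower()
        if data.ndim != len(axes) or not axes.endswith("zyx"):
            raise ValueError(f"axes {axes!r} do not match {data.ndim}-D data ending in zyx")
        if sorted(axes) != sorted(set(axes)) or any(a not in _AXES for a in axes):
            raise ValueError(f"axes {axes!r} must be unique characters from {_AXES!r}")
        # insert singleton axes for whatever is missing, then order as tczyx
        for a in _AXES:
            if a not in axes:
                data = data[np.newaxis]
                axes = a + axes
        data = np.moveaxis(data, [axes.index(a) for a in _AXES], range(5))
        return cls(data, voxel_spacing)

    # -- convenience accessors -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[2:]

    def volume(self, t: int = 0, c: int = 0) -> np.ndarray:
        """The 3-D ``(z, y, x)`` raster at one timepoint/channel."""
        return self.data[t, c]

    def copy_with(self, data: np.ndarray) -> "VolumetricImage":
        return VolumetricImage(data, self.voxel_spacing)


def write_stack(img: VolumetricImage, path) -> None:
    """Write an ImageJ-compatible hyperstack TIFF with spacing metadata.

    Spacing is stored the way ImageJ expects it: xy pixel size in the TIFF
    resolution tags, z step in the ImageJ ``spacing`` field (unit: micron).
    """
    data = img.data
    if data.dtype not in (np.uint8, np.uint16, np.float32):
        data = data.astype(np.float32)
    dz, dy, dx = img.voxel_spacing
    # ImageJ hyperstack axis order is TZCYX
    tifffile.imwrite(
        path,
        np.moveaxis(data, 1, 2),
        imagej=True,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "TZCYX"},
    )


def _resolution_to_um(tag_value) -> float | None:
    if tag_value is None:
        return None
    num, den = tag_value
    if num == 0:
        return None
    return den / num


def read_stack(path, spacing_override: tuple[float, float, float] | None = None) -> VolumetricImage:
    """Read a TIFF stack into canonical ``(t, c, z, y, x)`` layout.

    Voxel spacing is taken from ImageJ/resolution metadata; if absent,
    ``spacing_override`` (z, y, x in μm) must be supplied or
    :class:`MissingSpacingError` is raised.
    """
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.lower().replace("s", "c").replace("q", "t")
        page = tf.pages[0]

        dz = dy = dx = None
        ij = tf.imagej_metadata or {}
        if "spacing" in ij:
            dz = float(ij["spacing"])
        xres = page.tags.get("XResolution")
        yres = page.tags.get("YResolution")
        if xres is not None:
            dx = _resolution_to_um(xres.value)
        if yres is not None:
            dy = _resolution_to_um(yres.value)

    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    elif dz is not None and dy is not None and dx is not None:
        spacing = (dz, dy, dx)
    else:
        raise MissingSpacingError(
            f"{path}: no complete voxel-spacing metadata (z={dz}, y={dy}, x={dx}); "
            "pass spacing_override=(z, y, x) in μm"
        )
    if data.ndim == 2:  # single plane
        data = data[np.newaxis]
        axes = "z" + axes[-2:]
    try:
        return VolumetricImage.from_array(data, spacing, axes=axes)
    except ValueError:
        # unusual photometric interpretations yield axes like 'CYX' or 'SYX';
        # fall back to dimensionality-based inference
        return VolumetricImage.from_array(data, spacing)
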