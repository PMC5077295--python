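"""Image container with physical voxel sizes, plus TIFF I/O.

Axis order is fixed as (t, z, y, x), with lower-dimensional data using the
trailing axes (z, y, x), (y, x).  Coordinates are 0-based with the
voxel-centre convention: the physical position of pixel index ``i`` along an
axis is ``i * step`` µm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """An intensity array with physical pixel sizes (µm)."""

    data: np.ndarray
    pixel_size: float = 0.08
    z_step: float = 0.2

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def frame(self, t: int) -> "ImageStack":
        """Extract one time point from a 4D (t, z, y, x) stack."""
        if self.ndim != 4:
            raise ValueError("frame() requires a 4D (t,z,y,x) stack")
        return ImageStack(self.data[t], self.pixel_size, self.z_step)

    def save(self, path) -> None:
        """Write a multi-page TIFF with resolution metadata (µm units)."""
        tifffile.imwrite(
            path,
            np.asarray(self.data, dtype=np.float32),
            photometric="minisblack",
            resolution=(1.0 / self.pixel_size, 1.0 / self.pixel_size),
            metadata={
                "axes": "TZYX"[4 - self.ndim :],
                "unit": "um",
                "spacing": self.z_step,
                "PixelSizeUm": self.pixel_size,
            },
            imagej=False,
        )

    @classmethod
    def load(cls, path, pixel_size: float | None = None,
             z_step: float | None = None) -> "ImageStack":
        """Read a TIFF; pixel sizes from metadata unless overridden."""
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            px, zs = None, None
            try:
                meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
                px = meta.get("PixelSizeUm")
                zs = meta.get("spacing")
            except (AttributeError, IndexError, TypeError):
                pass
        if pixel_size is None:
            pixel_size = px if px else 0.08
        if z_step is None:
            z_step = zs if zs else 0.2
        return cls(data, float(pixel_size), float(z_step))
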