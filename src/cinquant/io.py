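"""Calibrated image container and file round-tripping.

Single-channel 16-bit fields are exchanged as TIFF with an ImageJ-style
spatial calibration (``unit=um``); record tables as CSV with a fixed column
order. An image without a resolvable pixel size is rejected by the analysis
operators, so the calibration is written and read explicitly here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass
class FieldImage:
    """A single-channel 16-bit microscopy field with physical calibration.

    Attributes
    ----------
    pixels : ndarray of uint16, shape (H, W)
        Raw intensities in arbitrary units on the 16-bit scale.
    pixel_size : float
        Lateral calibration in micrometres per pixel.
    """

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("FieldImage expects a single-channel 2-D array")
        if self.pixels.dtype != np.uint16:
            if np.issubdtype(self.pixels.dtype, np.integer) or np.issubdtype(
                self.pixels.dtype, np.floating
            ):
                self.pixels = np.clip(np.rint(self.pixels), 0, 65535).astype(np.uint16)
            else:
                raise ValueError("pixels must be numeric")
        if not (self.pixel_size and self.pixel_size > 0):
            raise ValueError("pixel_size must be a positive number (um/pixel)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def extent_um(self) -> tuple[float, float]:
        """(height, width) of the pixel-index grid in micrometres.

        Coordinates are 0-based pixel indices times ``pixel_size``; the last
        index along each axis defines the far edge used for border distances.
        """
        h, w = self.pixels.shape
        return ((h - 1) * self.pixel_size, (w - 1) * self.pixel_size)


def write_field_tiff(image: FieldImage, path: str | Path) -> Path:
    """Write a calibrated field as a 16-bit ImageJ TIFF (unit = um)."""
    path = Path(path)
    res = 1.0 / image.pixel_size  # pixels per micrometre
    tifffile.imwrite(
        path,
        image.pixels,
        imagej=True,
        resolution=(res, res),
        metadata={"unit": "um"},
    )
    return path


def read_field_tiff(path: str | Path) -> FieldImage:
    """Read a calibrated 16-bit TIFF; raises if no um calibration is stored."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        pixels = page.asarray()
        meta = tif.imagej_metadata or {}
        unit = meta.get("unit")
        xres = page.tags.get("XResolution")
        if unit != "um" or xres is None:
            raise ValueError(
                f"{path.name}: missing micrometre calibration (ImageJ unit/XResolution)"
            )
        num, den = xres.value
        if num == 0:
            raise ValueError(f"{path.name}: zero XResolution")
        pixel_size = den / num
    return FieldImage(pixels=pixels, pixel_size=float(pixel_size))
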