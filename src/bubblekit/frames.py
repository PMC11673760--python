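"""Greyscale image container shared by every pipeline stage.

An :class:`ImageFrame` is a 2-D array of non-negative intensities together
with its bit depth (8 or 16) and, once calibrated, the physical size of a
pixel in micrometres.  All optical and acoustic operations consume and
produce this type so that spatial calibration travels with the pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

_DTYPES = {8: np.uint8, 16: np.uint16}


@dataclass
class ImageFrame:
    """A single greyscale frame.

    Parameters
    ----------
    pixels
        2-D array of intensities.  Stored as ``uint8`` or ``uint16``
        according to ``bit_depth``.
    bit_depth
        8 or 16.
    pixel_size_um
        Physical width of one pixel in micrometres, or ``None`` when the
        frame is not yet spatially calibrated.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size_um: Optional[float] = None

    def __post_init__(self) -> None:
        if self.bit_depth not in _DTYPES:
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {arr.shape}")
        limit = 2**self.bit_depth - 1
        if arr.dtype != _DTYPES[self.bit_depth]:
            if np.any(arr < 0) or np.any(arr > limit):
                raise ValueError(
                    f"pixel values outside [0, {limit}] for {self.bit_depth}-bit frame"
                )
            arr = arr.astype(_DTYPES[self.bit_depth])
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        self.pixels = arr

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def max_value(self) -> int:
        """Largest representable intensity for this bit depth."""
        return 2**self.bit_depth - 1

    def with_pixels(self, pixels: np.ndarray, bit_depth: Optional[int] = None) -> "ImageFrame":
        """Copy of this frame with new pixel data, preserving calibration."""
        return replace(
            self,
            pixels=pixels,
            bit_depth=self.bit_depth if bit_depth is None else bit_depth,
        )

    def calibrated(self, pixel_size_um: float) -> "ImageFrame":
        """Copy of this frame with a spatial calibration attached."""
        return replace(self, pixel_size_um=pixel_size_um)
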