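"""Canonical in-memory image container.

All pipeline stages operate on a 2-D float64 raster scaled to [0, 1].
Loading from 8/16-bit integer files and RGB→luma conversion happen once, in
:mod:`sma.io_calib`; everything downstream is grayscale float.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .errors import ValidationError


@dataclass
class UltrasoundImage:
    """A grayscale B-mode scan plus optional mm-per-pixel calibration.

    Parameters
    ----------
    pixels:
        2-D float array in [0, 1]; row 0 is the top (shallow) edge,
        column 0 the left (proximal) edge.
    mm_per_px:
        Physical calibration, or ``None`` for pixel-only output.
    source:
        Origin of the raster (file path or a synthetic tag), for reporting.
    """

    pixels: np.ndarray
    mm_per_px: Optional[float] = None
    source: str = field(default="<array>")

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValidationError(
                f"expected a 2-D grayscale raster, got shape {arr.shape}"
            )
        if arr.size == 0:
            raise ValidationError("empty image")
        if self.mm_per_px is not None and not self.mm_per_px > 0:
            raise ValidationError("mm_per_px must be > 0")
        self.pixels = arr

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def copy(self) -> "UltrasoundImage":
        return replace(self, pixels=self.pixels.copy())

    def flipped(self) -> "UltrasoundImage":
        """Horizontally mirrored copy (proximal side swapped left/right)."""
        return replace(self, pixels=np.ascontiguousarray(self.pixels[:, ::-1]))
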