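"""Detection and cropping of the ultrasound field of view.

Scanner exports almost always embed the echo image in a dark information
frame (patient data, settings, a scale bar).  This stage suppresses the
frame text with a smoothing convolution and a median filter, binarizes the
image against a local-median threshold, and takes the bounding rectangle of
the largest bright connected component as the field of view.  The input
raster is never modified; all work happens on a duplicate.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters.rank import median as rank_median
from skimage.util import img_as_ubyte

from .config import AnalysisConfig
from .errors import FovNotFound, ValidationError
from .image import UltrasoundImage

__all__ = ["FovRect", "detect_fov", "crop"]


@dataclass(frozen=True)
class FovRect:
    """Half-open pixel rectangle, 0-based, top-left origin."""

    x: int
    y: int
    w: int
    h: int

    def validate_within(self, width: int, height: int) -> "FovRect":
        if self.w <= 0 or self.h <= 0:
            raise ValidationError(f"rectangle extents must be positive: {self}")
        if self.x < 0 or self.y < 0 or self.x + self.w > width or self.y + self.h > height:
            raise ValidationError(
                f"rectangle {self} exceeds image bounds {width}x{height}"
            )
        return self

    def as_tuple(self) -> tuple:
        return (self.x, self.y, self.w, self.h)


def detect_fov(image: UltrasoundImage, config: AnalysisConfig | None = None) -> FovRect:
    """Locate the echo field of view inside the information frame.

    Pipeline: box blur (washes out thin frame text) → median filter
    (removes what remains of small glyphs) → local-median threshold →
    morphological closing → largest connected bright component.  The
    component must cover at least ``fov_min_area_frac`` of the image,
    otherwise :class:`FovNotFound` is raised and the caller should crop
    manually.
    """
    cfg = config or AnalysisConfig()
    img = image.pixels  # read-only; every op below allocates a new array

    blurred = ndimage.uniform_filter(img, size=cfg.fov_blur_size, mode="reflect")
    size = 2 * cfg.fov_median_radius + 1
    smooth = ndimage.median_filter(blurred, size=size, mode="reflect")

    win = max(3, int(round(cfg.fov_threshold_window_frac * image.height)))
    if win % 2 == 0:
        win += 1
    as_u8 = img_as_ubyte(np.clip(smooth, 0, 1))
    local_med = rank_median(as_u8, footprint=np.ones((win, win), dtype=bool))
    # strictly greater: the information frame is (near-)uniform, so it sits
    # exactly at its local median and stays off, while speckle keeps a large
    # fraction of the echo field above its local median.  The comparison
    # uses the box-blurred (not median-suppressed) raster so that heavily
    # smoothed flat muscle regions still fluctuate around their median.
    blur_u8 = img_as_ubyte(np.clip(blurred, 0, 1))
    binary = blur_u8.astype(np.int16) > local_med.astype(np.int16)

    # closing plus hole filling turns that speckle salt into one solid
    # region before component analysis
    binary = morphology.closing(binary, np.ones((5, 5), dtype=bool))
    binary = ndimage.binary_fill_holes(binary)
    labels = measure.label(binary, connectivity=2)
    if labels.max() == 0:
        raise FovNotFound(
            "no bright region found — crop the field of view manually"
        )
    props = measure.regionprops(labels)
    best = max(props, key=lambda p: p.area)
    min_area = cfg.fov_min_area_frac * image.width * image.height
    if best.area < min_area:
        raise FovNotFound(
            f"largest bright region covers only "
            f"{best.area / (image.width * image.height):.1%} of the image "
            f"(minimum {cfg.fov_min_area_frac:.0%}) — crop the field of view manually"
        )
    minr, minc, maxr, maxc = best.bbox
    return FovRect(x=int(minc), y=int(minr), w=int(maxc - minc), h=int(maxr - minr))


def crop(image: UltrasoundImage, rect: FovRect) -> UltrasoundImage:
    """Extract the sub-image under ``rect`` (the input is left untouched)."""
    rect.validate_within(image.width, image.height)
    sub = image.pixels[rect.y:rect.y + rect.h, rect.x:rect.x + rect.w].copy()
    return replace(image, pixels=sub)
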