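"""Image I/O, pixel-to-mm calibration, result tables, Bland-Altman helper."""
from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import SmaError, ValidationError
from .image import UltrasoundImage

__all__ = [
    "Calibration",
    "AgreementStats",
    "calibrate",
    "bland_altman",
    "load_image",
    "write_results",
    "read_results",
    "write_overlay_stack",
]

#: ITU-R BT.601 luma weights for RGB→grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-millimetre scaling and where it came from."""

    mm_per_px: float
    source: str = "manual_line"  # manual_line | phantom_truth | none

    def __post_init__(self) -> None:
        if not self.mm_per_px > 0:
            raise ValidationError(f"mm_per_px must be > 0, got {self.mm_per_px}")


def calibrate(line_length_px: float, known_length_mm: float,
              source: str = "manual_line") -> Calibration:
    """Calibration from a line drawn over the scale bar.

    ``line_length_px`` is the drawn length in pixels, ``known_length_mm``
    the physical length it spans.
    """
    if not line_length_px > 0 or not known_length_mm > 0:
        raise ValidationError(
            "calibrate requires positive line length and physical length, got "
            f"{line_length_px} px / {known_length_mm} mm"
        )
    return Calibration(mm_per_px=known_length_mm / line_length_px, source=source)


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman agreement between two paired measurement series."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    n: int

    def __post_init__(self) -> None:
        if not (self.loa_low <= self.bias <= self.loa_high):
            raise ValidationError("limits of agreement must bracket the bias")


def bland_altman(
    series_a: Sequence[float],
    series_b: Sequence[float],
    plot_path: Optional[str] = None,
    label: str = "",
) -> AgreementStats:
    """Bias and 95% limits of agreement between two measurement methods.

    Differences d = a − b; bias = mean(d); limits = bias ± 1.96·sd(d) with
    the sample (n−1) standard deviation.  Optionally writes the standard
    difference-vs-mean plot with solid bias and dotted limit lines.
    """
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(
            f"paired series must be 1-D and equal length, got {a.shape} vs {b.shape}"
        )
    if a.size < 2:
        raise ValidationError("need at least 2 paired measurements")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = bias - 1.96 * sd, bias + 1.96 * sd
    stats = AgreementStats(bias=bias, loa_low=lo, loa_high=hi, sd_diff=sd, n=a.size)

    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter((a + b) / 2.0, d, s=18, color="k")
        ax.axhline(bias, color="k", linestyle="-")
        ax.axhline(lo, color="k", linestyle=":")
        ax.axhline(hi, color="k", linestyle=":")
        ax.set_xlabel("mean of methods")
        ax.set_ylabel("difference (a - b)")
        if label:
            ax.set_title(label)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return stats


def _to_float01(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    arr = arr.astype(np.float64)
    if arr.max() > 1.0:  # float image on a 0..255 scale
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def load_image(path: str, mm_per_px: Optional[float] = None) -> UltrasoundImage:
    """Read PNG/TIFF/JPEG/BMP as a [0, 1] grayscale raster.

    RGB(A) input is converted with BT.601 luma weights; 8- and 16-bit
    integer images are scaled by their dtype maximum.
    """
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as e:
        raise SmaError(f"cannot read image file {path!r}: {e}") from e
    if arr.ndim == 3:
        arr = _to_float01(arr[..., :3]) @ _LUMA
    elif arr.ndim == 2:
        arr = _to_float01(arr)
    else:
        raise SmaError(f"unsupported image shape {arr.shape} in {path!r}")
    return UltrasoundImage(arr, mm_per_px=mm_per_px, source=os.fspath(path))


def write_results(rows: Iterable[dict] | pd.DataFrame, path: str) -> pd.DataFrame:
    """Write the per-image results table as CSV (one row per image)."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False)
    return df


def read_results(path: str) -> pd.DataFrame:
    return pd.read_csv(path)


def write_overlay_stack(images: List[np.ndarray], path: str) -> None:
    """Collect per-image overlays into a multi-page TIFF stack."""
    if not images:
        raise ValidationError("no overlays to write")
    tifffile.imwrite(path, np.stack([np.asarray(im) for im in images]),
                     photometric="rgb")
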