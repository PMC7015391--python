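"""Dominant fascicle orientation inside overlapping ROIs.

The fascicles form an oblique striation texture between the aponeuroses.
Within each region of interest the texture is lightly denoised, spectrally
thresholded to keep its dominant periodic components, ridge-enhanced at
fascicle scale, and its orientation measured from the gradient structure
tensor: gradients come from a quasi-isotropic cubic-spline derivative
filter, the tensor components are smoothed with a Gaussian window of
standard deviation σ and pooled over the ROI, and the dominant angle and
coherency follow from the pooled tensor's eigenstructure.

Angle convention: feature angle from the horizontal, positive rising toward
the left (pixel slope dy/dx = +tan θ), range (−90°, 90°].  Coherency
(λ₁−λ₂)/(λ₁+λ₂) ∈ [0, 1] measures how anisotropic the texture is; 1 is a
perfect grating, 0 is isotropic.
"""
from __future__ import annotations

from dataclasses import dataclass
from math import atan2, degrees
from statistics import median
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .aponeurosis import AponeurosisPath
from .config import AnalysisConfig
from .errors import NoFascicleOrientation, RoiTooSmall, ValidationError
from .fov import FovRect
from .image import UltrasoundImage
from . import filters

__all__ = [
    "RoiSpec",
    "OrientationResult",
    "SigmaSweep",
    "define_rois",
    "dominant_orientation",
    "sigma_sweep",
    "aggregate_angles",
]


@dataclass(frozen=True)
class RoiSpec:
    """Number and relative size of the orientation ROIs.

    Widths are a percentage of the inter-aponeurosis field width; heights a
    percentage of the local inter-aponeurosis gap, anchored at the deep
    aponeurosis (researchers usually favour the deeper region, where
    fascicles align best with the line of force).
    """

    n_rois: int = 3
    roi_width_pct: float = 60.0
    roi_height_pct: float = 90.0

    def validate(self) -> "RoiSpec":
        if self.n_rois < 1:
            raise ValidationError("n_rois must be >= 1")
        for name, v in (("roi_width_pct", self.roi_width_pct),
                        ("roi_height_pct", self.roi_height_pct)):
            if not 0 < v <= 100:
                raise ValidationError(f"{name} must be in (0, 100], got {v}")
        return self


@dataclass(frozen=True)
class OrientationResult:
    """Dominant angle + coherency for one ROI."""

    dominant_angle_deg: float
    coherency: float
    roi_rect: Optional[FovRect] = None
    valid: bool = True


def define_rois(
    fov_rect: FovRect,
    sup_path: AponeurosisPath,
    deep_path: AponeurosisPath,
    spec: RoiSpec,
    margin_px: int = 10,
    min_height_px: int = 16,
) -> List[FovRect]:
    """Place ``n_rois`` overlapping rectangles between the aponeuroses.

    Left edges are evenly spread at ``i * (W − w) / (n − 1)`` (a single ROI
    is centered).  Each ROI spans ``roi_height_pct`` of the local
    inter-aponeurosis gap measured up from the deep path, inset by
    ``margin_px`` from both bands.  Rectangles are in FoV coordinates.
    """
    spec.validate()
    W = fov_rect.w
    w = int(round(spec.roi_width_pct / 100.0 * W))
    w = max(8, min(w, W))
    n = spec.n_rois
    if n == 1:
        lefts = [int(round((W - w) / 2.0))]
    else:
        lefts = [int(round(i * (W - w) / (n - 1))) for i in range(n)]

    rois = []
    for left in lefts:
        xc = left + w / 2.0
        sup_y = float(sup_path.y_at(xc))
        deep_y = float(deep_path.y_at(xc))
        usable = (deep_y - margin_px) - (sup_y + margin_px)
        h = int(round(spec.roi_height_pct / 100.0 * usable))
        if h < min_height_px:
            raise RoiTooSmall(
                f"ROI height {h} px below the minimum usable size "
                f"{min_height_px} px (gap {deep_y - sup_y:.0f} px at x={xc:.0f})"
            )
        bottom = int(round(deep_y - margin_px))
        top = max(0, bottom - h)
        rois.append(FovRect(x=left, y=top, w=w, h=bottom - top))
    return rois


def _spline_gradient(image: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Quasi-isotropic cubic-spline image gradient.

    The image is prefiltered to cubic B-spline coefficients; the derivative
    along one axis is the exact B-spline derivative sampled at the pixel
    grid, and the perpendicular axis is reconstructed with the B-spline
    smoothing kernel, giving a nearly isotropic frequency response.
    """
    coeffs = ndimage.spline_filter(image, order=3, mode="mirror")
    d = np.array([0.5, 0.0, -0.5])          # B3'(x) at x = -1, 0, 1
    s = np.array([1.0, 4.0, 1.0]) / 6.0     # B3(x) at x = -1, 0, 1
    ix = ndimage.correlate1d(coeffs, d[::-1], axis=1, mode="mirror")
    ix = ndimage.correlate1d(ix, s, axis=0, mode="mirror")
    iy = ndimage.correlate1d(coeffs, d[::-1], axis=0, mode="mirror")
    iy = ndimage.correlate1d(iy, s, axis=1, mode="mirror")
    return ix, iy


def _preprocess_roi(roi: np.ndarray, config: AnalysisConfig) -> Optional[np.ndarray]:
    """Light denoise + windowed spectral threshold + fascicle-scale tubeness.

    The ROI is mean-subtracted and Hann-windowed before the FFT so that the
    striation peaks do not leak asymmetrically across bins (hard
    thresholding of a leaky DFT snaps the reconstructed orientation toward
    lattice angles); the mean is re-injected as a DC pedestal so the
    brightness-proportional threshold still measures signal bins against
    overall image brightness.  Returns ``None`` when no structure survives
    the threshold (flat or pure-speckle ROI).
    """
    if roi.max() - roi.min() <= 0:
        return None
    den = filters.denoise(
        roi, "fascicle",
        patch_size=config.nlm_patch_size, patch_distance=config.nlm_patch_distance,
        h_factor_aponeurosis=config.nlm_h_factor_aponeurosis,
        h_factor_fascicle=config.nlm_h_factor_fascicle,
        clahe_clip_limit=config.clahe_clip_limit,
    )
    h, w = den.shape
    window = np.hanning(h)[:, None] * np.hanning(w)[None, :]
    mean = float(den.mean())
    spec = filters.forward_spectrum((den - mean) * window)
    spec.fft[spec.dc_index] += mean * den.size
    spec = filters.threshold_spectrum(
        spec, config.spectrum_threshold,
        reference_brightness=mean, auto_k=config.spectrum_auto_k_fascicle,
    )
    recon = spec.inverse()
    if recon.max() - recon.min() < 1e-9:
        return None
    return filters.tubeness(filters.normalize01(recon),
                            config.tubeness_sigma_fascicle)


def dominant_orientation(
    roi_image: np.ndarray | UltrasoundImage,
    sigma: float = 4.0,
    config: AnalysisConfig | None = None,
    roi_rect: Optional[FovRect] = None,
    _preprocessed: Optional[np.ndarray] = None,
) -> OrientationResult:
    """Structure-tensor dominant orientation of one ROI.

    ``sigma`` is the Gaussian window of the tensor smoothing (0 = none).  A
    constant or structureless ROI yields coherency 0 and ``valid=False``.
    """
    if sigma < 0:
        raise ValidationError(f"sigma must be >= 0, got {sigma}")
    cfg = config or AnalysisConfig()
    roi = roi_image.pixels if isinstance(roi_image, UltrasoundImage) else np.asarray(
        roi_image, dtype=np.float64)
    if roi.ndim != 2 or min(roi.shape) < 8:
        raise ValidationError("ROI must be 2-D and at least 8 px on each side")

    enh = _preprocessed if _preprocessed is not None else _preprocess_roi(roi, cfg)
    if enh is None:
        return OrientationResult(0.0, 0.0, roi_rect, valid=False)

    ix, iy = _spline_gradient(enh)
    jxx, jxy, jyy = ix * ix, ix * iy, iy * iy
    if sigma > 0:
        jxx = ndimage.gaussian_filter(jxx, sigma, mode="reflect")
        jxy = ndimage.gaussian_filter(jxy, sigma, mode="reflect")
        jyy = ndimage.gaussian_filter(jyy, sigma, mode="reflect")
    mxx, mxy, myy = float(jxx.mean()), float(jxy.mean()), float(jyy.mean())

    trace = mxx + myy
    if trace <= 1e-15:
        return OrientationResult(0.0, 0.0, roi_rect, valid=False)
    coherency = float(np.hypot(mxx - myy, 2 * mxy) / trace)
    # tensor orientation in y-down pixel coordinates; negated to express a
    # feature angle that is positive for structures rising toward the left
    angle = -0.5 * degrees(atan2(2 * mxy, myy - mxx))
    angle = (angle + 90.0) % 180.0 - 90.0
    if angle == -90.0:
        angle = 90.0
    return OrientationResult(float(angle), min(1.0, coherency), roi_rect, valid=True)


@dataclass(frozen=True)
class SigmaSweep:
    """Result table of a σ sweep plus the texture-quality warning."""

    rows: Tuple[Tuple[float, float, float, bool], ...]  # (sigma, angle, coherency, valid)
    #: True when the texture looks unsuitable: the measured orientation
    #: increases continuously with σ (insufficient fascicle resolution), or
    #: no σ yields a coherent orientation at all
    warning: bool

    def as_table(self) -> str:
        lines = ["sigma  angle_deg  coherency  valid"]
        for s, a, c, v in self.rows:
            lines.append(f"{s:5.0f}  {a:9.2f}  {c:9.3f}  {str(v):>5}")
        return "\n".join(lines)


def sigma_sweep(
    roi_image: np.ndarray | UltrasoundImage,
    sigmas: Sequence[float] = tuple(range(8)),
    config: AnalysisConfig | None = None,
    coherency_floor: Optional[float] = None,
) -> SigmaSweep:
    """Run :func:`dominant_orientation` for σ = 0..7 (by default).

    The warning flag implements the scan-quality heuristic: when fascicles
    are insufficiently resolved the measured orientation increases
    continuously with σ.  It also fires when every σ fails to produce a
    coherent orientation (e.g. pure noise), since such a ROI cannot support
    an orientation measurement either.
    """
    cfg = config or AnalysisConfig()
    floor = cfg.coherency_floor if coherency_floor is None else coherency_floor
    roi = roi_image.pixels if isinstance(roi_image, UltrasoundImage) else np.asarray(
        roi_image, dtype=np.float64)
    pre = _preprocess_roi(roi, cfg)
    rows = []
    for s in sigmas:
        r = dominant_orientation(roi, float(s), cfg, _preprocessed=pre)
        rows.append((float(s), r.dominant_angle_deg, r.coherency, r.valid))
    return SigmaSweep(rows=tuple(rows), warning=sweep_warning(rows, floor))


def sweep_warning(rows: Sequence[Tuple[float, float, float, bool]],
                  coherency_floor: float = 0.05) -> bool:
    """Scan-quality heuristic applied to a σ-sweep table.

    Warns when the dominant orientation increases strictly and continuously
    with σ ≥ 1 (the signature of insufficiently resolved fascicles), or when
    no σ yields a usable (valid, coherent) orientation at all.
    """
    usable = [(s, a) for s, a, c, v in rows if v and c >= coherency_floor and s >= 1]
    if not usable:
        return True
    angles = [a for _, a in usable]
    return len(angles) >= 3 and all(b > a for a, b in zip(angles, angles[1:]))


def fft_orientation(
    roi_image: np.ndarray, step_deg: float = 0.1, pad_to: int = 512
) -> float:
    """Dominant feature angle by exhaustive frequency-domain search.

    Independent of the structure-tensor route: the zero-padded FFT power
    spectrum is summed along the central line perpendicular to each
    candidate feature angle, and the angle maximizing that directional
    second moment wins.  Used to cross-validate ``dominant_orientation``.
    """
    from scipy.ndimage import map_coordinates

    roi = np.asarray(roi_image, dtype=np.float64)
    roi = roi - roi.mean()
    n = max(pad_to, *roi.shape)
    power = np.abs(np.fft.fftshift(np.fft.fft2(roi, s=(n, n)))) ** 2
    c = n // 2
    radii = np.arange(2.0, n // 2 - 1)

    def moment(theta_deg: float) -> float:
        # energy of a feature at theta lies along the perpendicular
        t = np.radians(theta_deg + 90.0)
        du, dv = np.cos(t), np.sin(t)  # (x, y-down) step in frequency plane
        rows = c + radii * dv
        cols = c + radii * du
        vals = map_coordinates(power, [rows, cols], order=1, mode="constant")
        return float(vals.sum())

    coarse = np.arange(-90.0, 90.0, 1.0)
    best = coarse[int(np.argmax([moment(a) for a in coarse]))]
    fine = np.arange(best - 1.0, best + 1.0 + step_deg / 2, step_deg)
    best = fine[int(np.argmax([moment(a) for a in fine]))]
    best = (best + 90.0) % 180.0 - 90.0
    return float(best if best != -90.0 else 90.0)


def aggregate_angles(angles: Sequence[float], method: str = "median") -> float:
    """Combine per-ROI dominant angles: greatest, mean or median."""
    vals = [float(a) for a in angles]
    if not vals:
        raise NoFascicleOrientation(
            "no ROI produced a valid dominant fascicle orientation"
        )
    if method == "greatest":
        return max(vals)
    if method == "mean":
        return float(np.mean(vals))
    if method == "median":
        return float(median(vals))
    raise ValidationError(f"aggregate method must be greatest|mean|median, got {method!r}")
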