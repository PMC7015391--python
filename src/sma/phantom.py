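"""Synthetic B-mode-like phantoms with exactly known muscle architecture.

A phantom emulates a longitudinal scan of a unipennate muscle: two bright,
near-horizontal aponeurosis bands; oblique fascicle striations between them;
multiplicative speckle; and, optionally, the dark information frame that
surrounds a real scanner's field of view, complete with text-like clutter and
a tick-marked scale bar.  Because the geometry is constructed analytically,
the ground-truth pennation angle, fascicle length and muscle thickness are
known exactly and every pipeline stage can be validated by parameter
recovery.

Angle conventions match the analysis stages: the scan is oriented with the
proximal side on the left, fascicles rise toward the left (positive fascicle
angle, pixel slope dy/dx = +tan β) and aponeurosis angles are positive when
the band descends toward the left (pixel slope −tan α).  The pennation angle
is the sum β + α of the fascicle and deep-aponeurosis inclinations.

``thickness_px`` is the vertical distance between the two band *centerlines*
at mid-width; the detected aponeurosis paths downstream are likewise band
centerlines, so recovery is directly comparable.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from math import cos, radians, sin, tan
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .image import UltrasoundImage

__all__ = ["PhantomSpec", "PhantomGroundTruth", "generate_phantom", "save_phantom"]

#: tick spacing of the synthetic scale bar, in millimetres
SCALE_TICK_MM = 4.0

# rendering levels (fractions of full scale)
_MUSCLE_BASE = 0.22
_STRIPE_AMP = 0.38
_BAND_AMP = 0.62
_SUBCUT_BASE = 0.18
_BELOW_BASE = 0.10
_FRAME_LEVEL = 0.02
_GLYPH_LEVEL = 0.85


@dataclass(frozen=True)
class PhantomSpec:
    """Full ground-truth geometry + noise parameters for one synthetic scan.

    All positions are in pixels of the field of view (FoV); when
    ``frame=True`` the FoV is inset inside a dark border and the stated
    geometry applies within it.
    """

    width_px: int = 512
    height_px: int = 400
    #: superficial aponeurosis angle, deg from horizontal, + descending-left
    sup_apo_angle_deg: float = 0.0
    #: deep aponeurosis angle, same convention
    deep_apo_angle_deg: float = 0.0
    #: depth (px) of the superficial band centerline at image mid-width
    sup_apo_depth_px: float = 80.0
    #: vertical centerline-to-centerline distance at mid-width
    thickness_px: float = 140.0
    #: aponeurosis band thickness (px)
    apo_band_px: float = 6.0
    #: fascicle inclination, deg from horizontal, + rising-left, in (0, 90)
    fascicle_angle_deg: float = 20.0
    #: stripe spacing (px) measured perpendicular to the fascicles
    fascicle_period_px: float = 14.0
    #: multiplicative speckle strength (std of the gain fluctuation), >= 0
    speckle_sigma: float = 0.15
    #: embed the FoV in a dark frame with clutter and a scale bar
    frame: bool = False
    #: ground-truth calibration; also drives the scale-bar tick spacing
    scale_mm_per_px: Optional[float] = None
    seed: int = 0
    #: multiplier on the deep band brightness (1 = nominal; low values
    #: emulate a poorly insonated deep aponeurosis)
    deep_band_contrast: float = 1.0

    def validate(self) -> "PhantomSpec":
        if self.width_px < 32 or self.height_px < 32:
            raise ValidationError("phantom must be at least 32x32 px")
        fh = self.fov_size()[1]
        if not (0 < self.sup_apo_depth_px
                < self.sup_apo_depth_px + self.thickness_px < fh):
            raise ValidationError(
                "invariant violated: 0 < sup_apo_depth_px < sup_apo_depth_px"
                " + thickness_px < FoV height "
                f"({self.sup_apo_depth_px}, {self.thickness_px}, {fh})"
            )
        if not 0 < self.fascicle_angle_deg < 90:
            raise ValidationError(
                f"invariant violated: fascicle_angle_deg in (0, 90),"
                f" got {self.fascicle_angle_deg}"
            )
        if self.apo_band_px < 2:
            raise ValidationError(
                f"invariant violated: apo_band_px >= 2, got {self.apo_band_px}"
            )
        if self.fascicle_period_px < 4:
            raise ValidationError(
                f"invariant violated: fascicle_period_px >= 4,"
                f" got {self.fascicle_period_px}"
            )
        if self.speckle_sigma < 0:
            raise ValidationError(
                f"invariant violated: speckle_sigma >= 0, got {self.speckle_sigma}"
            )
        if self.scale_mm_per_px is not None and not self.scale_mm_per_px > 0:
            raise ValidationError("scale_mm_per_px must be > 0")
        return self

    def fov_origin(self) -> Tuple[int, int]:
        """(x, y) of the FoV's top-left corner within the full image."""
        if not self.frame:
            return (0, 0)
        return (round(0.12 * self.width_px), round(0.10 * self.height_px))

    def fov_size(self) -> Tuple[int, int]:
        """(w, h) of the FoV."""
        if not self.frame:
            return (self.width_px, self.height_px)
        ox, oy = round(0.12 * self.width_px), round(0.10 * self.height_px)
        return (self.width_px - 2 * ox, self.height_px - 2 * oy)


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Analytic architecture values implied by a :class:`PhantomSpec`."""

    true_pennation_deg: float
    true_fascicle_length_px: float
    true_thickness_px: float
    #: (x, y, w, h) of the embedded field of view in full-image coordinates
    fov_rect: Tuple[int, int, int, int]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fov_rect"] = list(d["fov_rect"])
        return d


def _ground_truth(spec: PhantomSpec) -> PhantomGroundTruth:
    beta = radians(spec.fascicle_angle_deg)
    a_sup = radians(spec.sup_apo_angle_deg)
    theta = spec.fascicle_angle_deg + spec.deep_apo_angle_deg
    # chord from the deep centerline at mid-width up to the superficial
    # centerline, at inclination beta (see module docstring for the algebra)
    denom = sin(beta) + tan(a_sup) * cos(beta)
    if denom <= 0:
        raise ValidationError(
            "fascicle line does not reach the superficial aponeurosis"
        )
    length = spec.thickness_px / denom
    ox, oy = spec.fov_origin()
    w, h = spec.fov_size()
    gt = PhantomGroundTruth(
        true_pennation_deg=theta,
        true_fascicle_length_px=length,
        true_thickness_px=spec.thickness_px,
        fov_rect=(ox, oy, w, h),
    )
    if not (gt.true_pennation_deg > 0 and np.isfinite(length) and length > 0):
        raise ValidationError("ground truth is not finite and positive")
    return gt


def band_centerline_y(spec: PhantomSpec, role: str, x: np.ndarray) -> np.ndarray:
    """Analytic centerline depth of one aponeurosis at FoV column(s) ``x``."""
    w, _ = spec.fov_size()
    xc = (w - 1) / 2.0
    if role == "superficial":
        y0, ang = spec.sup_apo_depth_px, spec.sup_apo_angle_deg
    elif role == "deep":
        y0 = spec.sup_apo_depth_px + spec.thickness_px
        ang = spec.deep_apo_angle_deg
    else:
        raise ValidationError(f"role must be 'superficial' or 'deep', got {role!r}")
    return y0 - tan(radians(ang)) * (np.asarray(x, dtype=float) - xc)


def _render_fov(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    w, h = spec.fov_size()
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)

    y_sup = band_centerline_y(spec, "superficial", x[0])[None, :]
    y_deep = band_centerline_y(spec, "deep", x[0])[None, :]

    img = np.full((h, w), _SUBCUT_BASE)
    below = y > y_deep
    img[below] = _BELOW_BASE

    # fascicle striations: rectified sinusoid -> bright ridges at the stripe
    # period, which the tubeness filter responds to like real fascicles
    beta = radians(spec.fascicle_angle_deg)
    phase = (-x * sin(beta) + y * cos(beta)) * (2 * np.pi / spec.fascicle_period_px)
    stripes = np.maximum(np.cos(phase), 0.0)
    muscle = (y >= y_sup) & (y <= y_deep)
    img[muscle] = _MUSCLE_BASE + _STRIPE_AMP * stripes[muscle]

    # aponeurosis bands: flat-topped profile with a 1-px soft shoulder
    half = spec.apo_band_px / 2.0
    for yc, gain in ((y_sup, 1.0), (y_deep, spec.deep_band_contrast)):
        d = np.abs(y - yc)
        profile = np.clip(half + 0.5 - d, 0.0, 1.0)
        img = np.maximum(img, _MUSCLE_BASE + gain * _BAND_AMP * profile)

    # mild blur emulates the finite beam width and keeps edges band-limited
    img = ndimage.gaussian_filter(img, 0.6, mode="reflect")

    if spec.speckle_sigma > 0:
        gain = 1.0 + rng.normal(0.0, spec.speckle_sigma, size=img.shape)
        img = img * gain
    return np.clip(img, 0.0, 1.0)


def _render_frame(spec: PhantomSpec, fov: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    img = np.full((spec.height_px, spec.width_px), _FRAME_LEVEL)
    ox, oy = spec.fov_origin()
    h, w = fov.shape
    img[oy:oy + h, ox:ox + w] = fov

    # text-like clutter: small bright rectangles in the top and bottom border
    for _ in range(24):
        gw = int(rng.integers(4, 16))
        gh = int(rng.integers(2, 4))
        gx = int(rng.integers(2, max(3, spec.width_px - gw - 2)))
        if rng.random() < 0.5:
            gy = int(rng.integers(2, max(3, oy - gh - 6)))
        else:
            gy = int(rng.integers(oy + h + 6, max(oy + h + 7, spec.height_px - gh - 2)))
        img[gy:gy + gh, gx:gx + gw] = _GLYPH_LEVEL

    # vertical scale bar with ticks at SCALE_TICK_MM intervals
    if spec.scale_mm_per_px is not None:
        bx = ox + w + max(2, (spec.width_px - ox - w) // 2)
        bx = min(bx, spec.width_px - 4)
        tick_px = SCALE_TICK_MM / spec.scale_mm_per_px
        img[oy:oy + h, bx] = _GLYPH_LEVEL * 0.5
        n_ticks = int(h // tick_px) + 1
        for i in range(n_ticks):
            ty = oy + int(round(i * tick_px))
            if ty >= oy + h:
                break
            img[ty, max(0, bx - 3):bx + 1] = _GLYPH_LEVEL
    return img


def generate_phantom(spec: PhantomSpec) -> Tuple[UltrasoundImage, PhantomGroundTruth]:
    """Render a phantom scan and its analytic ground truth.

    Identical ``(spec, seed)`` pairs produce bit-identical images.  The image
    is returned on the canonical [0, 1] float scale; quantization to 8 bits
    happens only on save.
    """
    spec.validate()
    gt = _ground_truth(spec)
    rng = np.random.default_rng(spec.seed)
    fov = _render_fov(spec, rng)
    if spec.frame:
        img = _render_frame(spec, fov, rng)
    else:
        img = fov
    ultra = UltrasoundImage(
        img, mm_per_px=spec.scale_mm_per_px,
        source=f"<phantom seed={spec.seed}>",
    )
    return ultra, gt


def save_phantom(spec: PhantomSpec, image_path: str,
                 sidecar_path: Optional[str] = None
                 ) -> Tuple[UltrasoundImage, PhantomGroundTruth]:
    """Write a phantom as an 8-bit grayscale image + JSON ground-truth sidecar."""
    import imageio.v3 as iio

    img, gt = generate_phantom(spec)
    data = np.clip(np.round(img.pixels * 255), 0, 255).astype(np.uint8)
    iio.imwrite(image_path, data)
    if sidecar_path is None:
        sidecar_path = str(image_path) + ".json"
    spec_d = asdict(spec)
    with open(sidecar_path, "w") as fh:
        json.dump({"spec": spec_d, "ground_truth": gt.to_dict()}, fh, indent=2)
    return img, gt


def phantom_grid(betas=(10.0, 20.0, 30.0), gaps=(80.0, 140.0, 200.0),
                 speckles=(0.0, 0.15, 0.3), base_seed: int = 0):
    """The standard parameter-recovery grid: one spec per combination.

    Seeds are derived deterministically from ``base_seed`` so the grid is
    reproducible but each phantom gets independent speckle.
    """
    specs = []
    for i, beta in enumerate(betas):
        for j, gap in enumerate(gaps):
            for k, sp in enumerate(speckles):
                specs.append(replace(
                    PhantomSpec(),
                    fascicle_angle_deg=float(beta),
                    thickness_px=float(gap),
                    speckle_sigma=float(sp),
                    sup_apo_depth_px=80.0,
                    seed=(base_seed * 1000 + i * 100 + j * 10 + k) % (2**31 - 1),
                ))
    return specs
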