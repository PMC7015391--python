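"""Architecture parameters: pennation angle, fascicle length, thickness.

Sign conventions (all angles in degrees from the horizontal):

* fascicle angle β — positive when fascicles rise toward the left
  (pixel slope dy/dx = +tan β);
* deep aponeurosis angle α — positive when the band descends toward the
  left (pixel slope −tan α);
* pennation θ = β + α, which equals the geometric angle between the
  composite fascicle line and the deep aponeurosis line (asserted against
  the vector dot-product angle on every call).

Fascicle length is the straight chord through an anchor point on the deep
aponeurosis at inclination β, up to its intersection with the superficial
aponeurosis; detected path points are used inside the detected support and
the fitted line beyond it (flagging the result as extrapolated).  Muscle
thickness is the mean per-column vertical distance between the two paths
over their shared support.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import atan2, cos, degrees, radians, sin, tan
from typing import List, Optional, Tuple

import numpy as np

from .aponeurosis import AponeurosisPath, detect_aponeuroses
from .config import AnalysisConfig
from .errors import NoIntersection, SmaError, ValidationError
from .fov import FovRect, crop, detect_fov
from .image import UltrasoundImage
from .orientation import (OrientationResult, RoiSpec, aggregate_angles,
                          define_rois, dominant_orientation)

__all__ = [
    "ArchitectureResult",
    "pennation_angle",
    "fascicle_length",
    "muscle_thickness",
    "analyse_image",
]


def pennation_angle(fascicle_angle_deg: float, deep_apo_angle_deg: float) -> float:
    """Pennation as the sum β + α of fascicle and deep-aponeurosis angles.

    Internally asserted (to 1e-9°) against the signed angle between the two
    direction vectors, which the sum equals exactly under the conventions
    above.
    """
    beta = radians(fascicle_angle_deg)
    alpha = radians(deep_apo_angle_deg)
    theta = fascicle_angle_deg + deep_apo_angle_deg
    # direction vectors in y-down pixel coordinates
    fasc = (cos(beta), sin(beta))
    apo = (cos(alpha), -sin(alpha))
    cross = apo[0] * fasc[1] - apo[1] * fasc[0]
    dot = apo[0] * fasc[0] + apo[1] * fasc[1]
    vec_angle = degrees(atan2(cross, dot))
    assert abs(vec_angle - theta) < 1e-9, (vec_angle, theta)
    return theta


def fascicle_length(
    sup_path: AponeurosisPath,
    deep_path: AponeurosisPath,
    fascicle_angle_deg: float,
    anchor_x: Optional[float] = None,
) -> Tuple[float, bool]:
    """Length (px) of the composite fascicle chord, plus extrapolation flag.

    The chord starts on the deep aponeurosis at ``anchor_x`` (default: the
    midpoint of its detected x-extent) and runs at inclination β until it
    meets the superficial aponeurosis.  If the intersection falls outside
    the superficial path's detected support, its fitted line is used and
    ``extrapolated`` is True.
    """
    if anchor_x is None:
        anchor_x = 0.5 * (deep_path.xs[0] + deep_path.xs[-1])
    theta = pennation_angle(fascicle_angle_deg, deep_path.line_angle_deg)
    if abs(theta) <= 0.5:
        raise NoIntersection(
            f"pennation {theta:.2f} deg is too shallow for a defined"
            " fascicle/aponeurosis intersection"
        )
    x0 = float(anchor_x)
    y0 = float(deep_path.y_at(x0))
    # parametric chord P(t) = (x0, y0) + t (cos beta, sin beta); stable for
    # near-vertical fascicles where a slope formulation degenerates
    beta = radians(fascicle_angle_deg)
    dx, dy = cos(beta), sin(beta)
    m_s = sup_path.slope
    denom = dy - m_s * dx
    if abs(denom) < 1e-12:
        raise NoIntersection("fascicle is parallel to the superficial aponeurosis")
    t_line = (sup_path.line_intercept_px + m_s * x0 - y0) / denom
    x_line = x0 + t_line * dx
    lo, hi = sup_path.x_extent
    extrapolated = not (lo <= x_line <= hi)
    t_star = t_line
    if not extrapolated:
        # refine against the detected (possibly non-straight) path
        ts = np.linspace(0.0, 1.2 * t_line, max(128, sup_path.xs.size))
        gap = (y0 + ts * dy) - np.asarray(sup_path.y_at(x0 + ts * dx))
        sign = np.sign(gap)
        idx = np.flatnonzero(np.diff(sign) != 0)
        if idx.size:
            i = idx[np.argmin(np.abs(ts[idx] - t_line))]
            t1, t2, g1, g2 = ts[i], ts[i + 1], gap[i], gap[i + 1]
            t_star = t1 if g2 == g1 else t1 - g1 * (t2 - t1) / (g2 - g1)
    return float(abs(t_star)), bool(extrapolated)


def muscle_thickness(sup_path: AponeurosisPath, deep_path: AponeurosisPath) -> float:
    """Mean per-column vertical distance between the two detected paths."""
    x0 = max(sup_path.xs[0], deep_path.xs[0])
    x1 = min(sup_path.xs[-1], deep_path.xs[-1])
    if x1 <= x0:
        raise ValidationError("aponeurosis paths share no x support")
    xs = np.arange(np.ceil(x0), np.floor(x1) + 1.0)
    gaps = np.asarray(deep_path.y_at(xs)) - np.asarray(sup_path.y_at(xs))
    return float(gaps.mean())


@dataclass
class ArchitectureResult:
    """Full per-image analysis output (px, plus mm when calibrated)."""

    pennation_deg: float
    fascicle_length_px: float
    thickness_px: float
    extrapolated: bool
    fascicle_angle_deg: float
    deep_apo_angle_deg: float
    sup_apo_angle_deg: float
    per_roi: List[OrientationResult]
    aggregate_method: str
    fov_rect: FovRect
    fascicle_length_mm: Optional[float] = None
    thickness_mm: Optional[float] = None
    mm_per_px: Optional[float] = None
    source: str = "<array>"
    sup_path: Optional[AponeurosisPath] = None
    deep_path: Optional[AponeurosisPath] = None
    params: Optional[dict] = None

    @property
    def per_roi_angles(self) -> List[float]:
        return [r.dominant_angle_deg for r in self.per_roi if r.valid]

    def to_row(self, include_params: bool = False) -> dict:
        """Flatten into one results-table row."""
        row = {
            "file": self.source,
            "pennation_deg": self.pennation_deg,
            "fascicle_length_px": self.fascicle_length_px,
            "fascicle_length_mm": self.fascicle_length_mm,
            "thickness_px": self.thickness_px,
            "thickness_mm": self.thickness_mm,
            "fascicle_angle_deg": self.fascicle_angle_deg,
            "deep_apo_angle_deg": self.deep_apo_angle_deg,
            "extrapolated": self.extrapolated,
            "aggregate_method": self.aggregate_method,
        }
        for i, r in enumerate(self.per_roi, start=1):
            row[f"roi{i}_angle_deg"] = r.dominant_angle_deg
            row[f"roi{i}_coherency"] = r.coherency
        if include_params and self.params is not None:
            for k, v in self.params.items():
                row[f"param_{k}"] = v
        return row


def _stage(name: str, exc: SmaError) -> SmaError:
    exc.args = (f"[{name}] {exc.args[0]}",) + exc.args[1:] if exc.args else (f"[{name}]",)
    return exc


def analyse_image(
    image: UltrasoundImage, config: AnalysisConfig | None = None
) -> ArchitectureResult:
    """Run the full four-stage pipeline on one scan.

    Stages: field-of-view detection/cropping → aponeurosis segmentation →
    per-ROI dominant fascicle orientation → architecture computation.  The
    analysis is fully deterministic: repeated calls on the same input yield
    identical results.  Stage errors propagate with a stage-labelled
    message.
    """
    cfg = (config or AnalysisConfig()).validated()
    img = image.flipped() if cfg.flip else image

    try:
        if cfg.crop == "auto":
            rect = detect_fov(img, cfg)
        elif cfg.crop == "manual":
            rect = FovRect(*cfg.crop_rect).validate_within(img.width, img.height)
        else:
            rect = FovRect(0, 0, img.width, img.height)
        fov_img = crop(img, rect)
    except SmaError as e:
        raise _stage("fov", e)

    try:
        sup, deep = detect_aponeuroses(fov_img, cfg.tubeness_sigma_apo, cfg)
    except SmaError as e:
        raise _stage("aponeurosis", e)

    try:
        roi_spec = RoiSpec(cfg.n_rois, cfg.roi_width_pct, cfg.roi_height_pct)
        local_rect = FovRect(0, 0, fov_img.width, fov_img.height)
        rois = define_rois(local_rect, sup, deep, roi_spec,
                           margin_px=cfg.roi_margin_px,
                           min_height_px=cfg.min_roi_height_px)
        per_roi = []
        for r in rois:
            sub = fov_img.pixels[r.y:r.y + r.h, r.x:r.x + r.w]
            per_roi.append(dominant_orientation(
                sub, cfg.orientation_sigma, cfg, roi_rect=r))
        valid = [r.dominant_angle_deg for r in per_roi
                 if r.valid and r.coherency >= cfg.coherency_floor]
        beta = aggregate_angles(valid, cfg.aggregate)
    except SmaError as e:
        raise _stage("orientation", e)

    try:
        theta = pennation_angle(beta, deep.line_angle_deg)
        anchor_x = (deep.xs[0]
                    + cfg.fascicle_anchor_frac * (deep.xs[-1] - deep.xs[0]))
        length, extrapolated = fascicle_length(sup, deep, beta, anchor_x)
        thickness = muscle_thickness(sup, deep)
    except SmaError as e:
        raise _stage("architecture", e)

    mmpp = image.mm_per_px
    return ArchitectureResult(
        pennation_deg=theta,
        fascicle_length_px=length,
        thickness_px=thickness,
        extrapolated=extrapolated,
        fascicle_angle_deg=beta,
        deep_apo_angle_deg=deep.line_angle_deg,
        sup_apo_angle_deg=sup.line_angle_deg,
        per_roi=per_roi,
        aggregate_method=cfg.aggregate,
        fov_rect=rect,
        fascicle_length_mm=length * mmpp if mmpp else None,
        thickness_mm=thickness * mmpp if mmpp else None,
        mm_per_px=mmpp,
        source=image.source,
        sup_path=sup,
        deep_path=deep,
        params=cfg.to_dict(),
    )


def render_overlay(
    fov_image: UltrasoundImage, result: ArchitectureResult
) -> np.ndarray:
    """Draw aponeurosis paths, ROI boxes and the composite fascicle on the
    cropped scan; returns an RGB uint8 array."""
    from skimage.draw import line as draw_line

    base = np.clip(fov_image.pixels, 0, 1)
    rgb = np.stack([base, base, base], axis=-1)
    h, w = base.shape

    def _put(rr, cc, color):
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        rgb[rr[ok], cc[ok]] = color

    green = (0.1, 0.9, 0.2)
    yellow = (0.95, 0.9, 0.1)
    red = (0.95, 0.2, 0.1)

    for path in (result.sup_path, result.deep_path):
        if path is None:
            continue
        xs = path.xs.astype(int)
        ys = np.round(path.ys).astype(int)
        _put(ys, xs, green)

    for r in result.per_roi:
        rect = r.roi_rect
        if rect is None:
            continue
        x0, y0, x1, y1 = rect.x, rect.y, rect.x + rect.w - 1, rect.y + rect.h - 1
        for (ra, ca, rb, cb) in ((y0, x0, y0, x1), (y1, x0, y1, x1),
                                 (y0, x0, y1, x0), (y0, x1, y1, x1)):
            rr, cc = draw_line(ra, ca, rb, cb)
            _put(rr, cc, yellow)

    if result.deep_path is not None:
        # composite fascicle: from the deep-aponeurosis anchor, up-left
        # along the dominant orientation for the measured length
        x0 = result.deep_path.xs[0] + 0.5 * (
            result.deep_path.xs[-1] - result.deep_path.xs[0])
        y0 = float(result.deep_path.y_at(x0))
        L = result.fascicle_length_px
        x1 = x0 - L * cos(radians(result.fascicle_angle_deg))
        y1 = y0 - L * sin(radians(result.fascicle_angle_deg))
        rr, cc = draw_line(int(round(y0)), int(round(x0)),
                           int(round(y1)), int(round(x1)))
        _put(rr, cc, red)

    return (rgb * 255).astype(np.uint8)
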