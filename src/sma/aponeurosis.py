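"""Segmentation and registration of the superficial and deep aponeuroses.

The aponeuroses appear as two bright, near-horizontal bands bounding the
muscle belly.  The stage enhances them with the heavy denoise preset and a
tubeness (Hessian ridge) filter at a band-sized scale, removes
fascicle-direction components in the Fourier domain, detects edges with a
Canny detector on the reconstructed image, chains laterally contiguous edge
pixels into near-horizontal polylines, and merges the polylines belonging to
one band into a single centerline path with a fitted (total-least-squares)
line.

Angle convention: aponeurosis line angles are measured from the horizontal
and are positive when the band descends toward the left of the image (pixel
slope dy/dx = −tan α).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import atan2, degrees, radians, tan
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage import feature

from .config import AnalysisConfig
from .errors import ApoNotFound, ValidationError
from .image import UltrasoundImage
from . import filters

__all__ = [
    "AponeurosisPath",
    "detect_aponeuroses",
    "register_parallel_lines",
    "fit_line",
    "extrapolate",
]

_APO_FAIL_ADVICE = (
    "could not register two aponeuroses — try cropping the image manually "
    "or using a higher value of tubeness sigma"
)


def fit_line(points: Sequence[Tuple[float, float]]) -> Tuple[float, float]:
    """Total-least-squares line through ``points``.

    Returns ``(angle_deg, intercept_px)`` where the angle follows the
    aponeurosis convention (positive = descending toward the left, i.e.
    negative pixel slope) and the intercept is the fitted y at x = 0.
    Orthogonal (TLS) fitting is used so steeply noisy paths do not bias the
    angle the way ordinary y-on-x regression would.
    """
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValidationError("fit_line requires at least 2 (x, y) points")
    centroid = pts.mean(axis=0)
    u, s, vt = np.linalg.svd(pts - centroid, full_matrices=False)
    dx, dy = vt[0]
    if dx == 0:
        raise ValidationError("degenerate vertical point set")
    angle_deg = -degrees(atan2(dy, dx))
    angle_deg = (angle_deg + 90.0) % 180.0 - 90.0
    slope = dy / dx
    intercept = centroid[1] - slope * centroid[0]
    return float(angle_deg), float(intercept)


@dataclass
class AponeurosisPath:
    """Detected centerline of one aponeurosis plus its fitted line.

    ``xs``/``ys`` hold one point per sampled column within ``x_extent``; the
    fitted line extends the path beyond its detected support (used when the
    composite fascicle leaves the field of view).
    """

    role: str  # "superficial" | "deep"
    xs: np.ndarray
    ys: np.ndarray
    line_angle_deg: float = field(init=False)
    line_intercept_px: float = field(init=False)

    def __post_init__(self) -> None:
        if self.role not in ("superficial", "deep"):
            raise ValidationError(f"role must be superficial|deep, got {self.role!r}")
        self.xs = np.asarray(self.xs, dtype=np.float64)
        self.ys = np.asarray(self.ys, dtype=np.float64)
        if self.xs.ndim != 1 or self.xs.shape != self.ys.shape or self.xs.size < 2:
            raise ValidationError("path needs >= 2 points with matching shapes")
        if not np.all(np.diff(self.xs) > 0):
            raise ValidationError("path points must be strictly increasing in x")
        self.line_angle_deg, self.line_intercept_px = fit_line(
            np.column_stack([self.xs, self.ys])
        )

    @property
    def x_extent(self) -> Tuple[float, float]:
        return (float(self.xs[0]), float(self.xs[-1]))

    @property
    def slope(self) -> float:
        """Pixel slope dy/dx of the fitted line."""
        return -tan(radians(self.line_angle_deg))

    def line_y(self, x) -> np.ndarray:
        return self.line_intercept_px + self.slope * np.asarray(x, dtype=float)

    def y_at(self, x):
        """Detected y (linearly interpolated) inside the support, fitted
        line outside — the extrapolation rule for out-of-FoV fascicles."""
        x_arr = np.atleast_1d(np.asarray(x, dtype=float))
        inside = (x_arr >= self.xs[0]) & (x_arr <= self.xs[-1])
        out = np.where(
            inside, np.interp(x_arr, self.xs, self.ys), self.line_y(x_arr)
        )
        return out if np.ndim(x) else float(out[0])


def extrapolate(path: AponeurosisPath, x) -> float:
    """Depth of the aponeurosis at column ``x`` (detected or extrapolated)."""
    return path.y_at(x)


def register_parallel_lines(
    edge_map: np.ndarray,
    gap_tol: int = 10,
    dy_tol: float = 3.0,
    min_span_frac: float = 0.5,
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Chain edge pixels into near-horizontal candidate polylines.

    Scans the binary edge map column by column, linking each column's edge
    segments to the laterally nearest active chain (bridging gaps of up to
    ``gap_tol`` columns and vertical jumps up to ``dy_tol`` px per column).
    Chains spanning less than ``min_span_frac`` of the width, or steeper
    than 45° overall, are rejected.  Candidates are returned ordered by mean
    depth (shallowest first); an empty list is a valid result.
    """
    edge = np.asarray(edge_map, dtype=bool)
    if edge.ndim != 2:
        raise ValidationError("edge map must be 2-D")
    h, w = edge.shape
    chains: List[dict] = []
    active: List[dict] = []
    for x in range(w):
        rows = np.flatnonzero(edge[:, x])
        if rows.size:
            # group vertically adjacent edge pixels into one node per segment
            splits = np.flatnonzero(np.diff(rows) > 1) + 1
            nodes = [float(seg.mean()) for seg in np.split(rows, splits)]
        else:
            nodes = []
        # retire chains that fell too far behind
        still = []
        for c in active:
            if x - c["xs"][-1] > gap_tol:
                chains.append(c)
            else:
                still.append(c)
        active = still
        taken = set()
        for y in nodes:
            best = None
            best_d = None
            for idx, c in enumerate(active):
                if idx in taken:
                    continue
                dx = x - c["xs"][-1]
                d = abs(y - c["ys"][-1])
                if d <= dy_tol * dx and (best_d is None or d < best_d):
                    best, best_d = idx, d
            if best is None:
                active.append({"xs": [x], "ys": [y]})
                taken.add(len(active) - 1)
            else:
                active[best]["xs"].append(x)
                active[best]["ys"].append(y)
                taken.add(best)
    chains.extend(active)

    out = []
    for c in chains:
        xs = np.asarray(c["xs"], dtype=float)
        ys = np.asarray(c["ys"], dtype=float)
        if xs.size < 2 or (xs[-1] - xs[0]) < min_span_frac * w:
            continue
        angle, _ = fit_line(np.column_stack([xs, ys]))
        if abs(angle) >= 45.0:
            continue
        out.append((xs, ys))
    out.sort(key=lambda t: float(t[1].mean()))
    return out


def _merge_cluster(members: List[Tuple[np.ndarray, np.ndarray]], role: str
                   ) -> AponeurosisPath:
    """Average the edge polylines of one band into its centerline path."""
    all_x = np.concatenate([m[0] for m in members])
    all_y = np.concatenate([m[1] for m in members])
    xs = np.unique(all_x)
    ys = np.array([all_y[all_x == x].mean() for x in xs])
    return AponeurosisPath(role=role, xs=xs, ys=ys)


def _refine_centerline(
    path: AponeurosisPath, clean: np.ndarray, window_px: int
) -> AponeurosisPath:
    """Register the path onto the band in the stripe-suppressed image.

    The tubeness ridge skews a pixel or two toward the brighter side of an
    asymmetric neighbourhood (the striated muscle belly), so the initial
    Canny-based estimate is refined per column: within a vertical window
    around the estimate, the band's top and bottom shoulders are located as
    the extrema of the vertical intensity gradient and the centerline is
    their midpoint.  The band's intensity profile is symmetric about its
    centerline, which makes this registration insensitive to the background
    step that biases the ridge filter.
    """
    from scipy import ndimage

    grad = ndimage.gaussian_filter1d(clean, 1.5, axis=0, order=1)
    h = clean.shape[0]
    ys = path.ys.copy()
    for i, (x, y0) in enumerate(zip(path.xs.astype(int), path.ys)):
        lo = max(0, int(round(y0)) - window_px)
        hi = min(h, int(round(y0)) + window_px + 1)
        if hi - lo < 5:
            continue
        col = grad[lo:hi, x]
        top = lo + int(np.argmax(col))      # dark->bright shoulder
        bot = lo + int(np.argmin(col))      # bright->dark shoulder
        if bot > top:
            ys[i] = 0.5 * (top + bot)
    return AponeurosisPath(role=path.role, xs=path.xs, ys=ys)


def detect_aponeuroses(
    fov_image: UltrasoundImage,
    tubeness_sigma: Optional[float] = None,
    config: AnalysisConfig | None = None,
) -> Tuple[AponeurosisPath, AponeurosisPath]:
    """Segment both aponeuroses in a cropped field of view.

    Pipeline: heavy denoise → tubeness at ``tubeness_sigma`` → FFT →
    magnitude threshold → wedge mask suppressing fascicle-direction
    components → inverse FFT → Canny → polyline registration → merge the
    edge pair of each band into a centerline path.  Raises
    :class:`ApoNotFound` (with the manual-crop / higher-sigma advice) when
    fewer than two bands can be registered.
    """
    cfg = config or AnalysisConfig()
    sigma = float(tubeness_sigma if tubeness_sigma is not None else cfg.tubeness_sigma_apo)
    if sigma <= 0:
        raise ValidationError(f"tubeness sigma must be > 0, got {sigma}")

    den = filters.denoise(
        fov_image.pixels, "aponeurosis",
        patch_size=cfg.nlm_patch_size, patch_distance=cfg.nlm_patch_distance,
        h_factor_aponeurosis=cfg.nlm_h_factor_aponeurosis,
        h_factor_fascicle=cfg.nlm_h_factor_fascicle,
        clahe_clip_limit=cfg.clahe_clip_limit,
    )
    tub = filters.normalize01(filters.tubeness(den, sigma))

    spec = filters.forward_spectrum(tub)
    spec = filters.threshold_spectrum(
        spec, cfg.spectrum_threshold, reference_brightness=float(tub.mean()),
        auto_k=cfg.spectrum_auto_k,
    )
    lo, hi = cfg.mask_feature_angles
    spec = filters.orientation_mask(
        spec, suppress_center_deg=(lo + hi) / 2.0,
        suppress_halfwidth_deg=(hi - lo) / 2.0, taper_deg=cfg.mask_taper_deg,
    )
    recon = filters.normalize01(spec.inverse())

    edges = feature.canny(
        recon, sigma=cfg.canny_sigma,
        low_threshold=cfg.canny_low_quantile,
        high_threshold=cfg.canny_high_quantile,
        use_quantiles=True,
    )
    candidates = register_parallel_lines(
        edges, gap_tol=cfg.chain_gap_px, dy_tol=cfg.chain_dy_px,
        min_span_frac=cfg.min_line_span_frac,
    )
    if len(candidates) < 2:
        raise ApoNotFound(_APO_FAIL_ADVICE)

    # cluster candidates by depth: polylines closer than a few tubeness
    # sigmas are the two edges of the same band
    merge_dist = cfg.apo_merge_dist_sigmas * sigma
    clusters: List[List[Tuple[np.ndarray, np.ndarray]]] = [[candidates[0]]]
    for cand in candidates[1:]:
        if cand[1].mean() - clusters[-1][-1][1].mean() <= merge_dist:
            clusters[-1].append(cand)
        else:
            clusters.append([cand])
    if len(clusters) < 2:
        raise ApoNotFound(_APO_FAIL_ADVICE)

    # topmost cluster = superficial; bottommost = deep; anything between
    # (septa, fat fascia) is ignored
    sup = _merge_cluster(clusters[0], "superficial")
    deep = _merge_cluster(clusters[-1], "deep")

    # register both centerlines onto the bands of the stripe-suppressed
    # denoised image (see _refine_centerline)
    clean_spec = filters.orientation_mask(
        filters.forward_spectrum(den), suppress_center_deg=(lo + hi) / 2.0,
        suppress_halfwidth_deg=(hi - lo) / 2.0, taper_deg=cfg.mask_taper_deg,
    )
    clean = clean_spec.inverse()

    def _window(cluster) -> int:
        spreads = [m[1].mean() for m in cluster]
        spread = max(spreads) - min(spreads)
        return int(np.clip(np.ceil(0.75 * spread) + 2, 6, 16))

    sup = _refine_centerline(sup, clean, _window(clusters[0]))
    deep = _refine_centerline(deep, clean, _window(clusters[-1]))

    if abs(sup.line_angle_deg) >= 45 or abs(deep.line_angle_deg) >= 45:
        raise ApoNotFound(_APO_FAIL_ADVICE)
    x0 = max(sup.xs[0], deep.xs[0])
    x1 = min(sup.xs[-1], deep.xs[-1])
    if x1 <= x0:
        raise ApoNotFound(_APO_FAIL_ADVICE)
    shared = np.linspace(x0, x1, 32)
    if not np.all(deep.y_at(shared) > sup.y_at(shared)):
        raise ApoNotFound(_APO_FAIL_ADVICE)
    return sup, deep
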