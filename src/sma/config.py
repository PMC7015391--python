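"""Analysis configuration.

One flat dataclass gathers every tunable of the four pipeline stages so a run
can be serialized to a manifest and replayed exactly.  Defaults mirror the
values recommended for typical longitudinal scans of superficial pennate
muscle (e.g. gastrocnemius medialis at 9-12 MHz).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple, Union

from .errors import ValidationError


@dataclass
class AnalysisConfig:
    # --- image preparation -------------------------------------------------
    #: mirror the scan so the proximal side is on the left
    flip: bool = False
    #: "auto" = detect the field of view, "manual" = use crop_rect, "none"
    crop: str = "auto"
    crop_rect: Optional[Tuple[int, int, int, int]] = None

    # --- field-of-view detection ------------------------------------------
    #: box-blur kernel that washes out frame text before thresholding
    fov_blur_size: int = 5
    #: median filter radius (px) applied after the blur
    fov_median_radius: int = 3
    #: local-median threshold window, as a fraction of image height
    fov_threshold_window_frac: float = 0.125
    #: smallest believable FoV, as a fraction of total image area
    fov_min_area_frac: float = 0.20

    # --- aponeurosis stage -------------------------------------------------
    #: Gaussian scale (px) of the tubeness filter used to enhance aponeuroses
    tubeness_sigma_apo: float = 10.0
    #: feature-angle band (degrees, rising-left positive) suppressed in the
    #: spectrum before aponeurosis edge detection — the directions in which
    #: fascicles, not aponeuroses, are expected
    mask_feature_angles: Tuple[float, float] = (10.0, 80.0)
    #: cosine-taper width (deg) of the wedge mask edges; 0 = hard edges
    mask_taper_deg: float = 0.0
    #: Canny: Gaussian scale and hysteresis thresholds (gradient quantiles)
    canny_sigma: float = 2.0
    canny_low_quantile: float = 0.85
    canny_high_quantile: float = 0.95
    #: lateral gap (px) bridged when chaining edge pixels into polylines
    chain_gap_px: int = 10
    #: per-column vertical jump tolerance (px) when chaining
    chain_dy_px: float = 3.0
    #: minimum polyline span, as a fraction of the FoV width
    min_line_span_frac: float = 0.5
    #: candidates closer than this many tubeness sigmas are edges of the
    #: same aponeurosis band and are merged into one path
    apo_merge_dist_sigmas: float = 2.5

    # --- spectrum thresholding ---------------------------------------------
    #: "auto" or a fraction of the peak spectral magnitude in (0, 1]
    spectrum_threshold: Union[str, float] = "auto"
    #: auto threshold = k x mean brightness (of the image whose spectrum is
    #: being thresholded; brightness on the [0, 1] scale)
    spectrum_auto_k: float = 0.5
    #: same constant for the windowed ROI spectra of the fascicle stage;
    #: smaller because the Hann window attenuates non-DC bins (tuned on
    #: phantoms so fascicle fundamentals survive and pure speckle does not)
    spectrum_auto_k_fascicle: float = 0.05

    # --- denoise presets ---------------------------------------------------
    nlm_patch_size: int = 5
    nlm_patch_distance: int = 5  # search window 11 px
    #: cut strength h as a multiple of the estimated noise sigma
    nlm_h_factor_aponeurosis: float = 1.6
    nlm_h_factor_fascicle: float = 0.9
    clahe_clip_limit: float = 0.003

    # --- fascicle orientation ----------------------------------------------
    n_rois: int = 3
    roi_width_pct: float = 60.0
    roi_height_pct: float = 90.0
    #: safety margin (px) kept between each ROI and both aponeuroses
    roi_margin_px: int = 10
    min_roi_height_px: int = 16
    #: Gaussian window sigma of the structure tensor (0 = no smoothing)
    orientation_sigma: float = 4.0
    #: tubeness scale (px) used to enhance fascicles inside ROIs
    tubeness_sigma_fascicle: float = 2.0
    #: ROIs with pooled coherency below this floor are dropped
    coherency_floor: float = 0.05
    #: how per-ROI dominant angles are combined: greatest | mean | median
    aggregate: str = "median"

    # --- architecture -------------------------------------------------------
    #: anchor of the composite fascicle on the deep aponeurosis, as a
    #: fraction of the detected x-extent (0.5 = midpoint)
    fascicle_anchor_frac: float = 0.5

    # --- output -------------------------------------------------------------
    print_params: bool = False

    def validated(self) -> "AnalysisConfig":
        if self.crop not in ("auto", "manual", "none"):
            raise ValidationError(f"crop must be auto|manual|none, got {self.crop!r}")
        if self.crop == "manual" and self.crop_rect is None:
            raise ValidationError("crop='manual' requires crop_rect")
        if self.tubeness_sigma_apo <= 0:
            raise ValidationError("tubeness_sigma_apo must be > 0")
        if self.aggregate not in ("greatest", "mean", "median"):
            raise ValidationError(
                f"aggregate must be greatest|mean|median, got {self.aggregate!r}"
            )
        if self.n_rois < 1:
            raise ValidationError("n_rois must be >= 1")
        for name in ("roi_width_pct", "roi_height_pct"):
            v = getattr(self, name)
            if not 0 < v <= 100:
                raise ValidationError(f"{name} must be in (0, 100], got {v}")
        if isinstance(self.spectrum_threshold, str):
            if self.spectrum_threshold != "auto":
                raise ValidationError("spectrum_threshold must be 'auto' or a number")
        elif not 0 < float(self.spectrum_threshold) <= 1:
            raise ValidationError("numeric spectrum_threshold must be in (0, 1]")
        return self

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["crop_rect"] is not None:
            d["crop_rect"] = list(d["crop_rect"])
        d["mask_feature_angles"] = list(d["mask_feature_angles"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        kwargs = dict(d)
        if kwargs.get("crop_rect") is not None:
            kwargs["crop_rect"] = tuple(kwargs["crop_rect"])
        if "mask_feature_angles" in kwargs:
            kwargs["mask_feature_angles"] = tuple(kwargs["mask_feature_angles"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(kwargs) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs).validated()
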