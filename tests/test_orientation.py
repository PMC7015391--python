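"""ROI layout, structure-tensor orientation, sigma sweep, aggregation."""
import numpy as np
import pytest

from helpers import grating, path_from_line
from sma.config import AnalysisConfig
from sma.errors import NoFascicleOrientation, RoiTooSmall, ValidationError
from sma.fov import FovRect
from sma.orientation import (RoiSpec, aggregate_angles, define_rois,
                             dominant_orientation, fft_orientation,
                             sigma_sweep)


# ------------------------------------------------------------- define_rois

def _flat_paths(gap=200.0, width=400):
    sup = path_from_line("superficial", 0.0, 50.0, 0, width)
    deep = path_from_line("deep", 0.0, 50.0 + gap, 0, width)
    return sup, deep


def test_roi_left_edges_follow_spacing_formula():
    sup, deep = _flat_paths(width=300)
    rois = define_rois(FovRect(0, 0, 300, 300), sup, deep,
                       RoiSpec(n_rois=3, roi_width_pct=60, roi_height_pct=50))
    assert [r.x for r in rois] == [0, 60, 120]
    assert all(r.w == 180 for r in rois)
    # adjacent ROIs overlap by 120 px
    assert rois[0].x + rois[0].w - rois[1].x == 120


def test_two_rois_at_sixty_percent_overlap():
    sup, deep = _flat_paths(width=300)
    rois = define_rois(FovRect(0, 0, 300, 300), sup, deep,
                       RoiSpec(n_rois=2, roi_width_pct=60, roi_height_pct=50))
    assert rois[0].x + rois[0].w > rois[1].x  # 2 x 60% > 100%


def test_full_height_roi_spans_gap_minus_margins():
    sup, deep = _flat_paths(gap=200.0)
    margin = 10
    rois = define_rois(FovRect(0, 0, 400, 300), sup, deep,
                       RoiSpec(n_rois=1, roi_width_pct=50, roi_height_pct=100),
                       margin_px=margin)
    r = rois[0]
    assert r.y == pytest.approx(50 + margin, abs=1)
    assert r.y + r.h == pytest.approx(250 - margin, abs=1)


def test_rois_exclude_aponeuroses(default_phantom, analysis_config):
    from sma.aponeurosis import detect_aponeuroses
    spec, img, _ = default_phantom
    sup, deep = detect_aponeuroses(img)
    rois = define_rois(FovRect(0, 0, img.width, img.height), sup, deep,
                       RoiSpec(3, 60, 90), margin_px=10)
    for r in rois:
        xc = r.x + r.w / 2.0
        assert r.y > sup.y_at(xc)
        assert r.y + r.h < deep.y_at(xc)


def test_too_small_gap_raises_roi_too_small():
    sup, deep = _flat_paths(gap=30.0)
    with pytest.raises(RoiTooSmall):
        define_rois(FovRect(0, 0, 400, 300), sup, deep,
                    RoiSpec(2, 60, 50), margin_px=10, min_height_px=16)


# ----------------------------------------------------- dominant_orientation

def test_grating_angle_within_half_degree():
    r = dominant_orientation(grating(20.0), sigma=4.0)
    assert abs(r.dominant_angle_deg - 20.0) < 0.5
    assert r.coherency > 0.9
    assert r.valid


def test_rotation_equivariance_within_half_degree():
    base = dominant_orientation(grating(20.0), 4.0).dominant_angle_deg
    rot = dominant_orientation(grating(30.0), 4.0).dominant_angle_deg
    assert abs((rot - base) - 10.0) < 0.5


def test_constant_roi_is_flagged_invalid():
    r = dominant_orientation(np.full((64, 64), 0.4), 4.0)
    assert r.coherency == 0.0 and not r.valid


def test_white_noise_roi_has_negligible_coherency():
    rng = np.random.default_rng(4)
    for _ in range(3):
        noise = np.clip(rng.normal(0.4, 0.12, (64, 64)), 0, 1)
        r = dominant_orientation(noise, 4.0)
        assert r.coherency < 0.1


def test_speckle_reduces_coherency_of_grating():
    rng = np.random.default_rng(5)
    g = grating(20.0, amp=0.2)
    noisy = np.clip(g + rng.normal(0.0, 0.25, g.shape), 0, 1)
    clean = dominant_orientation(g, 4.0)
    speckled = dominant_orientation(noisy, 4.0)
    assert 0.0 <= speckled.coherency <= 1.0
    assert speckled.coherency < clean.coherency


def test_negative_sigma_rejected():
    with pytest.raises(ValidationError):
        dominant_orientation(grating(20.0), -1.0)


def test_structure_tensor_matches_fft_directional_moment_oracle():
    """Dual-route check: pooled-tensor angle vs exhaustive frequency-domain
    search, on small gratings of random angle/period/phase."""
    rng = np.random.default_rng(12)
    for _ in range(8):
        ang = rng.uniform(-80, 80)
        g = grating(ang, shape=(64, 64), period=rng.uniform(6, 18),
                    phase0=rng.uniform(0, 2 * np.pi))
        st = dominant_orientation(g, 4.0).dominant_angle_deg
        fo = fft_orientation(g)
        assert abs((st - fo + 90) % 180 - 90) < 1.0


# ------------------------------------------------------------- sigma_sweep

def test_sweep_covers_sigma_zero_to_seven_and_is_stable_on_gratings():
    sw = sigma_sweep(grating(25.0))
    assert [row[0] for row in sw.rows] == [0, 1, 2, 3, 4, 5, 6, 7]
    angles = [row[1] for row in sw.rows]
    assert max(angles) - min(angles) < 1.0
    assert sw.warning is False


def test_sweep_warns_on_pure_noise():
    rng = np.random.default_rng(6)
    noise = np.clip(rng.normal(0.4, 0.12, (96, 96)), 0, 1)
    assert sigma_sweep(noise).warning is True


def test_sweep_warning_rule_on_constructed_tables():
    """The insufficient-resolution heuristic: orientation that keeps
    growing with sigma marks the scan as unsuitable; a stable or
    non-monotonic orientation does not."""
    from sma.orientation import sweep_warning

    increasing = [(float(s), 10.0 + 2.0 * s, 0.5, True) for s in range(8)]
    assert sweep_warning(increasing) is True
    stable = [(float(s), 20.0 + 0.1 * (-1) ** s, 0.5, True) for s in range(8)]
    assert sweep_warning(stable) is False
    all_invalid = [(float(s), 0.0, 0.0, False) for s in range(8)]
    assert sweep_warning(all_invalid) is True


# -------------------------------------------------------------- aggregate

@pytest.mark.parametrize("angles, method, expected", [
    ([10.0, 12.0, 14.0], "mean", 12.0),
    ([10.0, 12.0, 20.0], "median", 12.0),
    ([10.0, 12.0, 20.0], "greatest", 20.0),
])
def test_aggregate_methods(angles, method, expected):
    assert aggregate_angles(angles, method) == pytest.approx(expected)


def test_aggregate_empty_raises():
    with pytest.raises(NoFascicleOrientation):
        aggregate_angles([], "mean")


def test_aggregate_unknown_method_raises():
    with pytest.raises(ValidationError):
        aggregate_angles([1.0], "mode")
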