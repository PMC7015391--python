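"""Architecture computation: pennation, fascicle length, thickness,
end-to-end analysis."""
from math import radians, sin, tan

import numpy as np
import pytest

from helpers import path_from_line
from sma.architecture import (analyse_image, fascicle_length, muscle_thickness,
                              pennation_angle, render_overlay)
from sma.config import AnalysisConfig
from sma.errors import NoIntersection, ValidationError
from sma.fov import crop
from sma.phantom import PhantomSpec, generate_phantom


# --------------------------------------------------------------- pennation

@pytest.mark.parametrize("beta, alpha, expected", [
    (15.0, 3.0, 18.0),
    (20.0, 0.0, 20.0),
    (20.0, -4.0, 16.0),
])
def test_pennation_is_sum_of_angles(beta, alpha, expected):
    # the sum is internally asserted against the vector dot-product oracle
    assert pennation_angle(beta, alpha) == pytest.approx(expected, abs=1e-9)


def test_pennation_equals_vector_angle_on_a_grid():
    for beta in np.linspace(1, 40, 9):
        for alpha in np.linspace(-10, 10, 9):
            # the internal assertion is the oracle; it must never trip
            assert pennation_angle(beta, alpha) == pytest.approx(beta + alpha,
                                                                 abs=1e-9)


# --------------------------------------------------------- fascicle_length

def test_parallel_horizontal_aponeuroses_closed_form():
    sup = path_from_line("superficial", 0.0, 50.0)
    deep = path_from_line("deep", 0.0, 150.0)
    length, extrapolated = fascicle_length(sup, deep, 30.0, anchor_x=350.0)
    assert length == pytest.approx(100.0 / sin(radians(30.0)), rel=1e-6)
    assert not extrapolated


def test_vertical_chord_limit():
    sup = path_from_line("superficial", 0.0, 50.0)
    deep = path_from_line("deep", 0.0, 150.0)
    length, _ = fascicle_length(sup, deep, 90.0, anchor_x=200.0)
    assert length == pytest.approx(100.0, rel=1e-6)


def test_non_parallel_lines_match_analytic_intersection_oracle():
    alpha, sup_angle, beta = 4.0, -2.0, 18.0
    anchor_x = 200.0
    deep = path_from_line("deep", alpha, 250.0)
    # choose the superficial intercept so the gap at the anchor is 120 px
    deep_y0 = 250.0 - tan(radians(alpha)) * anchor_x
    sup_b = deep_y0 - 120.0 + tan(radians(sup_angle)) * anchor_x
    sup = path_from_line("superficial", sup_angle, sup_b)

    # brute-force oracle: intersect the three explicit line equations
    m_f, m_s = tan(radians(beta)), -tan(radians(sup_angle))
    x_star = (sup_b - (deep_y0 - m_f * anchor_x)) / (m_f - m_s)
    y_star = sup_b + m_s * x_star
    expected = np.hypot(x_star - anchor_x, y_star - deep_y0)

    length, _ = fascicle_length(sup, deep, beta, anchor_x=anchor_x)
    assert length == pytest.approx(expected, rel=1e-9)


def test_chord_leaving_the_fov_sets_extrapolated_flag():
    sup = path_from_line("superficial", 0.0, 50.0, 0, 100)   # short support
    deep = path_from_line("deep", 0.0, 250.0, 0, 100)
    length, extrapolated = fascicle_length(sup, deep, 15.0, anchor_x=90.0)
    assert extrapolated
    assert length == pytest.approx(200.0 / sin(radians(15.0)), rel=1e-6)


def test_parallel_fascicle_and_aponeurosis_raise():
    sup = path_from_line("superficial", 0.0, 50.0)
    deep = path_from_line("deep", 0.0, 150.0)
    with pytest.raises(NoIntersection):
        fascicle_length(sup, deep, 0.2)  # pennation below the 0.5 deg floor


# --------------------------------------------------------- muscle_thickness

def test_thickness_flat_paths():
    sup = path_from_line("superficial", 0.0, 50.0)
    deep = path_from_line("deep", 0.0, 150.0)
    assert muscle_thickness(sup, deep) == pytest.approx(100.0)


def test_thickness_of_converging_paths_is_midrange_mean():
    # gap falls linearly 120 -> 80 across the image; the mean of a linear
    # function is its central value
    xs = np.arange(0, 400, dtype=float)
    sup = path_from_line("superficial", 0.0, 50.0)
    from sma.aponeurosis import AponeurosisPath
    deep = AponeurosisPath("deep", xs, 170.0 - 40.0 * xs / 399.0)
    assert muscle_thickness(sup, deep) == pytest.approx(100.0, abs=0.2)


def test_thickness_requires_shared_support():
    sup = path_from_line("superficial", 0.0, 50.0, 0, 100)
    deep = path_from_line("deep", 0.0, 150.0, 200, 300)
    with pytest.raises(ValidationError):
        muscle_thickness(sup, deep)


def test_phantom_thickness_recovery(default_phantom, analysis_config):
    from sma.aponeurosis import detect_aponeuroses
    spec, img, gt = default_phantom
    sup, deep = detect_aponeuroses(img)
    assert muscle_thickness(sup, deep) == pytest.approx(gt.true_thickness_px,
                                                        abs=2.0)


# ------------------------------------------------------------ analyse_image

def test_end_to_end_parameter_recovery(default_phantom, analysis_config):
    spec, img, gt = default_phantom
    res = analyse_image(img, analysis_config)
    assert res.pennation_deg == pytest.approx(gt.true_pennation_deg, abs=2.0)
    assert res.thickness_px == pytest.approx(gt.true_thickness_px, abs=4.0)
    assert res.fascicle_length_px == pytest.approx(gt.true_fascicle_length_px,
                                                   rel=0.05)


def test_repeated_analysis_is_bit_identical(default_phantom, analysis_config):
    _, img, _ = default_phantom
    a = analyse_image(img, analysis_config)
    b = analyse_image(img, analysis_config)
    assert a.pennation_deg == b.pennation_deg
    assert a.fascicle_length_px == b.fascicle_length_px
    assert a.thickness_px == b.thickness_px
    assert a.per_roi_angles == b.per_roi_angles


def test_flip_equivariance(default_phantom, analysis_config):
    _, img, _ = default_phantom
    direct = analyse_image(img, analysis_config)
    import dataclasses
    flipped_cfg = dataclasses.replace(analysis_config, flip=True)
    mirrored = analyse_image(img.flipped(), flipped_cfg)
    assert abs(mirrored.pennation_deg - direct.pennation_deg) < 1e-6
    assert abs(mirrored.thickness_px - direct.thickness_px) < 1e-6
    assert abs(mirrored.fascicle_length_px - direct.fascicle_length_px) < 1e-6


def test_chord_never_shorter_than_thickness(grid_results):
    for _, _, res in grid_results:
        assert res.fascicle_length_px >= res.thickness_px


def test_narrow_fov_extrapolates_with_small_error():
    spec = PhantomSpec(width_px=256, height_px=400, fascicle_angle_deg=12.0,
                       thickness_px=180.0, speckle_sigma=0.1, seed=4)
    img, gt = generate_phantom(spec)
    res = analyse_image(img, AnalysisConfig(crop="none"))
    assert res.extrapolated
    assert res.fascicle_length_px == pytest.approx(gt.true_fascicle_length_px,
                                                   rel=0.05)


def test_calibrated_outputs_scale_linearly(analysis_config):
    spec = PhantomSpec(speckle_sigma=0.15, seed=11, scale_mm_per_px=0.08)
    img, _ = generate_phantom(spec)
    res = analyse_image(img, analysis_config)
    assert res.fascicle_length_mm == pytest.approx(0.08 * res.fascicle_length_px,
                                                   rel=1e-12)
    assert res.thickness_mm == pytest.approx(0.08 * res.thickness_px, rel=1e-12)


def test_result_row_and_parameter_echo(default_phantom, analysis_config):
    _, img, _ = default_phantom
    res = analyse_image(img, analysis_config)
    row = res.to_row(include_params=True)
    assert {"file", "pennation_deg", "fascicle_length_px", "thickness_px",
            "extrapolated"} <= set(row)
    assert row["param_aggregate"] == "median"
    assert "roi1_coherency" in row
    plain = res.to_row()
    assert not any(k.startswith("param_") for k in plain)


def test_overlay_has_expected_shape_and_annotations(default_phantom,
                                                    analysis_config):
    _, img, _ = default_phantom
    res = analyse_image(img, analysis_config)
    fov_img = crop(img, res.fov_rect)
    overlay = render_overlay(fov_img, res)
    assert overlay.shape == (fov_img.height, fov_img.width, 3)
    assert overlay.dtype == np.uint8
    # annotation colors present (pure green channel dominance somewhere)
    assert (overlay[..., 1].astype(int) - overlay[..., 0]).max() > 100
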