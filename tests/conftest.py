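from __future__ import annotations

import numpy as np
import pytest

from sma.architecture import analyse_image
from sma.config import AnalysisConfig
from sma.phantom import PhantomSpec, generate_phantom, phantom_grid


@pytest.fixture(scope="session")
def default_phantom():
    """Standard mid-grid phantom: β=20°, gap 140 px, moderate speckle."""
    spec = PhantomSpec(speckle_sigma=0.15, seed=11)
    img, gt = generate_phantom(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def framed_phantom():
    spec = PhantomSpec(frame=True, speckle_sigma=0.15,
                       scale_mm_per_px=0.08, seed=2)
    img, gt = generate_phantom(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def analysis_config():
    """Pipeline defaults for frameless phantoms (nothing to crop)."""
    return AnalysisConfig(crop="none")


@pytest.fixture(scope="session")
def grid_results(analysis_config):
    """Full-pipeline parameter recovery over the 27-phantom grid.

    Computed once per session; shared by the recovery and end-to-end tests.
    """
    out = []
    for spec in phantom_grid(base_seed=1):
        img, gt = generate_phantom(spec)
        res = analyse_image(img, analysis_config)
        out.append((spec, gt, res))
    return out
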