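"""Shared fixtures-support code for the test suite."""
from __future__ import annotations

import numpy as np

from sma.aponeurosis import AponeurosisPath


def grating(theta_deg: float, shape=(128, 128), period: float = 12.0,
            amp: float = 0.4, base: float = 0.4, phase0: float = 0.0) -> np.ndarray:
    """Sinusoidal stripe pattern at feature angle ``theta_deg``.

    Positive angle = stripes rising toward the left (pixel slope +tan θ).
    """
    h, w = shape
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    t = np.radians(theta_deg)
    phase = (-x * np.sin(t) + y * np.cos(t)) * (2 * np.pi / period) + phase0
    return base + amp * np.cos(phase)


def lattice_grating(fx: int, fy: int, n: int = 128, amp: float = 0.4,
                    base: float = 0.5) -> np.ndarray:
    """Grating whose frequency lies exactly on DFT bin (fx, fy).

    Its feature angle is ``degrees(atan2(fx, -fy))`` folded to (-90, 90];
    being lattice-exact, the pattern occupies just two conjugate bins plus
    DC, which makes spectral pass/kill assertions exact.
    """
    y, x = np.mgrid[0:n, 0:n].astype(np.float64)
    return base + amp * np.cos(2 * np.pi * (fx * x + fy * y) / n)


def lattice_feature_angle(fx: int, fy: int) -> float:
    ang = np.degrees(np.arctan2(fx, -fy))
    ang = (ang + 90.0) % 180.0 - 90.0
    return float(ang if ang != -90.0 else 90.0)


def path_from_line(role: str, angle_deg: float, intercept_px: float,
                   x0: int = 0, x1: int = 400) -> AponeurosisPath:
    """Aponeurosis path lying exactly on a fitted line.

    ``angle_deg`` follows the aponeurosis convention (positive descending
    toward the left): pixel slope is −tan(angle).
    """
    xs = np.arange(x0, x1, dtype=float)
    ys = intercept_px - np.tan(np.radians(angle_deg)) * xs
    return AponeurosisPath(role=role, xs=xs, ys=ys)
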