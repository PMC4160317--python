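"""Shared fixtures: rendered blobs and small simulated scenes."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import settings
from scipy.ndimage import gaussian_filter

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

from fishtrack.detection import DetectionParams, Frame


def gaussian_spot(sigma: float, cx: float = 64.0, cy: float = 64.0,
                  size: int = 128, depth: float = 150.0,
                  background: float = 200.0) -> Frame:
    """Dark isotropic Gaussian spot on a light background."""
    yy, xx = np.mgrid[0:size, 0:size]
    img = background - depth * np.exp(
        -(((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2))
    )
    return Frame(np.clip(img, 0, 255))


def solid_ellipse(a: float, b: float, angle_deg: float, size: int = 160,
                  cx: float | None = None, cy: float | None = None,
                  fg: float = 50.0, bg: float = 200.0,
                  blur: float = 1.0) -> Frame:
    """Solid dark ellipse with half-axes (a, b), lightly blurred."""
    cx = size / 2.0 if cx is None else cx
    cy = size / 2.0 if cy is None else cy
    yy, xx = np.mgrid[0:size, 0:size]
    t = math.radians(angle_deg)
    dx, dy = xx - cx, yy - cy
    u = dx * math.cos(t) + dy * math.sin(t)
    v = -dx * math.sin(t) + dy * math.cos(t)
    img = np.where((u / a) ** 2 + (v / b) ** 2 <= 1.0, fg, bg)
    return Frame(np.clip(gaussian_filter(img, blur), 0, 255))


def aniso_gaussian(sx: float, sy: float, angle_deg: float = 0.0,
                   size: int = 128, depth: float = 150.0) -> Frame:
    """Dark anisotropic Gaussian spot (axis stds sx > sy)."""
    yy, xx = np.mgrid[0:size, 0:size]
    t = math.radians(angle_deg)
    dx, dy = xx - size / 2.0, yy - size / 2.0
    u = dx * math.cos(t) + dy * math.sin(t)
    v = -dx * math.sin(t) + dy * math.cos(t)
    img = 200.0 - depth * np.exp(-(u**2 / (2 * sx**2) + v**2 / (2 * sy**2)))
    return Frame(np.clip(img, 0, 255))


@pytest.fixture(scope="session")
def spot_params() -> DetectionParams:
    """Scale grid covering sigma in [2, 14] for Gaussian-spot tests."""
    grid = [2.0]
    while grid[-1] < 14.0:
        grid.append(grid[-1] * 1.26)
    return DetectionParams(w_min=4.0, w_max=40.0, scale_grid=tuple(grid))


def brute_force_scale_space(frame: Frame, scales) -> tuple[float, float, float]:
    """Independent oracle: dense argmax of the dark-blob DoH response.

    Evaluates compute_doh_response on every scale of a fine grid and
    returns the (x, y, s) of the global maximum restricted to dark blobs
    (positive Laplacian).
    """
    from scipy.ndimage import gaussian_filter as gf

    from fishtrack.detection import compute_doh_response

    best = (-np.inf, 0.0, 0.0, 0.0)
    for s in scales:
        resp = compute_doh_response(frame, s)
        lap = (gf(frame.pixels, s, order=(2, 0), truncate=3.0)
               + gf(frame.pixels, s, order=(0, 2), truncate=3.0))
        resp = np.where(lap > 0, resp, -np.inf)
        r, c = np.unravel_index(np.argmax(resp), resp.shape)
        if resp[r, c] > best[0]:
            best = (resp[r, c], float(c), float(r), float(s))
    return best[1], best[2], best[3]
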