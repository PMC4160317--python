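"""Fish-head detection: scale-space blob detection plus ellipse fitting.

A fish seen from above is a rigid, dark, roughly elliptical head followed by
a deformable tapering tail.  The head is the only part whose shape and gray
distribution stay constant while the fish swims, so detection reduces to
finding dark elliptical blobs of head-like width.

The detector works in three stages:

1. *Scale-space determinant-of-Hessian (DoH) blob detection.*  The image is
   convolved with Gaussian second-derivative kernels at a geometric grid of
   scales; blob centers are extrema of the scale-normalized determinant
   ``s^4 (Lxx Lyy - Lxy^2)`` over the 26-neighborhood in (x, y, s), refined
   to sub-grid accuracy by a quadratic fit.  Only dark blobs (positive
   Laplacian) are kept.
2. *Ellipse fitting.*  The 2x2 Hessian at the refined extremum is
   eigen-decomposed; the eigenvector of the smaller-magnitude eigenvalue
   gives the elongation direction, and the eigenvalue ratio the anisotropy.
3. *Candidate constraints.*  Width, contrast, and per-region angle
   constraints remove tail/body blobs and duplicate detections while keeping
   both heads of an occluding pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from skimage import measure


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Frame:
    """A 2-D 8-bit grayscale video frame.

    Coordinates are 0-based with ``x`` = column, ``y`` = row and pixel
    centers at integer positions.
    """

    pixels: np.ndarray
    index: int = 0

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("frame must be a 2-D gray image")
        if px.shape[0] < 32 or px.shape[1] < 32:
            raise ValueError("frame must be at least 32x32 px")
        if not np.all(np.isfinite(px)) or px.min() < 0 or px.max() > 255:
            raise ValueError("pixel values must be finite and in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ScaleSpacePoint:
    """A refined dark-blob extremum in (x, y, scale) space."""

    x: float
    y: float
    s: float
    doh_value: float


@dataclass(frozen=True)
class EllipseFit:
    cx: float
    cy: float
    length: float     # full major axis, px
    width: float      # full minor axis, px
    angle: float      # major-axis orientation, degrees in [0, 180)
    lambda1: float    # larger-|.| Hessian eigenvalue
    lambda2: float
    contrast: float = 0.0

    @property
    def ratio(self) -> float:
        return abs(self.lambda1) / abs(self.lambda2)


@dataclass(frozen=True)
class HeadDetection:
    frame_index: int
    ellipse: EllipseFit
    scale: float
    segment_label: int | None = None

    # convenience accessors used throughout tracking/evaluation
    @property
    def x(self) -> float:
        return self.ellipse.cx

    @property
    def y(self) -> float:
        return self.ellipse.cy

    @property
    def angle(self) -> float:
        return self.ellipse.angle

    @property
    def length(self) -> float:
        return self.ellipse.length

    @property
    def width(self) -> float:
        return self.ellipse.width


def _default_scale_grid(w_min: float, w_max: float) -> tuple[float, ...]:
    """Geometric grid s_i = s_min * 1.26**i spanning [w_min/4, w_max/1.5].

    Heads of width 16-24 px produce in-range DoH extrema on this grid
    (a solid disc of radius r responds maximally at s = r/sqrt(2)).
    """
    s_min, s_max = w_min / 4.0, w_max / 1.5
    grid = [s_min]
    while grid[-1] * 1.26 < s_max:
        grid.append(grid[-1] * 1.26)
    grid.append(s_max)
    return tuple(grid)


@dataclass(frozen=True)
class DetectionParams:
    """Detection-stage parameters.

    ``w_min``/``w_max`` bound the fitted head width in pixels (default
    16-24), ``k`` is the contrast adjustment parameter (a candidate is an
    effective head iff its local contrast >= k), and ``angle_sep_deg`` the
    duplicate-suppression angle: two candidates in one segmented fish region
    whose headings differ by less than this are duplicates of one head.
    """

    w_min: float = 16.0
    w_max: float = 24.0
    k: float = 0.03
    angle_sep_deg: float = 30.0
    # [w_min, w_max] describes the animals' physical head-width range; the
    # Hessian width estimator carries measurement error (+5% on isolated
    # elliptical blobs, ~-10% on heads with an attached body, which inflates
    # the curvature ratio), so the band is expanded by this fraction before
    # comparing against an estimate.
    width_margin: float = 0.15
    scale_grid: tuple[float, ...] = None  # type: ignore[assignment]
    min_region_area: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if not (0 < self.w_min < self.w_max):
            raise ValueError("need 0 < w_min < w_max")
        if self.k <= 0:
            raise ValueError("contrast parameter k must be > 0")
        if self.scale_grid is None:
            object.__setattr__(
                self, "scale_grid", _default_scale_grid(self.w_min, self.w_max)
            )
        grid = tuple(float(s) for s in self.scale_grid)
        if any(b <= a for a, b in zip(grid, grid[1:])) or grid[0] <= 0:
            raise ValueError("scale grid must be positive and strictly increasing")
        object.__setattr__(self, "scale_grid", grid)
        if self.min_region_area is None:
            # large enough to kill speckle, smaller than a lone head
            object.__setattr__(
                self, "min_region_area", math.pi * self.w_min**2 / 8.0
            )


# --------------------------------------------------------------------------
# Scale-space DoH
# --------------------------------------------------------------------------

def _hessian_components(img: np.ndarray, s: float):
    """Gaussian second derivatives Lxx, Lyy, Lxy at scale s (reflect pad).

    Axis 0 is y (rows), axis 1 is x (columns).  The image mean is removed
    first: truncated derivative kernels have a small nonzero DC gain, so
    without this a constant offset would leak into the response (a constant
    image must give an identically zero Hessian).
    """
    img = img - img.dtype.type(img.mean(dtype=np.float64))
    lyy = ndimage.gaussian_filter(img, s, order=(2, 0), mode="reflect", truncate=3.0)
    lxx = ndimage.gaussian_filter(img, s, order=(0, 2), mode="reflect", truncate=3.0)
    lxy = ndimage.gaussian_filter(img, s, order=(1, 1), mode="reflect", truncate=3.0)
    return lxx, lyy, lxy


def compute_doh_response(frame: Frame, s: float) -> np.ndarray:
    """Scale-normalized determinant-of-Hessian response at scale ``s``.

    Returns ``s^4 * (Lxx*Lyy - Lxy^2)``, same shape as the frame.  The s^4
    factor is the standard gamma-normalization that makes responses
    comparable across scales: a solid disc of radius r then attains its
    maximum at s = r/sqrt(2).
    """
    if s <= 0:
        raise ValueError("scale must be positive")
    lxx, lyy, lxy = _hessian_components(frame.pixels, s)
    return s**4 * (lxx * lyy - lxy * lxy)


class _ScaleSpaceStacks:
    """Per-scale DoH, Laplacian and Hessian-component grids (float32)."""

    def __init__(self, frame: Frame, scales):
        img32 = frame.pixels.astype(np.float32)
        shape = (len(scales),) + frame.pixels.shape
        self.scales = tuple(scales)
        self.doh = np.empty(shape, np.float32)
        self.lap = np.empty(shape, np.float32)
        self.lxx = np.empty(shape, np.float32)
        self.lyy = np.empty(shape, np.float32)
        self.lxy = np.empty(shape, np.float32)
        for i, s in enumerate(scales):
            lxx, lyy, lxy = _hessian_components(img32, s)
            self.lxx[i], self.lyy[i], self.lxy[i] = lxx, lyy, lxy
            self.doh[i] = s**4 * (lxx * lyy - lxy * lxy)
            self.lap[i] = lxx + lyy

    def hessian_at(self, x: float, y: float, s: float) -> np.ndarray:
        """2x2 Hessian at a sub-pixel point, linear in space and log-scale."""
        scales = self.scales
        i = min(range(len(scales)), key=lambda k: abs(math.log(s / scales[k])))
        if s >= scales[i] and i + 1 < len(scales):
            j = i + 1
        elif i > 0:
            i, j = i - 1, i
        else:
            j = i + 1
        w = (math.log(s) - math.log(scales[i])) / (
            math.log(scales[j]) - math.log(scales[i]))
        w = min(1.0, max(0.0, w))
        coords = np.array([[y], [x]])
        out = np.empty((2, 2))
        comps = []
        for stack in (self.lxx, self.lyy, self.lxy):
            vi = ndimage.map_coordinates(stack[i], coords, order=1)[0]
            vj = ndimage.map_coordinates(stack[j], coords, order=1)[0]
            comps.append((1.0 - w) * vi + w * vj)
        vxx, vyy, vxy = comps
        return np.array([[vxx, vxy], [vxy, vyy]])


def _doh_stack(frame: Frame, scales) -> tuple[np.ndarray, np.ndarray]:
    """(n_scales, H, W) DoH stack and Laplacian stack (float32 scan)."""
    st = _ScaleSpaceStacks(frame, scales)
    return st.doh, st.lap


def _refine_quadratic(stack: np.ndarray, i: int, r: int, c: int):
    """Second-order Taylor refinement of a 3-D lattice extremum.

    Returns (di, dr, dc) sub-grid offsets, each clamped to [-0.5, 0.5], and
    the interpolated peak value.
    """
    cube = stack[i - 1 : i + 2, r - 1 : r + 2, c - 1 : c + 2]
    g = np.array(
        [
            (cube[2, 1, 1] - cube[0, 1, 1]) / 2.0,
            (cube[1, 2, 1] - cube[1, 0, 1]) / 2.0,
            (cube[1, 1, 2] - cube[1, 1, 0]) / 2.0,
        ]
    )
    h = np.empty((3, 3))
    h[0, 0] = cube[2, 1, 1] - 2 * cube[1, 1, 1] + cube[0, 1, 1]
    h[1, 1] = cube[1, 2, 1] - 2 * cube[1, 1, 1] + cube[1, 0, 1]
    h[2, 2] = cube[1, 1, 2] - 2 * cube[1, 1, 1] + cube[1, 1, 0]
    h[0, 1] = h[1, 0] = (cube[2, 2, 1] - cube[2, 0, 1] - cube[0, 2, 1] + cube[0, 0, 1]) / 4.0
    h[0, 2] = h[2, 0] = (cube[2, 1, 2] - cube[2, 1, 0] - cube[0, 1, 2] + cube[0, 1, 0]) / 4.0
    h[1, 2] = h[2, 1] = (cube[1, 2, 2] - cube[1, 2, 0] - cube[1, 0, 2] + cube[1, 0, 0]) / 4.0
    try:
        off = -np.linalg.solve(h, g)
    except np.linalg.LinAlgError:
        off = np.zeros(3)
    off = np.clip(off, -0.5, 0.5)
    val = cube[1, 1, 1] + 0.5 * float(g @ off)
    return off, val


def detect_scale_space_minima(
    frame: Frame, params: DetectionParams,
    _stacks: _ScaleSpaceStacks | None = None,
) -> list[ScaleSpacePoint]:
    """Dark-blob extrema of the DoH response over (x, y, scale).

    A retained point is a strict 26-neighborhood maximum of the
    scale-normalized determinant with positive determinant *and* positive
    Laplacian (the dark-blob polarity: an intensity minimum has positive
    curvature in both directions).  ``doh_value`` is reported negated so
    that retained points carry a negative, minimum-like response, the darker
    and blobbier the more negative.

    Extrema closer than ``2 s`` to the image border are discarded.
    """
    scales = params.scale_grid
    if len(scales) < 3:
        raise ValueError("need at least 3 scales for scale-space extrema")
    if _stacks is None:
        _stacks = _ScaleSpaceStacks(frame, scales)
    doh, lap = _stacks.doh, _stacks.lap

    # strict interior maxima over the 26-neighborhood (separable box max)
    maxf = doh
    for ax in range(3):
        maxf = ndimage.maximum_filter1d(maxf, 3, axis=ax, mode="constant",
                                        cval=-np.inf)
    # tiny absolute floor rejects numerically-flat regions of constant images
    is_peak = (doh == maxf) & (doh > 1e-8) & (lap > 0)
    is_peak[0] = is_peak[-1] = False

    pts: list[ScaleSpacePoint] = []
    log_step = {
        i: math.log(scales[min(i + 1, len(scales) - 1)] / scales[max(i - 1, 0)]) / 2.0
        for i in range(len(scales))
    }
    h, w = frame.pixels.shape
    for i, r, c in zip(*np.nonzero(is_peak)):
        if r < 1 or c < 1 or r >= h - 1 or c >= w - 1:
            continue
        # guard against plateaus: strictness on the full neighborhood
        cube = doh[i - 1 : i + 2, r - 1 : r + 2, c - 1 : c + 2]
        if np.count_nonzero(cube == cube[1, 1, 1]) > 1:
            continue
        off, val = _refine_quadratic(doh, i, r, c)
        s_ref = scales[i] * math.exp(off[0] * log_step[i])
        y_ref, x_ref = r + off[1], c + off[2]
        if (
            x_ref < 2 * s_ref
            or y_ref < 2 * s_ref
            or x_ref > w - 1 - 2 * s_ref
            or y_ref > h - 1 - 2 * s_ref
        ):
            continue
        pts.append(ScaleSpacePoint(x=float(x_ref), y=float(y_ref), s=float(s_ref),
                                   doh_value=-float(val)))
    pts.sort(key=lambda p: p.doh_value)
    return pts


# --------------------------------------------------------------------------
# Ellipse fitting
# --------------------------------------------------------------------------

def hessian_at(frame: Frame, x: float, y: float, s: float) -> np.ndarray:
    """2x2 image Hessian [[Lxx, Lxy], [Lxy, Lyy]] at a sub-pixel point.

    Computed on a local patch (radius 4s) so that per-point evaluation stays
    cheap for arbitrary refined scales.
    """
    h, w = frame.pixels.shape
    rad = int(math.ceil(4 * s)) + 2
    r0, r1 = max(0, int(y) - rad), min(h, int(y) + rad + 1)
    c0, c1 = max(0, int(x) - rad), min(w, int(x) + rad + 1)
    patch = frame.pixels[r0:r1, c0:c1]
    lxx, lyy, lxy = _hessian_components(patch, s)
    coords = np.array([[y - r0], [x - c0]])
    vxx = ndimage.map_coordinates(lxx, coords, order=1)[0]
    vyy = ndimage.map_coordinates(lyy, coords, order=1)[0]
    vxy = ndimage.map_coordinates(lxy, coords, order=1)[0]
    return np.array([[vxx, vxy], [vxy, vyy]])


class DegenerateHessianError(ValueError):
    """Raised when the Hessian at an extremum is numerically degenerate."""


def fit_ellipse(frame: Frame, p: ScaleSpacePoint,
                _stacks: _ScaleSpaceStacks | None = None) -> EllipseFit:
    """Fit an ellipse to a scale-space extremum via Hessian eigenstructure.

    The eigenvector belonging to the smaller-magnitude eigenvalue (the
    direction of least curvature) is the elongation direction of the blob,
    i.e. the head axis.  Half-axes are ``sqrt(2)*s*ratio**(+-1/2)`` with
    ``ratio = |l1|/|l2| >= 1``: the geometric-mean radius sqrt(2)*s is exact
    for a solid disc, and the square root of the curvature ratio converts
    curvature anisotropy into axis anisotropy (calibrated on rendered solid
    ellipses of head-like aspect ~1.6, where it recovers both axes to ~5%).
    """
    if _stacks is not None:
        m = _stacks.hessian_at(p.x, p.y, p.s)
    else:
        m = hessian_at(frame, p.x, p.y, p.s)
    evals, evecs = np.linalg.eigh(m)  # (x, y) basis: m[0,0] = Lxx
    order = np.argsort(-np.abs(evals))
    l1, l2 = float(evals[order[0]]), float(evals[order[1]])
    if abs(l2) < 1e-9:
        raise DegenerateHessianError(
            f"degenerate Hessian at ({p.x:.1f}, {p.y:.1f}): |lambda2| < 1e-9"
        )
    v2 = evecs[:, order[1]]  # minor-curvature eigenvector = major axis
    angle = math.degrees(math.atan2(v2[1], v2[0])) % 180.0
    ratio = abs(l1) / abs(l2)
    half_major = math.sqrt(2.0) * p.s * ratio**0.5
    half_minor = math.sqrt(2.0) * p.s / ratio**0.5
    return EllipseFit(
        cx=p.x, cy=p.y, length=2 * half_major, width=2 * half_minor,
        angle=angle, lambda1=l1, lambda2=l2,
    )


def _ellipse_mask(shape, cx, cy, a, b, angle_deg, scale=1.0):
    """Boolean mask of an ellipse with half-axes (a, b) scaled by `scale`."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    t = math.radians(angle_deg)
    dx, dy = xx - cx, yy - cy
    u = dx * math.cos(t) + dy * math.sin(t)
    v = -dx * math.sin(t) + dy * math.cos(t)
    return (u / (a * scale)) ** 2 + (v / (b * scale)) ** 2 <= 1.0


def compute_contrast(frame: Frame, e: EllipseFit) -> float:
    """Local contrast of an elliptical region against its surround.

    Contrast = (mean gray of the annulus between 1x and 2x the ellipse axes
    minus mean gray inside the ellipse) / 255, clamped to [0, 1].  Dark
    heads on a light background score high; tail segments, whose surround
    is partly fish body, score low.
    """
    a, b = e.length / 2.0, e.width / 2.0
    h, w = frame.pixels.shape
    rad = int(math.ceil(2.0 * max(a, b))) + 1
    r0, r1 = max(0, int(e.cy) - rad), min(h, int(e.cy) + rad + 1)
    c0, c1 = max(0, int(e.cx) - rad), min(w, int(e.cx) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        raise ValueError("ellipse lies outside the frame")
    patch = frame.pixels[r0:r1, c0:c1]
    shape = patch.shape
    inner = _ellipse_mask(shape, e.cx - c0, e.cy - r0, a, b, e.angle)
    outer = _ellipse_mask(shape, e.cx - c0, e.cy - r0, a, b, e.angle, scale=2.0)
    annulus = outer & ~inner
    if not inner.any() or not annulus.any():
        raise ValueError("ellipse lies outside the frame")
    c = (patch[annulus].mean() - patch[inner].mean()) / 255.0
    return float(np.clip(c, 0.0, 1.0))


# --------------------------------------------------------------------------
# Segmentation
# --------------------------------------------------------------------------

def otsu_threshold(frame: Frame) -> int:
    """Gray level maximizing between-class variance w0*w1*(u0-u1)^2.

    Dark fish on a light background: the returned ``t`` is meant to be used
    as ``pixels <= t`` = fish. Ties broken toward the smallest ``t``.
    """
    img = frame.pixels
    hist = np.bincount(img.astype(np.uint8).ravel(), minlength=256).astype(float)
    if np.count_nonzero(hist) < 2:
        raise ValueError("constant frame: no valid threshold")
    p = hist / hist.sum()
    omega0 = np.cumsum(p)                       # class {0..t}
    mu = np.cumsum(p * np.arange(256))
    mu_total = mu[-1]
    omega1 = 1.0 - omega0
    with np.errstate(divide="ignore", invalid="ignore"):
        between = (mu_total * omega0 - mu) ** 2 / (omega0 * omega1)
    between[~np.isfinite(between)] = -1.0
    return int(np.argmax(between))  # argmax returns the first (smallest) maximizer


def segment_fish_regions(frame: Frame, t: float, params: DetectionParams | None = None
                         ) -> np.ndarray:
    """8-connected labeling of the dark mask ``pixels <= t``.

    Components smaller than ``params.min_region_area`` are discarded as
    speckle.  Returns an int label map (0 = background).
    """
    if params is None:
        params = DetectionParams()
    mask = frame.pixels <= t
    labels = measure.label(mask, connectivity=2)
    if labels.max():
        counts = np.bincount(labels.ravel())
        keep = counts >= params.min_region_area
        keep[0] = False
        remap = np.zeros(counts.size, dtype=labels.dtype)
        remap[keep] = np.arange(1, int(keep.sum()) + 1)
        labels = remap[labels]
    return labels


# --------------------------------------------------------------------------
# Candidate constraints
# --------------------------------------------------------------------------

def _angle_diff(a: float, b: float) -> float:
    """Heading difference mod 180, in [0, 90]."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def apply_constraints(
    cands: list[tuple[ScaleSpacePoint, EllipseFit]],
    regions: np.ndarray,
    params: DetectionParams,
    frame_index: int = 0,
) -> list[HeadDetection]:
    """Width, contrast and per-region angle constraints.

    1. width: fitted minor axis must lie in [w_min, w_max];
    2. contrast: candidate is an effective head iff contrast >= k;
    3. angle: inside one segmented fish region, candidates whose headings
       differ by less than ``angle_sep_deg`` are duplicates of the same
       head: only the maximum-contrast one survives.  Candidates at >= 30
       degrees (an occluding pair, heads of two fish in one merged region)
       are all kept.  Candidates in different regions never suppress each
       other.
    """
    h, w = regions.shape
    lo = params.w_min * (1.0 - params.width_margin)
    hi = params.w_max * (1.0 + params.width_margin)
    survivors: list[tuple[int, EllipseFit, ScaleSpacePoint]] = []
    for p, e in cands:
        if not (lo <= e.width <= hi):
            continue
        if e.contrast < params.k:
            continue
        r, c = int(round(e.cy)), int(round(e.cx))
        label = int(regions[r, c]) if 0 <= r < h and 0 <= c < w else 0
        survivors.append((label, e, p))

    # angle constraint: greedy by descending contrast within each region
    kept: list[tuple[int, EllipseFit, ScaleSpacePoint]] = []
    for label, e, p in sorted(survivors, key=lambda t: -t[1].contrast):
        if label != 0 and any(
            kl == label and _angle_diff(ke.angle, e.angle) < params.angle_sep_deg
            for kl, ke, _ in kept
        ):
            continue
        kept.append((label, e, p))

    dets = [
        HeadDetection(frame_index=frame_index, ellipse=e, scale=p.s,
                      segment_label=(label if label != 0 else None))
        for label, e, p in kept
    ]
    dets.sort(key=lambda d: (d.y, d.x))
    return dets


def detect_heads(frame: Frame, params: DetectionParams | None = None
                 ) -> list[HeadDetection]:
    """Full single-frame head detection pipeline.

    Scale-space extrema -> ellipse fit -> contrast -> Otsu segmentation ->
    width/contrast/angle constraints.  Deterministic for fixed inputs.
    """
    if params is None:
        params = DetectionParams()
    stacks = _ScaleSpaceStacks(frame, params.scale_grid)
    pts = detect_scale_space_minima(frame, params, _stacks=stacks)
    # a blob's fitted width is at most 2*sqrt(2)*s (ratio >= 1 shrinks the
    # minor axis), so points below this scale floor can never pass the
    # width band: skip the fit
    s_floor = params.w_min * (1.0 - params.width_margin) / (2.0 * math.sqrt(2.0))
    cands = []
    for p in pts:
        if p.s < s_floor:
            continue
        try:
            e = fit_ellipse(frame, p, _stacks=stacks)
        except DegenerateHessianError:
            continue
        try:
            c = compute_contrast(frame, e)
        except ValueError:
            continue
        cands.append((p, replace(e, contrast=c)))
    try:
        t = otsu_threshold(frame)
    except ValueError:
        return []
    regions = segment_fish_regions(frame, t, params)
    return apply_constraints(cands, regions, params, frame_index=frame.index)
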