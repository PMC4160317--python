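"""Frame-to-frame association: Kalman prediction + cascade feature matching.

Each tracked fish carries a 4-state constant-velocity Kalman filter
(x, y, vx, vy).  Candidate detections for a track are gated by the
predicted position; when the gate is empty (burst motion the
constant-velocity model cannot follow) a *compensation window* takes over:
a quarter-circle around the last detection, radius equal to the head
ellipse's major axis, spanning +-45 degrees about the heading — the range
fish head motion stays within between consecutive frames at 30 fps.

Ambiguity inside the gate is resolved by appearance, not distance alone:
an active contour grown from the detected ellipse yields a *matching
region* (the head-side part of the body outline, cut perpendicular to the
head axis through the ellipse center), and two regions are compared by a
width / aligned-area / gray-histogram cascade with early rejection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure, segmentation

from .detection import Frame, HeadDetection

__all__ = [
    "KalmanState", "TrackingParams", "MatchingRegion", "Track",
    "CompensationWindow", "kalman_predict", "kalman_update",
    "compensation_window", "extract_matching_region", "match_features",
    "associate_frame", "Tracker",
]

_F = np.array([[1.0, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]])
_H = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])


@dataclass
class KalmanState:
    """Constant-velocity filter state: position, velocity, covariance."""

    x: float
    y: float
    vx: float = 0.0
    vy: float = 0.0
    P: np.ndarray = field(default_factory=lambda: 10.0 * np.eye(4))
    effective: bool = True  # an observation was associated this frame

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y])

    def vec(self) -> np.ndarray:
        return np.array([self.x, self.y, self.vx, self.vy])


@dataclass(frozen=True)
class TrackingParams:
    """Tracking-stage parameters.

    ``tau_w`` (px), ``tau_a`` (px^2) and ``tau_g`` are the cascade
    thresholds for the width, aligned-area and grayscale matching stages.
    ``q``/``r`` scale the process/observation noise; ``gate_radius`` of
    None means adaptive: 3 sigma of predicted positional uncertainty plus
    the track's head length.
    """

    dt: float = 1.0
    q: float = 1.0
    r: float = 1.0
    tau_w: float = 5.0
    tau_a: float = 50.0
    tau_g: float = 0.15
    gate_radius: float | None = None
    # iteration budget for the morphological active contour; from an
    # ellipse init covering most of the head it converges in ~15-20 sweeps,
    # and a tight budget also keeps the region from leaking along the body
    contour_iters: int = 20
    contour_smoothing: int = 1
    # ablation switch: disable the quarter-circle fallback search
    use_compensation: bool = True

    def __post_init__(self):
        if min(self.tau_w, self.tau_a, self.tau_g) <= 0:
            raise ValueError("thresholds must be positive")

    def F(self) -> np.ndarray:
        f = _F.copy()
        f[0, 2] = f[1, 3] = self.dt
        return f

    def Q(self) -> np.ndarray:
        return self.q * np.diag([0.25, 0.25, 1.0, 1.0])

    def R(self) -> np.ndarray:
        return self.r * np.eye(2)


# --------------------------------------------------------------------------
# Kalman filter
# --------------------------------------------------------------------------

def kalman_predict(state: KalmanState, params: TrackingParams) -> KalmanState:
    """Time update: x <- F x, P <- F P F' + Q."""
    f = params.F()
    xv = f @ state.vec()
    p = f @ state.P @ f.T + params.Q()
    return KalmanState(x=xv[0], y=xv[1], vx=xv[2], vy=xv[3], P=p,
                       effective=False)


def kalman_update(prior: KalmanState, z, params: TrackingParams) -> KalmanState:
    """Measurement update with observation z = (zx, zy).

    K = P H' (H P H' + R)^-1; as R -> 0 the posterior position snaps to z,
    as R -> inf the posterior equals the prior.
    """
    z = np.asarray(z, float)
    p = prior.P
    innov_cov = _H @ p @ _H.T + params.R()
    try:
        k = np.linalg.solve(innov_cov.T, (_H @ p.T)).T
    except np.linalg.LinAlgError as exc:
        raise ArithmeticError("singular innovation covariance") from exc
    xv = prior.vec() + k @ (z - _H @ prior.vec())
    p_post = (np.eye(4) - k @ _H) @ p
    return KalmanState(x=xv[0], y=xv[1], vx=xv[2], vy=xv[3], P=p_post,
                       effective=True)


# --------------------------------------------------------------------------
# Compensation window
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CompensationWindow:
    """Quarter-circle fallback search region.

    Centered at the last effective detection, radius = head major axis,
    spanning +-45 degrees about the heading.
    """

    cx: float
    cy: float
    radius: float
    heading_deg: float

    def contains(self, x: float, y: float) -> bool:
        dx, dy = x - self.cx, y - self.cy
        d = math.hypot(dx, dy)
        if d > self.radius:
            return False
        if d == 0:
            return True
        ang = math.degrees(math.atan2(dy, dx))
        diff = (ang - self.heading_deg + 180.0) % 360.0 - 180.0
        return abs(diff) <= 45.0


def compensation_window(det: HeadDetection,
                        heading_deg: float | None = None) -> CompensationWindow:
    """Build the fallback window from a track's last effective detection.

    ``heading_deg`` overrides the ellipse angle when the track has resolved
    the motion direction (the fitted angle is only defined mod 180).
    """
    return CompensationWindow(
        cx=det.x, cy=det.y, radius=det.length,
        heading_deg=det.angle if heading_deg is None else heading_deg,
    )


# --------------------------------------------------------------------------
# Matching region
# --------------------------------------------------------------------------

@dataclass
class MatchingRegion:
    """Head-side region of the fish outline used by cascade matching.

    Stored in frame coordinates: ``mask`` is a boolean patch with origin
    ``origin`` = (row0, col0); the alignment line runs from the ellipse
    center (inner endpoint) to the farthest contour point within +-15
    degrees of the heading (outer endpoint); the cutting line passes
    through the inner endpoint perpendicular to it.
    """

    mask: np.ndarray
    origin: tuple[int, int]
    inner_endpoint: tuple[float, float]
    outer_endpoint: tuple[float, float]
    cutting_points: tuple[tuple[float, float], tuple[float, float]]
    width: float
    area: float
    histogram: np.ndarray

    @property
    def alignment_angle(self) -> float:
        (x0, y0), (xa, ya) = self.inner_endpoint, self.outer_endpoint
        return math.degrees(math.atan2(ya - y0, xa - x0))


def extract_matching_region(
    frame: Frame,
    det: HeadDetection,
    params: TrackingParams | None = None,
    heading_deg: float | None = None,
) -> MatchingRegion:
    """Segment the head contour and cut out the matching region.

    A two-phase piecewise-constant active contour (morphological
    Chan-Vese), initialized from the detected ellipse and run for a fixed
    iteration budget on a local window, outlines the dark body.  The
    farthest contour point within heading +-15 degrees gives the outer
    endpoint; the cutting line through the ellipse center perpendicular to
    the alignment line bounds the head-side region, whose cutting-line
    width, area and 256-bin gray histogram are the matching features.

    Falls back to the plain ellipse mask if the contour collapses.
    """
    params = params or TrackingParams()
    theta = det.angle if heading_deg is None else heading_deg
    h, w = frame.pixels.shape
    rad = int(math.ceil(1.1 * det.length)) + 4
    r0, r1 = max(0, int(det.y) - rad), min(h, int(det.y) + rad + 1)
    c0, c1 = max(0, int(det.x) - rad), min(w, int(det.x) + rad + 1)
    if r0 >= r1 - 2 or c0 >= c1 - 2:
        raise ValueError("detection outside frame")
    patch = frame.pixels[r0:r1, c0:c1]
    cx, cy = det.x - c0, det.y - r0

    yy, xx = np.mgrid[0 : patch.shape[0], 0 : patch.shape[1]]
    t = math.radians(det.angle)
    u = (xx - cx) * math.cos(t) + (yy - cy) * math.sin(t)
    v = -(xx - cx) * math.sin(t) + (yy - cy) * math.cos(t)
    init = (u / (det.length / 2.0)) ** 2 + (v / (det.width / 2.0)) ** 2 <= 1.0

    # dark fish on light background: evolve on inverted gray
    ls = segmentation.morphological_chan_vese(
        (255.0 - patch) / 255.0,
        num_iter=params.contour_iters,
        init_level_set=init,
        smoothing=params.contour_smoothing,
    ).astype(bool)
    # keep the component containing the ellipse center
    lab = measure.label(ls, connectivity=2)
    center_label = lab[int(round(cy)), int(round(cx))]
    if center_label == 0 or (lab == center_label).sum() < 4:
        mask = init  # contour collapse: fall back to the ellipse
    else:
        mask = lab == center_label

    contour_pts = np.argwhere(mask ^ _erode(mask))  # boundary pixels (r, c)
    rel = contour_pts[:, ::-1].astype(float) - [cx, cy]
    dist = np.hypot(rel[:, 0], rel[:, 1])
    ang = np.degrees(np.arctan2(rel[:, 1], rel[:, 0]))

    def _sector_far(direction_deg: float) -> int | None:
        dang = np.abs((ang - direction_deg + 180.0) % 360.0 - 180.0)
        sector = dang <= 15.0
        if not sector.any():
            return None
        return int(np.argmax(np.where(sector, dist, -1.0)))

    if heading_deg is None:
        # the fitted angle is only defined mod 180; the head front is the
        # direction in which the body outline extends *less* far (the tail
        # side runs long)
        jf = _sector_far(theta)
        jb = _sector_far(theta + 180.0)
        if jf is None and jb is None:
            j = int(np.argmax(dist))
        elif jb is None:
            j = jf
        elif jf is None or dist[jb] < dist[jf]:
            j = jb
            theta = (theta + 180.0) % 360.0
        else:
            j = jf
    else:
        j = _sector_far(theta)
        if j is None:
            j = int(np.argmax(dist))
    th = math.radians(theta)
    fwd = np.array([math.cos(th), math.sin(th)])
    xa, ya = contour_pts[j, 1], contour_pts[j, 0]

    # head side = half-plane ahead of the cutting line (through the center,
    # perpendicular to the alignment line)
    axis = np.array([xa - cx, ya - cy], float)
    n = np.linalg.norm(axis)
    axis = axis / n if n > 0 else fwd
    side = (xx - cx) * axis[0] + (yy - cy) * axis[1] >= 0
    region = mask & side

    # cutting line through the center along the perpendicular direction:
    # walk both ways until leaving the mask
    perp = np.array([-axis[1], axis[0]])
    ends = []
    for sign in (1.0, -1.0):
        step = 0.0
        px, py = cx, cy
        while True:
            nx, ny = cx + sign * perp[0] * (step + 0.5), cy + sign * perp[1] * (step + 0.5)
            ir, ic = int(round(ny)), int(round(nx))
            if not (0 <= ir < mask.shape[0] and 0 <= ic < mask.shape[1]) or not mask[ir, ic]:
                break
            px, py, step = nx, ny, step + 0.5
        ends.append((px, py))
    (xb, yb), (xc_, yc_) = ends
    width = math.hypot(xb - xc_, yb - yc_)

    area = float(region.sum())
    if area < 4.0:
        region = init & side
        area = float(region.sum())
    vals = patch[region].astype(np.uint8)
    hist = np.bincount(vals, minlength=256).astype(float)
    # a few hundred pixels spread over 256 bins is sampling-noise
    # dominated; a small Gaussian blur over gray levels makes the
    # intersection distance stable without losing the mode structure
    hist = ndimage.gaussian_filter1d(hist, 2.0)
    hist /= max(hist.sum(), 1e-12)

    return MatchingRegion(
        mask=region,
        origin=(r0, c0),
        inner_endpoint=(det.x, det.y),
        outer_endpoint=(xa + c0, ya + r0),
        cutting_points=((xb + c0, yb + r0), (xc_ + c0, yc_ + r0)),
        width=width,
        area=area,
        histogram=hist,
    )


def _erode(mask: np.ndarray) -> np.ndarray:
    out = mask.copy()
    out[1:] &= mask[:-1]
    out[:-1] &= mask[1:]
    out[:, 1:] &= mask[:, :-1]
    out[:, :-1] &= mask[:, 1:]
    return out


# --------------------------------------------------------------------------
# Cascade feature matching
# --------------------------------------------------------------------------

def _aligned_symmetric_difference(a: MatchingRegion, b: MatchingRegion) -> float:
    """Area of the symmetric difference after rigidly aligning b onto a.

    b's alignment line (inner -> outer endpoint) is rotated and translated
    onto a's and the mask is warped with subpixel (bilinear)
    interpolation; the statistic is the summed absolute difference of the
    soft masks, minimized over a +-1 px jitter of the endpoint — the
    endpoint itself is only pixel-accurate and the comparison should
    measure shape, not quantization.
    """
    rot = math.radians(a.alignment_angle - b.alignment_angle)
    cosr, sinr = math.cos(rot), math.sin(rot)
    # inverse map (a-patch coords -> b-patch coords) in (y, x) order
    m_inv = np.array([[cosr, -sinr], [sinr, cosr]])
    a_c = np.array([a.inner_endpoint[1] - a.origin[0],
                    a.inner_endpoint[0] - a.origin[1]])
    b_c = np.array([b.inner_endpoint[1] - b.origin[0],
                    b.inner_endpoint[0] - b.origin[1]])
    a_f = a.mask.astype(float)
    b_f = b.mask.astype(float)
    best = math.inf
    for dy in (-1.0, 0.0, 1.0):
        for dx in (-1.0, 0.0, 1.0):
            offset = m_inv @ (-a_c) + b_c + np.array([dy, dx])
            warped = ndimage.affine_transform(
                b_f, m_inv, offset=offset, output_shape=a_f.shape,
                order=1, mode="constant", cval=0.0,
            )
            diff = float(np.abs(a_f - warped).sum())
            if diff < best:
                best = diff
    return best


def match_features(a: MatchingRegion, b: MatchingRegion,
                   params: TrackingParams) -> tuple[bool, float]:
    """Cascade width / area / grayscale test of two matching regions.

    1. width:  |width_a - width_b|            <= tau_w
    2. area:   aligned symmetric difference   <= tau_a
    3. gray:   1 - histogram intersection     <= tau_g

    Early exit on the first failing stage (score = inf).  On success the
    score is the mean of the three threshold-normalized statistics; smaller
    is better, 0 for identical regions.
    """
    dw = abs(a.width - b.width)
    if dw > params.tau_w:
        return False, math.inf
    da = _aligned_symmetric_difference(a, b)
    if da > params.tau_a:
        return False, math.inf
    dg = 1.0 - float(np.minimum(a.histogram, b.histogram).sum())
    if dg > params.tau_g:
        return False, math.inf
    score = (dw / params.tau_w + da / params.tau_a + dg / params.tau_g) / 3.0
    return True, score


# --------------------------------------------------------------------------
# Tracks and per-frame association
# --------------------------------------------------------------------------

@dataclass
class Track:
    """One fish's state history and associated detections."""

    id: int
    states: dict[int, KalmanState] = field(default_factory=dict)
    detections: dict[int, HeadDetection | None] = field(default_factory=dict)
    region: MatchingRegion | None = None       # latest cached matching region
    start_region: MatchingRegion | None = None
    status: str = "active"                     # active | incomplete | terminated
    miss_count: int = 0
    start_tag: tuple[int, tuple[float, float]] | None = None
    end_tag: tuple[int, tuple[float, float]] | None = None
    heading: float | None = None               # motion-disambiguated, deg

    @property
    def frames(self) -> list[int]:
        return sorted(self.states)

    @property
    def last_frame(self) -> int:
        return max(self.states)

    def last_detection(self) -> HeadDetection | None:
        for t in sorted(self.detections, reverse=True):
            if self.detections[t] is not None:
                return self.detections[t]
        return None

    def resolved_heading(self) -> float:
        """Heading (deg) with the mod-180 ambiguity of the ellipse angle
        resolved by the velocity direction when the track is moving."""
        det = self.last_detection()
        ang = det.angle if det is not None else 0.0
        st = self.states[self.last_frame]
        if math.hypot(st.vx, st.vy) > 0.5:
            vel_ang = math.degrees(math.atan2(st.vy, st.vx))
            if abs((ang - vel_ang + 180.0) % 360.0 - 180.0) > 90.0:
                ang = (ang + 180.0) % 360.0
        elif self.heading is not None:
            if abs((ang - self.heading + 180.0) % 360.0 - 180.0) > 90.0:
                ang = (ang + 180.0) % 360.0
        return ang


def _gate_radius(track: Track, prior: KalmanState,
                 params: TrackingParams) -> float:
    if params.gate_radius is not None:
        return params.gate_radius
    det = track.last_detection()
    head_len = det.length if det is not None else 30.0
    return 3.0 * math.sqrt(prior.P[0, 0] + prior.P[1, 1]) + head_len


@dataclass
class Assignment:
    """Result of one frame of data association."""

    pairs: dict[int, int]          # track id -> detection index
    unmatched_tracks: list[int]
    unmatched_detections: list[int]


def associate_frame(
    tracks: list[Track],
    dets: list[HeadDetection],
    frame: Frame,
    params: TrackingParams,
    priors: dict[int, KalmanState] | None = None,
    det_regions: list[MatchingRegion] | None = None,
) -> Assignment:
    """Associate current-frame detections with active tracks.

    Candidates per track are the detections inside the Kalman gate; if the
    gate is empty (or nothing in it passes the feature cascade), the
    quarter-circle compensation window around the last effective detection
    is searched instead.  Track-candidate pairs are scored by cascade
    feature matching against the track's cached matching region, and
    conflicts are resolved globally: passing pairs are accepted greedily by
    ascending score, one-to-one.

    A track that has been coasting adds a small score penalty per
    consecutive miss: its cached appearance is stale, so on a near-tie a
    freshly observed track wins the contested detection.  Without this a
    coasting track and its replacement can alternate stealing one fish's
    detection indefinitely, which both keeps the duplicate alive and
    prevents the fragments from ever linking.
    """
    if priors is None:
        priors = {tr.id: kalman_predict(tr.states[tr.last_frame], params)
                  for tr in tracks}
    if det_regions is None:
        det_regions = [extract_matching_region(frame, d, params) for d in dets]

    scored: list[tuple[float, int, int]] = []
    for tr in tracks:
        prior = priors[tr.id]
        gate = _gate_radius(tr, prior, params)
        in_gate = [
            j for j, d in enumerate(dets)
            if math.hypot(d.x - prior.x, d.y - prior.y) <= gate
        ]
        cand = in_gate
        passing: list[tuple[float, int]] = []
        for j in cand:
            ok, score = _score_pair(tr, det_regions[j], params)
            if ok:
                passing.append((score, j))
        if not passing and params.use_compensation:
            last = tr.last_detection()
            if last is not None:
                win = compensation_window(last, tr.resolved_heading())
                for j, d in enumerate(dets):
                    if j in in_gate or not win.contains(d.x, d.y):
                        continue
                    ok, score = _score_pair(tr, det_regions[j], params)
                    if ok:
                        passing.append((score, j))
        stale = 0.02 * tr.miss_count
        for score, j in passing:
            scored.append((score + stale, tr.id, j))

    scored.sort()
    used_tracks: set[int] = set()
    used_dets: set[int] = set()
    pairs: dict[int, int] = {}
    for score, tid, j in scored:
        if tid in used_tracks or j in used_dets:
            continue
        pairs[tid] = j
        used_tracks.add(tid)
        used_dets.add(j)
    return Assignment(
        pairs=pairs,
        unmatched_tracks=[tr.id for tr in tracks if tr.id not in used_tracks],
        unmatched_detections=[j for j in range(len(dets)) if j not in used_dets],
    )


def _score_pair(track: Track, region: MatchingRegion,
                params: TrackingParams) -> tuple[bool, float]:
    if track.region is None:
        return True, 0.5  # no appearance yet: accept on gate alone
    return match_features(track.region, region, params)


class Tracker:
    """Stateful first-pass tracker: detection streams in, tracks come out.

    Lifecycle (miss counting, incomplete marking, track spawning) is
    delegated to :mod:`fishtrack.linking`.
    """

    def __init__(self, params: TrackingParams | None = None,
                 linking_params=None):
        from .linking import LinkingParams
        self.params = params or TrackingParams()
        self.link_params = linking_params or LinkingParams()
        self.active: list[Track] = []
        self.finished: list[Track] = []
        self._next_id = 0

    def step(self, frame: Frame, dets: list[HeadDetection]) -> None:
        from .linking import update_lifecycle

        params = self.params
        priors = {tr.id: kalman_predict(tr.states[tr.last_frame], params)
                  for tr in self.active}
        det_regions = [extract_matching_region(frame, d, params) for d in dets]
        asg = associate_frame(self.active, dets, frame, params,
                              priors=priors, det_regions=det_regions)

        t = frame.index
        still_active: list[Track] = []
        for tr in self.active:
            prior = priors[tr.id]
            if tr.id in asg.pairs:
                j = asg.pairs[tr.id]
                d = dets[j]
                post = kalman_update(prior, (d.x, d.y), params)
                tr.states[t] = post
                tr.detections[t] = d
                tr.region = det_regions[j]
                tr.heading = tr.resolved_heading()
                update_lifecycle(tr, "associated", self.link_params)
            else:
                tr.states[t] = prior
                tr.detections[t] = None
                update_lifecycle(tr, "missed", self.link_params)
            if tr.status == "active":
                still_active.append(tr)
            else:
                self.finished.append(tr)
        self.active = still_active

        for j in asg.unmatched_detections:
            d = dets[j]
            tr = Track(id=self._next_id)
            self._next_id += 1
            tr.states[t] = KalmanState(x=d.x, y=d.y)
            tr.detections[t] = d
            tr.region = det_regions[j]
            tr.start_region = det_regions[j]
            tr.start_tag = (t, (d.x, d.y))
            self.active.append(tr)

    def run(self, frames, detections_per_frame) -> list[Track]:
        """Run over an iterable of frames with per-frame detection lists."""
        for frame, dets in zip(frames, detections_per_frame):
            self.step(frame, dets)
        return self.tracks()

    def tracks(self) -> list[Track]:
        out = self.finished + self.active
        out.sort(key=lambda tr: tr.id)
        return out
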