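"""Seeded synthetic top-view fish-school video with per-frame ground truth.

Emulates the laboratory imaging conditions the tracker is designed for: a
light, slightly noisy background (tank bottom plus suspended matter) seen
from directly above, with each fish appearing as a rigid dark elliptical
head and a deformable tapering tail that swings as it swims.  Motion mixes
smooth mean-reverting heading changes, cruise-speed fluctuation and
occasional burst-glide events; walls reflect specularly.

All randomness flows from one explicit seed; identical seeds and parameters
give bit-identical frames and truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .detection import Frame

TRUTH_COLUMNS = ["frame", "id", "x", "y", "angle", "occluded", "head_visible"]


@dataclass(frozen=True)
class FishModel:
    """Appearance of one fish.

    ``head_width``/``head_length`` are the full minor/major axes of the dark
    head ellipse in px; ``head_intensity`` its gray level (background is
    ~200).  The tail is a tapering polyline of length ``body_length`` whose
    lateral bend oscillates with amplitude ``tail_amp`` degrees at
    ``tail_freq`` Hz.
    """

    head_width: float = 20.0
    head_length: float = 32.0
    head_intensity: float = 60.0
    body_length: float = 64.0
    tail_amp: float = 25.0
    tail_freq: float = 2.0
    tail_intensity: float = 110.0

    def __post_init__(self):
        if not self.head_width < self.head_length:
            raise ValueError("head must be longer than wide")


@dataclass(frozen=True)
class MotionParams:
    """Kinematics of the simulated school.

    Speeds are px/frame at ``fps`` = 30.  ``heading_reversion`` is the
    per-frame decay of angular velocity toward zero and ``heading_noise``
    the per-frame std-dev (deg) of its Gaussian perturbation — together they
    produce smooth turning whose per-frame heading change stays within
    +-45 degrees for >= 99% of frames.  Bursts multiply speed by
    ``burst_gain`` with probability ``burst_prob`` per frame, decaying back
    to cruise (glide).  ``separation_radius`` > 0 adds gentle
    collision-avoidance steering (used for no-occlusion variants).
    """

    speed_mean: float = 3.0
    speed_sd: float = 0.8
    heading_reversion: float = 0.25
    heading_noise: float = 3.0
    burst_prob: float = 0.01
    burst_gain: float = 3.0
    arena: int = 1024
    wall_margin: float = 60.0
    fps: float = 30.0
    separation_radius: float = 0.0
    # > 0 enforces a hard minimum pairwise center distance (positions are
    # projected apart when a step would violate it).  115 px exceeds the
    # largest head-center-to-tail-tip reach plus a head radius, so body
    # masks can never touch another head: occlusion-free by construction.
    hard_min_distance: float = 0.0

    def __post_init__(self):
        if self.speed_mean < 0 or self.speed_sd < 0:
            raise ValueError("speeds must be non-negative")


@dataclass(frozen=True)
class NoiseParams:
    """Background/imaging noise: Gaussian sensor noise, dark speckle on the
    tank bottom, and slowly drifting suspended particles."""

    background: float = 200.0
    gauss_sd: float = 5.0
    speckle_density: float = 3e-5   # dark dots per px^2
    speckle_radius: float = 2.0
    speckle_depth: float = 60.0     # gray levels below background
    n_particles: int = 0
    particle_depth: float = 40.0


@dataclass
class SceneTruth:
    """Ground truth for a simulated scene.

    ``df`` has one row per (frame, fish): columns ``frame, id, x, y, angle``
    (head center px, heading deg in [0, 360)), plus ``occluded`` (another
    fish's body mask touches this head) and ``head_visible`` (>= 50% of the
    head's pixels are not covered), both computed from rendered masks.
    ``tail_phase`` drives the tail swing during rendering.
    """

    df: pd.DataFrame
    fish: list[FishModel]
    motion: MotionParams
    noise: NoiseParams
    seed: int

    @property
    def n_frames(self) -> int:
        return int(self.df["frame"].max()) + 1 if len(self.df) else 0

    @property
    def n_fish(self) -> int:
        return len(self.fish)


def _rng_for(seed: int, stream: str, t: int = 0) -> np.random.Generator:
    # stable across processes (unlike hash()): sum of stream bytes
    tag = int.from_bytes(stream.encode()[:8].ljust(8, b"\0"), "little") & 0x7FFFFFFF
    ss = np.random.SeedSequence([seed & 0x7FFFFFFF, tag, t])
    return np.random.default_rng(ss)


def default_fish(n: int, seed: int) -> list[FishModel]:
    """n fish with head widths drawn uniformly from [16, 24] px and
    correlated lengths (aspect ~1.6), emulating 2-3 cm zebrafish."""
    rng = _rng_for(seed, "fish")
    out = []
    for _ in range(n):
        w = float(rng.uniform(16.0, 24.0))
        out.append(
            FishModel(
                head_width=w,
                head_length=1.6 * w,
                head_intensity=float(rng.uniform(50.0, 75.0)),
                body_length=3.2 * w,
                tail_amp=float(rng.uniform(18.0, 30.0)),
                tail_freq=float(rng.uniform(1.5, 3.0)),
            )
        )
    return out


# --------------------------------------------------------------------------
# Kinematics
# --------------------------------------------------------------------------

def simulate_school(
    n_fish: int,
    n_frames: int,
    motion: MotionParams | None = None,
    seed: int = 0,
    fish: list[FishModel] | None = None,
    noise: NoiseParams | None = None,
    annotate: bool = True,
) -> SceneTruth:
    """Simulate ``n_fish`` trajectories over ``n_frames`` frames.

    Headings follow a mean-reverting angular-velocity process; speed mixes
    an Ornstein-Uhlenbeck cruise component with multiplicative burst-glide
    events; walls reflect specularly inside ``wall_margin``.  Deterministic
    for a given seed.  If ``annotate``, occlusion flags are computed from
    rendered per-fish masks.
    """
    if n_fish < 1 or n_frames < 2:
        raise ValueError("need n_fish >= 1 and n_frames >= 2")
    motion = motion or MotionParams()
    noise = noise or NoiseParams()
    fish = fish if fish is not None else default_fish(n_fish, seed)
    if len(fish) != n_fish:
        raise ValueError("len(fish) must equal n_fish")
    rng = _rng_for(seed, "motion")

    lo = motion.wall_margin
    hi = motion.arena - motion.wall_margin
    x = rng.uniform(lo, hi, n_fish)
    y = rng.uniform(lo, hi, n_fish)
    if motion.hard_min_distance > 0:
        # rejection-sample starting positions respecting the hard distance
        for i in range(1, n_fish):
            for _ in range(1000):
                if np.hypot(x[:i] - x[i], y[:i] - y[i]).min() \
                        >= motion.hard_min_distance:
                    break
                x[i] = rng.uniform(lo, hi)
                y[i] = rng.uniform(lo, hi)
    heading = rng.uniform(0.0, 360.0, n_fish)
    omega = np.zeros(n_fish)                      # deg/frame
    speed = np.full(n_fish, motion.speed_mean)
    burst = np.ones(n_fish)                       # multiplicative burst state
    phase = rng.uniform(0.0, 2 * math.pi, n_fish)

    rows = []
    for t in range(n_frames):
        for i in range(n_fish):
            rows.append((t, i, x[i], y[i], heading[i] % 360.0, phase[i]))
        # angular velocity: mean-reverting with Gaussian kicks, hard-capped
        omega = (1.0 - motion.heading_reversion) * omega + \
            motion.heading_noise * rng.standard_normal(n_fish)
        np.clip(omega, -40.0, 40.0, out=omega)
        # collision avoidance: steer away from every too-close neighbor,
        # harder the closer it is
        if motion.separation_radius > 0 and n_fish > 1:
            for i in range(n_fish):
                dx, dy = x - x[i], y - y[i]
                d = np.hypot(dx, dy)
                d[i] = np.inf
                for j in np.nonzero(d < motion.separation_radius)[0]:
                    away = math.degrees(math.atan2(y[i] - y[j], x[i] - x[j]))
                    diff = (away - heading[i] + 180.0) % 360.0 - 180.0
                    w = (1.0 - d[j] / motion.separation_radius) ** 2
                    omega[i] += np.clip(diff, -40.0, 40.0) * min(1.0, 2.5 * w)
        heading = heading + np.clip(omega, -44.0, 44.0)
        # burst-glide: multiplicative spike decaying back to 1
        kick = rng.random(n_fish) < motion.burst_prob
        burst = np.where(kick, motion.burst_gain, 1.0 + (burst - 1.0) * 0.85)
        speed = speed + 0.3 * (motion.speed_mean - speed) + \
            motion.speed_sd * rng.standard_normal(n_fish)
        np.clip(speed, 0.3, motion.speed_mean * 4.0, out=speed)
        v = speed * burst
        x = x + v * np.cos(np.radians(heading))
        y = y + v * np.sin(np.radians(heading))
        # specular wall reflection: fold position back, mirror heading
        hit_x = (x > hi) | (x < lo)
        hit_y = (y > hi) | (y < lo)
        x = np.where(x > hi, 2 * hi - x, np.where(x < lo, 2 * lo - x, x))
        y = np.where(y > hi, 2 * hi - y, np.where(y < lo, 2 * lo - y, y))
        heading = np.where(hit_x, 180.0 - heading, heading)
        heading = np.where(hit_y, -heading, heading)
        np.clip(x, lo, hi, out=x)
        np.clip(y, lo, hi, out=y)
        if motion.hard_min_distance > 0 and n_fish > 1:
            # fish give way: project violating pairs apart
            for _ in range(3):
                moved = False
                for i in range(n_fish):
                    for j in range(i + 1, n_fish):
                        ddx, ddy = x[j] - x[i], y[j] - y[i]
                        d = math.hypot(ddx, ddy)
                        if d >= motion.hard_min_distance:
                            continue
                        if d < 1e-9:
                            ddx, ddy, d = 1.0, 0.0, 1.0
                        push = (motion.hard_min_distance - d) / (2.0 * d)
                        x[i] -= ddx * push
                        y[i] -= ddy * push
                        x[j] += ddx * push
                        y[j] += ddy * push
                        moved = True
                if not moved:
                    break
            np.clip(x, lo, hi, out=x)
            np.clip(y, lo, hi, out=y)
        phase = phase + 2 * math.pi * np.array([f.tail_freq for f in fish]) / motion.fps

    df = pd.DataFrame(rows, columns=["frame", "id", "x", "y", "angle", "tail_phase"])
    scene = SceneTruth(df=df, fish=fish, motion=motion, noise=noise, seed=seed)
    if annotate:
        annotate_occlusion(scene)
    return scene


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _fish_masks(scene: SceneTruth, t: int):
    """Per-fish (full-body mask, head mask) boolean arrays for frame t."""
    sub = scene.df[scene.df["frame"] == t]
    size = scene.motion.arena
    out = []
    for _, row in sub.iterrows():
        fm = scene.fish[int(row["id"])]
        body, head, _ = _rasterize_fish(
            size, row["x"], row["y"], row["angle"], row["tail_phase"], fm
        )
        out.append((int(row["id"]), body, head))
    return out


def _rasterize_fish(size, x, y, heading_deg, phase, fm: FishModel):
    """Rasterize one fish onto a full-size gray canvas.

    Returns (body_mask, head_mask, gray) where gray is +inf outside the
    fish.  The head is a solid ellipse; the tail a chain of shrinking discs
    along a centerline that bends with the tail phase.
    """
    th = math.radians(heading_deg)
    gray = np.full((size, size), np.inf)
    head_mask = np.zeros((size, size), bool)
    body_mask = np.zeros((size, size), bool)

    a, b = fm.head_length / 2.0, fm.head_width / 2.0
    _paint_ellipse(gray, head_mask, x, y, a, b, th, fm.head_intensity)

    # tail: discs from the head rear toward the back, bending sinusoidally
    n_seg = 9
    bend = math.radians(fm.tail_amp) * math.sin(phase)
    px, py = x - 0.6 * a * math.cos(th), y - 0.6 * a * math.sin(th)
    direc = th + math.pi  # pointing backwards
    seg_len = fm.body_length / n_seg
    for j in range(n_seg):
        frac = (j + 1) / n_seg
        direc += bend * 0.35 * frac
        px += seg_len * math.cos(direc)
        py += seg_len * math.sin(direc)
        r = max(1.2, b * (1.0 - 0.85 * frac))
        inten = fm.tail_intensity + (180.0 - fm.tail_intensity) * frac * 0.4
        _paint_ellipse(gray, body_mask, px, py, r, r, 0.0, inten)

    body_mask |= head_mask
    return body_mask, head_mask, gray


def _paint_ellipse(gray, mask, x, y, a, b, theta, intensity):
    size = gray.shape[0]
    rad = int(math.ceil(max(a, b))) + 2
    r0, r1 = max(0, int(y) - rad), min(size, int(y) + rad + 1)
    c0, c1 = max(0, int(x) - rad), min(size, int(x) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx, dy = xx - x, yy - y
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    sub = gray[r0:r1, c0:c1]
    sub[inside] = np.minimum(sub[inside], intensity)
    mask[r0:r1, c0:c1] |= inside


def render_frame(scene: SceneTruth, t: int) -> Frame:
    """Render frame ``t`` of a scene to an 8-bit grayscale Frame.

    Light noisy background; fish composited by the darkest-pixel rule
    (overlap shows whichever body is darker); 1 px blur stands in for
    optical softness.  Deterministic: noise is seeded per (seed, frame).
    """
    size = scene.motion.arena
    noise = scene.noise
    rng = _rng_for(scene.seed, "render", t)
    img = noise.background + noise.gauss_sd * rng.standard_normal((size, size))

    # static speckle on the tank bottom (same seed for all frames)
    srng = _rng_for(scene.seed, "speckle")
    n_spk = int(noise.speckle_density * size * size)
    spk_xy = srng.uniform(0, size, (n_spk, 2))
    spk_r = srng.uniform(1.0, noise.speckle_radius, n_spk)

    fish_gray = np.full((size, size), np.inf)
    sub = scene.df[scene.df["frame"] == t]
    for _, row in sub.iterrows():
        fm = scene.fish[int(row["id"])]
        _, _, g = _rasterize_fish(size, row["x"], row["y"], row["angle"],
                                  row["tail_phase"], fm)
        fish_gray = np.minimum(fish_gray, g)

    for (sx, sy), r in zip(spk_xy, spk_r):
        rr = int(math.ceil(r))
        r0, r1 = max(0, int(sy) - rr), min(size, int(sy) + rr + 1)
        c0, c1 = max(0, int(sx) - rr), min(size, int(sx) + rr + 1)
        if r0 >= r1 or c0 >= c1:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        inside = (xx - sx) ** 2 + (yy - sy) ** 2 <= r * r
        img[r0:r1, c0:c1][inside] = noise.background - noise.speckle_depth

    # drifting suspended particles
    if noise.n_particles:
        prng = _rng_for(scene.seed, "particles")
        p0 = prng.uniform(0, size, (noise.n_particles, 2))
        vel = prng.uniform(-0.5, 0.5, (noise.n_particles, 2))
        pos = (p0 + vel * t) % size
        for px, py in pos:
            r0, r1 = max(0, int(py) - 1), min(size, int(py) + 2)
            c0, c1 = max(0, int(px) - 1), min(size, int(px) + 2)
            img[r0:r1, c0:c1] = noise.background - noise.particle_depth

    img = np.where(np.isfinite(fish_gray), np.minimum(img, fish_gray), img)
    img = ndimage.gaussian_filter(img, 1.0)
    return Frame(np.clip(np.round(img), 0, 255), index=t)


def render_video(scene: SceneTruth):
    """Yield all frames of a scene in order."""
    for t in range(scene.n_frames):
        yield render_frame(scene, t)


def annotate_occlusion(scene: SceneTruth) -> None:
    """Set ``occluded``/``head_visible`` flags from rendered per-fish masks.

    A fish is occluded at t when any other fish's body mask overlaps its
    head mask; its head is visible when >= 50% of head pixels are
    uncovered.
    """
    occ = np.zeros(len(scene.df), bool)
    vis = np.ones(len(scene.df), bool)
    idx_of = {(int(r.frame), int(r.id)): i
              for i, r in enumerate(scene.df.itertuples(index=False))}
    for t in range(scene.n_frames):
        masks = _fish_masks(scene, t)
        for fid, _, head in masks:
            others = np.zeros_like(head)
            for gid, body, _ in masks:
                if gid != fid:
                    others |= body
            inter = int((head & others).sum())
            i = idx_of[(t, fid)]
            if inter > 0:
                occ[i] = True
                vis[i] = inter < 0.5 * int(head.sum())
    scene.df["occluded"] = occ
    scene.df["head_visible"] = vis


# --------------------------------------------------------------------------
# Scripted occlusion / dropout fixtures
# --------------------------------------------------------------------------

def make_occlusion_fixture(kind: str, seed: int = 0, gap: int = 5,
                           arena: int = 256):
    """Scripted two-fish scenarios for occlusion and fragmentation tests.

    kind = 'tail_cross': two fish pass so their tails/bodies merge into one
    dark region while both heads stay visible, headings > 30 deg apart.
    kind = 'head_cover': fish B's body covers fish A's head for ``gap``
    frames mid-sequence.
    kind = 'dropout': plain well-separated crossing; callers delete
    detections in ``scene.dropout_window`` (attached attribute) to force
    fragmentation.

    Returns a SceneTruth (render with :func:`render_frame`).
    """
    if kind not in {"tail_cross", "head_cover", "dropout"}:
        raise ValueError(f"unknown fixture kind {kind!r}")
    rng = _rng_for(seed, kind)
    motion = MotionParams(arena=arena, wall_margin=20.0)
    noise = NoiseParams(speckle_density=0.0, gauss_sd=3.0)
    f1 = FishModel(head_width=22.0, head_length=35.0, head_intensity=55.0,
                   body_length=70.0)
    f2 = FishModel(head_width=17.0, head_length=27.0, head_intensity=65.0,
                   body_length=55.0)
    n_frames = 60
    c = arena / 2.0
    rows = []

    if kind == "tail_cross":
        # fish 1 swims east along y=c-13; fish 2 swims north-east at 60 deg,
        # timed so fish 2's head passes just behind fish 1's head: bodies
        # merge, heads stay clear.
        for t in range(n_frames):
            x1, y1 = 30.0 + 3.0 * t, c - 13.0
            rows.append((t, 0, x1, y1, 0.0, 0.0))
            x2 = c - 35.0 + 2.0 * (t - 2)
            y2 = c + 70.0 - 3.4 * (t - 2)
            rows.append((t, 1, x2, y2, 300.0, math.pi / 2))
    elif kind == "head_cover":
        # fish 1 heads east; fish 2 crosses over its head mid-sequence
        t_mid = n_frames // 2
        for t in range(n_frames):
            x1, y1 = 30.0 + 2.5 * t, c
            rows.append((t, 0, x1, y1, 0.0, 0.0))
            # fish 2 rides on top of fish 1's head during the gap window
            if t_mid <= t < t_mid + gap:
                x2, y2 = x1 + 2.0, y1 + 1.0
                ang2 = 90.0
            else:
                x2 = c + 60.0
                y2 = 40.0 + 3.0 * t
                ang2 = 90.0
            rows.append((t, 1, x2, y2, ang2, 0.0))
    else:  # dropout
        for t in range(n_frames):
            rows.append((t, 0, 30.0 + 3.0 * t, c - 60.0, 0.0, 0.0))
            rows.append((t, 1, arena - 30.0 - 3.0 * t, c + 60.0, 180.0, 0.0))

    df = pd.DataFrame(rows, columns=["frame", "id", "x", "y", "angle", "tail_phase"])
    scene = SceneTruth(df=df, fish=[f1, f2], motion=motion, noise=noise, seed=seed)
    annotate_occlusion(scene)
    if kind == "dropout":
        t_mid = n_frames // 2
        scene.dropout_window = (t_mid, t_mid + gap)  # type: ignore[attr-defined]
    return scene
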