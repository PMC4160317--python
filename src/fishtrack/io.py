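"""Frame readers, CSV trajectory formats and flat key=value configuration."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .detection import DetectionParams, Frame, HeadDetection, EllipseFit
from .linking import LinkingParams
from .tracking import Track, TrackingParams

IMAGE_EXTS = {".png", ".tif", ".tiff", ".bmp", ".jpg", ".jpeg"}

DETECTIONS_COLUMNS = ["frame", "x", "y", "length", "width", "angle",
                      "contrast", "scale"]
TRACKS_COLUMNS = ["frame", "track_id", "x", "y", "vx", "vy", "angle",
                  "associated"]
TRAJECTORIES_COLUMNS = ["frame", "traj_id", "x", "y", "angle", "interpolated"]


# --------------------------------------------------------------------------
# Frames
# --------------------------------------------------------------------------

def _to_gray8(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        img = img[..., :3].astype(float) @ np.array([0.299, 0.587, 0.114])
    img = np.asarray(img)
    if img.dtype == np.uint8:
        return img.astype(float)
    if np.issubdtype(img.dtype, np.integer):
        info = np.iinfo(img.dtype)
        return img.astype(float) * (255.0 / info.max)
    # float input assumed already on a 0-255 or 0-1 scale
    img = img.astype(float)
    if img.max() <= 1.0:
        img = img * 255.0
    return np.clip(img, 0, 255)


def read_frames(source: str | Path):
    """Yield Frames from an image-sequence directory or a video file.

    Directory frames are taken in lexicographic name order and converted
    to 8-bit grayscale; 16-bit input is rescaled so full range maps to
    255.  Mixed resolutions are an error.
    """
    source = Path(source)
    if source.is_dir():
        files = sorted(p for p in source.iterdir()
                       if p.suffix.lower() in IMAGE_EXTS)
        if not files:
            raise IOError(f"no image files found in {source}")
        shape = None
        for i, p in enumerate(files):
            img = _to_gray8(iio.imread(p))
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise IOError(f"mixed frame resolutions: {p.name} is "
                              f"{img.shape}, expected {shape}")
            yield Frame(img, index=i)
    elif source.exists():
        try:
            it = iio.imiter(source)
        except Exception as exc:  # container/codec problems
            raise IOError(f"cannot read video {source}: {exc}") from exc
        shape = None
        for i, img in enumerate(it):
            img = _to_gray8(np.asarray(img))
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise IOError("mixed frame resolutions in video stream")
            yield Frame(img, index=i)
    else:
        raise IOError(f"frame source {source} does not exist")


def write_frames(frames, out_dir: str | Path) -> int:
    """Write frames as zero-padded PNGs; returns the count."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = 0
    for f in frames:
        iio.imwrite(out_dir / f"frame_{f.index:06d}.png",
                    f.pixels.astype(np.uint8))
        n += 1
    return n


# --------------------------------------------------------------------------
# CSV formats
# --------------------------------------------------------------------------

def detections_to_df(dets: list[HeadDetection]) -> pd.DataFrame:
    rows = [
        (d.frame_index, d.x, d.y, d.length, d.width, d.angle,
         d.ellipse.contrast, d.scale)
        for d in dets
    ]
    return pd.DataFrame(rows, columns=DETECTIONS_COLUMNS)


def write_detections(dets: list[HeadDetection] | pd.DataFrame,
                     path: str | Path) -> None:
    df = dets if isinstance(dets, pd.DataFrame) else detections_to_df(dets)
    df.to_csv(path, index=False, float_format="%.4f")


def read_detections(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(DETECTIONS_COLUMNS) - set(df.columns)
    if missing:
        raise IOError(f"detections file {path} lacks columns {sorted(missing)}")
    return df


def detections_from_df(df: pd.DataFrame) -> dict[int, list[HeadDetection]]:
    """Group a detections table into per-frame HeadDetection lists."""
    out: dict[int, list[HeadDetection]] = {}
    for r in df.itertuples(index=False):
        e = EllipseFit(cx=r.x, cy=r.y, length=r.length, width=r.width,
                       angle=r.angle, lambda1=-1.0, lambda2=-1.0,
                       contrast=r.contrast)
        out.setdefault(int(r.frame), []).append(
            HeadDetection(frame_index=int(r.frame), ellipse=e, scale=r.scale)
        )
    return out


def tracks_to_df(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for t in tr.frames:
            st = tr.states[t]
            det = tr.detections.get(t)
            ang = det.angle if det is not None else np.nan
            rows.append((t, tr.id, st.x, st.y, st.vx, st.vy, ang,
                         int(st.effective)))
    df = pd.DataFrame(rows, columns=TRACKS_COLUMNS)
    return df.sort_values(["frame", "track_id"]).reset_index(drop=True)


def write_tracks(tracks: list[Track] | pd.DataFrame, path: str | Path) -> None:
    df = tracks if isinstance(tracks, pd.DataFrame) else tracks_to_df(tracks)
    df.to_csv(path, index=False, float_format="%.4f")


def trajectories_to_df(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        for t in tr.frames:
            st = tr.states[t]
            det = tr.detections.get(t)
            ang = det.angle if det is not None else np.nan
            rows.append((t, tr.id, st.x, st.y, ang, int(not st.effective)))
    df = pd.DataFrame(rows, columns=TRAJECTORIES_COLUMNS)
    return df.sort_values(["frame", "traj_id"]).reset_index(drop=True)


def write_trajectories(tracks, path: str | Path) -> None:
    df = tracks if isinstance(tracks, pd.DataFrame) else trajectories_to_df(tracks)
    df.to_csv(path, index=False, float_format="%.4f")


def read_trajectories(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "frame" not in df.columns:
        raise IOError(f"trajectory file {path} lacks a 'frame' column")
    return df


def write_truth(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.4f")


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclasses.dataclass
class PipelineConfig:
    """Bundle of per-stage parameters plus I/O options and seed."""

    detection: DetectionParams = dataclasses.field(default_factory=DetectionParams)
    tracking: TrackingParams = dataclasses.field(default_factory=TrackingParams)
    linking: LinkingParams = dataclasses.field(default_factory=LinkingParams)
    seed: int = 0


_SECTIONS = {
    "detection": DetectionParams,
    "tracking": TrackingParams,
    "linking": LinkingParams,
}


def _coerce(cls, name: str, raw: str):
    ftypes = {f.name: f for f in dataclasses.fields(cls)}
    if name not in ftypes:
        raise KeyError(f"unknown parameter '{cls.__name__}.{name}'")
    raw = raw.strip()
    if raw.lower() in {"none", ""}:
        return None
    if name == "scale_grid":
        return tuple(float(v) for v in raw.split())
    try:
        f = float(raw)
    except ValueError as exc:
        raise ValueError(f"cannot parse value {raw!r} for {name}") from exc
    return int(f) if f == int(f) and name in {
        "T1", "T2", "min_track_len", "contour_iters", "contour_smoothing"
    } else f


def parse_config(path: str | Path) -> PipelineConfig:
    """Parse a flat ``section.key = value`` text config.

    Example::

        detection.w_min = 16
        detection.w_max = 24
        detection.k = 0.03
        tracking.tau_w = 5
        linking.T1 = 10
        seed = 1

    Unknown sections or keys are errors (typos in threshold names should
    fail loudly, not silently fall back to defaults).
    """
    overrides: dict[str, dict] = {s: {} for s in _SECTIONS}
    seed = 0
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value'")
        key, raw = (s.strip() for s in line.split("=", 1))
        if key == "seed":
            seed = int(raw)
            continue
        if "." not in key:
            raise KeyError(f"{path}:{ln}: unknown key '{key}'")
        section, name = key.split(".", 1)
        if section not in _SECTIONS:
            raise KeyError(f"{path}:{ln}: unknown section '{section}'")
        overrides[section][name] = _coerce(_SECTIONS[section], name, raw)
    return PipelineConfig(
        detection=DetectionParams(**overrides["detection"]),
        tracking=TrackingParams(**overrides["tracking"]),
        linking=LinkingParams(**overrides["linking"]),
        seed=seed,
    )
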