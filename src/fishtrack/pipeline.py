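"""End-to-end pipeline: detect -> track -> link, with stage-labeled errors."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as ftio
from .detection import Frame, detect_heads
from .linking import fragments_from_tracks, link_fragments, prune_spurious
from .tracking import Tracker

log = logging.getLogger("fishtrack")


class StageError(RuntimeError):
    """An error raised by one pipeline stage, labeled with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineResult:
    detections: pd.DataFrame
    raw_tracks: pd.DataFrame
    trajectories: pd.DataFrame
    n_frames: int
    n_tracks_raw: int
    n_tracks_linked: int


def detect_all(frames, params) -> list:
    """Run head detection over an iterable of frames."""
    all_dets = []
    for frame in frames:
        dets = detect_heads(frame, params)
        log.info("frame %d: %d detections", frame.index, len(dets))
        all_dets.extend(dets)
    return all_dets


def run_pipeline(
    frames,
    config: "ftio.PipelineConfig | None" = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Detect, track and link over a frame iterable.

    ``frames`` may be any iterable of Frame (a reader from
    :func:`fishtrack.io.read_frames` or rendered synthetic frames).  When
    ``out_dir`` is set, the intermediate and final CSVs are written there.
    Deterministic for fixed frames and config.
    """
    config = config or ftio.PipelineConfig()
    frame_list = list(frames)
    n_frames = len(frame_list)

    try:
        dets = detect_all(frame_list, config.detection)
    except Exception as exc:
        raise StageError("detect", exc) from exc
    det_df = ftio.detections_to_df(dets)

    try:
        by_frame = ftio.detections_from_df(det_df)
        tracker = Tracker(config.tracking, config.linking)
        for frame in frame_list:
            tracker.step(frame, by_frame.get(frame.index, []))
        raw = tracker.tracks()
    except Exception as exc:
        raise StageError("track", exc) from exc
    raw_df = ftio.tracks_to_df(raw)
    n_raw = len(raw)
    log.info("tracking: %d raw tracks", n_raw)

    try:
        frags = fragments_from_tracks(raw, n_frames=n_frames)
        linked = link_fragments(frags, config.linking, config.tracking)
        linked = prune_spurious(linked, config.linking)
    except Exception as exc:
        raise StageError("link", exc) from exc
    traj_df = ftio.trajectories_to_df(linked)
    log.info("linking: %d trajectories", len(linked))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        ftio.write_detections(det_df, out_dir / "detections.csv")
        ftio.write_tracks(raw_df, out_dir / "tracks.csv")
        ftio.write_trajectories(traj_df, out_dir / "trajectories.csv")

    return PipelineResult(
        detections=det_df,
        raw_tracks=raw_df,
        trajectories=traj_df,
        n_frames=n_frames,
        n_tracks_raw=n_raw,
        n_tracks_linked=len(linked),
    )
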