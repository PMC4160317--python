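"""Track lifecycle and two-pass trajectory linking.

Occlusion hides a head for a stretch of frames; the first-pass tracker then
coasts on Kalman predictions (virtual observations) and, after ``T1``
consecutive misses, closes the track as *incomplete* with an end tag at its
last effective state.  The re-emerging fish spawns a new track with a start
tag.  The second pass stitches such fragments back together: a pair
(end-tagged A, start-tagged B) is linkable when B starts after A ends with
a gap below ``T2`` frames, the endpoints lie within ``D`` px, and the
stored endpoint matching regions pass the same width/area/grayscale
cascade used for frame-to-frame association.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tracking import (KalmanState, MatchingRegion, Track, TrackingParams,
                       match_features)


@dataclass(frozen=True)
class LinkingParams:
    """Lifecycle / linking parameters.

    ``T1``: consecutive-miss limit before a track is marked incomplete;
    ``T2``: maximum frame gap between linkable fragments; ``D``: maximum
    distance (px) between an end tag and a start tag; ``min_track_len``:
    tracks shorter than this with no link partner are detection noise.
    """

    T1: int = 10
    T2: int = 30
    D: float = 80.0
    min_track_len: int = 5

    def __post_init__(self):
        if min(self.T1, self.T2, self.min_track_len) <= 0 or self.D <= 0:
            raise ValueError("all linking parameters must be positive")


@dataclass
class Fragment:
    """A trajectory fragment with its endpoint tags and appearance."""

    track: Track
    start_tag: tuple[int, tuple[float, float]]
    end_tag: tuple[int, tuple[float, float]]
    start_region: MatchingRegion | None
    end_region: MatchingRegion | None
    start_open: bool = True   # incomplete at the start (born mid-video)
    end_open: bool = True     # incomplete at the end (lost before video end)


# --------------------------------------------------------------------------
# Lifecycle
# --------------------------------------------------------------------------

def update_lifecycle(track: Track, frame_result: str,
                     params: LinkingParams) -> Track:
    """Advance a track's lifecycle after one frame of association.

    ``associated``: the state is effective, the miss counter resets.
    ``missed``: the track coasted on a virtual (predicted) observation,
    the state is ineffective and the counter grows; at ``T1`` consecutive
    misses the track becomes incomplete, its end tag set to the time and
    position of the last effective state, and it leaves the active set.
    """
    t = track.last_frame
    if frame_result == "associated":
        track.states[t].effective = True
        track.miss_count = 0
    elif frame_result == "missed":
        track.states[t].effective = False
        track.miss_count += 1
        if track.miss_count >= params.T1:
            track.status = "incomplete"
            eff = [f for f in track.frames if track.states[f].effective]
            if eff:
                last = eff[-1]
                st = track.states[last]
                track.end_tag = (last, (st.x, st.y))
                # drop the coasted tail: those states were never observed
                for f in [f for f in track.frames if f > last]:
                    del track.states[f]
                    track.detections.pop(f, None)
            else:
                track.status = "terminated"  # never observed effectively
    else:
        raise ValueError(f"unknown frame result {frame_result!r}")
    return track


def prune_spurious(tracks: list[Track], params: LinkingParams) -> list[Track]:
    """Drop tracks shorter than ``min_track_len`` frames.

    Spurious detections (speckle, tail flicker) die within a few frames;
    real fish persist.  Idempotent.
    """
    return [tr for tr in tracks if len(tr.states) >= params.min_track_len]


# --------------------------------------------------------------------------
# Linking constraints
# --------------------------------------------------------------------------

def time_constraint(end_tag, start_tag, params: LinkingParams) -> bool:
    """True iff the start is strictly later than the end, gap < T2."""
    et, st = end_tag[0], start_tag[0]
    return 0 < st - et < params.T2


def space_constraint(end_tag, start_tag, params: LinkingParams) -> bool:
    """True iff the endpoint distance is strictly below D px."""
    (ex, ey), (sx, sy) = end_tag[1], start_tag[1]
    return math.hypot(sx - ex, sy - ey) < params.D


# --------------------------------------------------------------------------
# Fragment linking
# --------------------------------------------------------------------------

def fragments_from_tracks(tracks: list[Track],
                          n_frames: int | None = None) -> list[Fragment]:
    """Wrap first-pass tracks as linkable fragments.

    A fragment is open at the start when it was born after frame 0 (the
    fish may have re-emerged from occlusion) and open at the end when the
    track was closed as incomplete before the video ended.  Incomplete
    tracks stay eligible for linking for the remainder of the video; T2
    bounds the gap between fragments, not when linking runs.
    """
    out = []
    for tr in tracks:
        frames = tr.frames
        if not frames:
            continue
        start = tr.start_tag or (frames[0],
                                 (tr.states[frames[0]].x, tr.states[frames[0]].y))
        end = tr.end_tag or (frames[-1],
                             (tr.states[frames[-1]].x, tr.states[frames[-1]].y))
        end_open = tr.status == "incomplete" or (
            n_frames is not None and end[0] < n_frames - 1
        )
        out.append(
            Fragment(
                track=tr,
                start_tag=start,
                end_tag=end,
                start_region=tr.start_region,
                end_region=tr.region,
                start_open=start[0] > 0,
                end_open=end_open,
            )
        )
    return out


def link_fragments(fragments: list[Fragment], params: LinkingParams,
                   tp: TrackingParams | None = None) -> list[Track]:
    """Greedily merge fragment pairs that pass time, space and feature tests.

    Candidate pairs (A ends, B starts) must satisfy the time and space
    constraints and their endpoint matching regions must pass the cascade
    feature match; passing pairs are linked by ascending match score, each
    fragment used at most once per side, iterating until no link remains.
    Gaps are filled by linear interpolation of position, flagged as
    interpolated (virtual states).
    """
    tp = tp or TrackingParams()
    frags = list(fragments)

    while True:
        candidates = []
        for i, fa in enumerate(frags):
            if not fa.end_open:
                continue
            for j, fb in enumerate(frags):
                if i == j or not fb.start_open:
                    continue
                if not time_constraint(fa.end_tag, fb.start_tag, params):
                    continue
                if not space_constraint(fa.end_tag, fb.start_tag, params):
                    continue
                if fa.end_region is not None and fb.start_region is not None:
                    ok, score = match_features(fa.end_region, fb.start_region, tp)
                    if not ok:
                        continue
                else:
                    score = 0.5
                candidates.append((score, i, j))
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1], c[2]))
        used: set[int] = set()
        links: list[tuple[int, int]] = []
        for score, i, j in candidates:
            if i in used or j in used:
                continue
            links.append((i, j))
            used.add(i)
            used.add(j)
        merged_ids = set()
        new_frags = []
        for i, j in links:
            new_frags.append(_merge(frags[i], frags[j]))
            merged_ids.update((i, j))
        frags = [f for k, f in enumerate(frags) if k not in merged_ids] + new_frags

    return [f.track for f in frags]


def _merge(fa: Fragment, fb: Fragment) -> Fragment:
    """Concatenate fragment B after fragment A, interpolating the gap."""
    a, b = fa.track, fb.track
    et, (ex, ey) = fa.end_tag
    st, (sx, sy) = fb.start_tag
    merged = Track(id=a.id)
    merged.states = dict(a.states)
    merged.detections = dict(a.detections)
    for t in range(et + 1, st):
        w = (t - et) / (st - et)
        ks = KalmanState(x=ex + w * (sx - ex), y=ey + w * (sy - ey),
                         effective=False)
        merged.states[t] = ks
        merged.detections[t] = None
    merged.states.update(b.states)
    merged.detections.update(b.detections)
    merged.status = b.status
    merged.start_tag = a.start_tag
    merged.end_tag = b.end_tag
    merged.start_region = fa.start_region
    merged.region = fb.end_region
    return Fragment(
        track=merged,
        start_tag=fa.start_tag,
        end_tag=fb.end_tag,
        start_region=fa.start_region,
        end_region=fb.end_region,
        start_open=fa.start_open,
        end_open=fb.end_open,
    )
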