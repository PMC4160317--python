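"""Detection and tracking metrics against ground truth.

Detection quality is summarized by precision and recall over all frames,
plus two occlusion-specific rates: OR (occlusion ratio, occlusion events
per fish-frame) and ODR (occlusion detection ratio, the fraction of
occluded targets still detected).

Tracking quality follows the trajectory-association scheme of Perera-style
MOT evaluation: every output trajectory is assigned to at most one ground
truth trajectory so as to minimize the summed mean positional distance
over overlapping frames (several fragments may map to one truth); from the
optimal association come TCF (trajectory completeness factor: mean
fraction of each truth trajectory covered by its associated outputs) and
TFF (trajectory fragmentation factor: mean number of outputs needed per
matched truth trajectory).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd


@dataclass
class DetectionTally:
    """Detection counts accumulated over a video."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    n_occlusions: int = 0
    n_occl_detected: int = 0
    n_fish: int = 0
    n_frames: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.n_occlusions,
               self.n_occl_detected) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_occl_detected > self.n_occlusions:
            raise ValueError("n_occl_detected cannot exceed n_occlusions")


@dataclass
class Trajectory:
    """Per-frame positions of one target: frame -> (x, y)."""

    id: int
    points: dict[int, tuple[float, float]]

    @property
    def frames(self) -> set[int]:
        return set(self.points)

    def __len__(self) -> int:
        return len(self.points)


def trajectories_from_df(df: pd.DataFrame, id_col: str = "id") -> list[Trajectory]:
    """Build trajectories from a tidy frame/id/x/y table."""
    out = []
    for tid, g in df.groupby(id_col):
        pts = {int(r.frame): (float(r.x), float(r.y))
               for r in g.itertuples(index=False)}
        out.append(Trajectory(id=int(tid), points=pts))
    return out


# --------------------------------------------------------------------------
# Detection metrics
# --------------------------------------------------------------------------

def match_detections(
    dets_xy: np.ndarray, truth_xy: np.ndarray, radius: float
) -> tuple[int, int, int, list[int]]:
    """One-to-one greedy matching of detections to truth heads by distance.

    A detection is a true positive iff its center lies within ``radius`` of
    a not-yet-matched ground-truth head center.  Returns (tp, fp, fn,
    matched_truth_indices).
    """
    dets_xy = np.atleast_2d(np.asarray(dets_xy, float))
    truth_xy = np.atleast_2d(np.asarray(truth_xy, float))
    nd = 0 if dets_xy.size == 0 else len(dets_xy)
    nt = 0 if truth_xy.size == 0 else len(truth_xy)
    if nd == 0 or nt == 0:
        return 0, nd, nt, []
    d = np.hypot(dets_xy[:, None, 0] - truth_xy[None, :, 0],
                 dets_xy[:, None, 1] - truth_xy[None, :, 1])
    pairs = sorted(
        ((d[i, j], i, j) for i, j in product(range(nd), range(nt))
         if d[i, j] <= radius)
    )
    used_d: set[int] = set()
    used_t: set[int] = set()
    for _, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
    tp = len(used_d)
    return tp, nd - tp, nt - tp, sorted(used_t)


def tally_detections(
    detections: pd.DataFrame, truth: pd.DataFrame, radius: float | None = None
) -> DetectionTally:
    """Accumulate per-frame TP/FP/FN and occlusion counts over a video.

    ``detections``: frame/x/y table; ``truth``: frame/id/x/y with optional
    ``occluded`` flags.  Match radius defaults to half the mean truth head
    length when a ``length`` column exists, else 16 px.
    """
    if radius is None:
        radius = (0.5 * truth["length"].mean()
                  if "length" in truth.columns else 16.0)
    tally = DetectionTally(
        n_fish=truth["id"].nunique(),
        n_frames=int(truth["frame"].max()) + 1 if len(truth) else 0,
    )
    det_by_frame = dict(tuple(detections.groupby("frame"))) if len(detections) else {}
    for t, tg in truth.groupby("frame"):
        dg = det_by_frame.get(t)
        dxy = dg[["x", "y"]].to_numpy() if dg is not None else np.empty((0, 2))
        txy = tg[["x", "y"]].to_numpy()
        tp, fp, fn, matched = match_detections(dxy, txy, radius)
        tally.tp += tp
        tally.fp += fp
        tally.fn += fn
        if "occluded" in tg.columns:
            occ = tg["occluded"].to_numpy().astype(bool)
            tally.n_occlusions += int(occ.sum())
            tally.n_occl_detected += int(occ[list(matched)].sum()) if matched else 0
    return tally


def detection_metrics(tally: DetectionTally) -> tuple[float, float]:
    """precision = tp/(tp+fp), recall = tp/(tp+fn).

    Raises on an undefined ratio (no detections or no truth) so the caller
    must handle the degenerate case explicitly.
    """
    if tally.tp + tally.fp == 0:
        raise ZeroDivisionError("precision undefined: no detections")
    if tally.tp + tally.fn == 0:
        raise ZeroDivisionError("recall undefined: no ground-truth targets")
    return (tally.tp / (tally.tp + tally.fp),
            tally.tp / (tally.tp + tally.fn))


def occlusion_metrics(tally: DetectionTally) -> tuple[float, float]:
    """OR = occlusions per fish-frame; ODR = detected occluded / occluded."""
    if tally.n_fish <= 0 or tally.n_frames <= 0:
        raise ValueError("need n_fish > 0 and n_frames > 0")
    or_ratio = tally.n_occlusions / (tally.n_fish * tally.n_frames)
    odr = (tally.n_occl_detected / tally.n_occlusions
           if tally.n_occlusions else 0.0)
    return or_ratio, odr


# --------------------------------------------------------------------------
# Trajectory association
# --------------------------------------------------------------------------

def trajectory_distance(a: Trajectory, b: Trajectory) -> float:
    """Mean Euclidean distance over the overlapping frames.

    Infinite when the trajectories never coexist (they can never be
    associated).
    """
    overlap = a.frames & b.frames
    if not overlap:
        return math.inf
    return float(
        np.mean([math.hypot(a.points[t][0] - b.points[t][0],
                            a.points[t][1] - b.points[t][1])
                 for t in overlap])
    )


def associate_trajectories(
    obtained: list[Trajectory], truth: list[Trajectory]
) -> dict[int, int]:
    """Optimal association: obtained trajectory -> truth trajectory.

    Every obtained trajectory that temporally overlaps at least one truth
    trajectory is assigned to exactly one of them; the assignment minimizes
    the summed trajectory distance.  Several obtained fragments may map to
    the same truth (fragmentation), so each obtained simply takes its
    minimum-distance feasible truth — with no per-truth capacity the
    per-fragment optimum is the global optimum.  Returns a mapping of
    trajectory ids.
    """
    if not truth:
        raise ValueError("need non-empty ground truth")
    assoc: dict[int, int] = {}
    for ob in obtained:
        best, best_d = None, math.inf
        for gt in truth:
            d = trajectory_distance(ob, gt)
            if d < best_d:
                best, best_d = gt.id, d
        if best is not None and math.isfinite(best_d):
            assoc[ob.id] = best
    return assoc


def tcf_tff(
    association: dict[int, int],
    obtained: list[Trajectory],
    truth: list[Trajectory],
) -> tuple[float, float]:
    """Trajectory completeness and fragmentation factors.

    TCF = mean over truth trajectories of the fraction of their frames
    covered by associated obtained trajectories; TFF = mean number of
    obtained trajectories per *matched* truth trajectory (>= 1).
    """
    by_id = {ob.id: ob for ob in obtained}
    tcfs = []
    frag_counts = []
    for gt in truth:
        members = [oid for oid, gid in association.items() if gid == gt.id]
        covered: set[int] = set()
        for oid in members:
            covered |= by_id[oid].frames & gt.frames
        tcfs.append(len(covered) / len(gt.frames) if gt.frames else 0.0)
        if members:
            frag_counts.append(len(members))
    tcf = float(np.mean(tcfs)) if tcfs else 0.0
    tff = float(np.mean(frag_counts)) if frag_counts else 0.0
    return tcf, tff


def identity_switches(
    obtained: list[Trajectory], truth: list[Trajectory], radius: float = 16.0
) -> int:
    """Count frames where an output trajectory jumps between truth targets.

    Each output position is attributed to the nearest truth target within
    ``radius``; a switch is counted whenever consecutive attributed ids of
    one output trajectory differ.
    """
    switches = 0
    truth_by_frame: dict[int, list[tuple[int, float, float]]] = {}
    for gt in truth:
        for t, (x, y) in gt.points.items():
            truth_by_frame.setdefault(t, []).append((gt.id, x, y))
    for ob in obtained:
        prev = None
        for t in sorted(ob.points):
            cand = truth_by_frame.get(t, [])
            if not cand:
                continue
            ox, oy = ob.points[t]
            gid, d = min(
                ((g, math.hypot(ox - x, oy - y)) for g, x, y in cand),
                key=lambda p: p[1],
            )
            if d > radius:
                continue
            if prev is not None and gid != prev:
                switches += 1
            prev = gid
    return switches


@dataclass
class EvalReport:
    precision: float
    recall: float
    or_ratio: float
    odr: float
    tcf: float
    tff: float
    association: dict[int, int] = field(default_factory=dict)
    id_switches: int | None = None

    def as_dict(self) -> dict:
        d = {
            "precision": self.precision,
            "recall": self.recall,
            "or_ratio": self.or_ratio,
            "odr": self.odr,
            "tcf": self.tcf,
            "tff": self.tff,
        }
        if self.id_switches is not None:
            d["id_switches"] = self.id_switches
        return d


def evaluate(
    detections: pd.DataFrame,
    trajectories: pd.DataFrame,
    truth: pd.DataFrame,
    radius: float | None = None,
) -> EvalReport:
    """Full report: detection tally + trajectory association metrics."""
    tally = tally_detections(detections, truth, radius)
    precision, recall = detection_metrics(tally)
    or_ratio, odr = occlusion_metrics(tally)
    obtained = trajectories_from_df(
        trajectories, id_col="traj_id" if "traj_id" in trajectories.columns else "id"
    )
    gts = trajectories_from_df(truth)
    assoc = associate_trajectories(obtained, gts)
    tcf, tff = tcf_tff(assoc, obtained, gts)
    if radius is None:
        radius = (0.5 * truth["length"].mean()
                  if "length" in truth.columns else 16.0)
    ids = identity_switches(obtained, gts, radius)
    return EvalReport(precision=precision, recall=recall, or_ratio=or_ratio,
                      odr=odr, tcf=tcf, tff=tff, association=assoc,
                      id_switches=ids)
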