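"""Tracking evaluation: detection counts, occlusion statistics, CTR/CIR, IDS.

The metrics quantify two distinct abilities.  Detection quality is
precision/recall over per-frame matched target positions, plus how often
individuals involved in occlusions are still found.  Tracking quality is
the correct tracking ratio (CTR: fraction of fish-frames carrying the
right identity at the right place) and the correct identification ratio
(CIR: fraction of occlusion events after which *every* involved fish still
carries its pre-occlusion identity), plus the ID-switch count.

All ratios are percentages in [0, 100]; ``None`` marks an undefined value
(zero denominator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "DetectionCounts",
    "EvalReport",
    "precision_recall",
    "occlusion_rate",
    "detection_rate_from_occlusions",
    "ctr",
    "cir",
    "match_pred_to_truth",
    "count_id_switches",
    "evaluate_tracking",
]


@dataclass
class DetectionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    n_occlusions: int = 0
    n_occ_detected: int = 0
    n_individuals: int = 0
    n_frames: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.n_occlusions, self.n_occ_detected) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_occ_detected > self.n_occlusions:
            raise ValueError("n_occ_detected cannot exceed n_occlusions")


@dataclass
class EvalReport:
    """Percent-scale summary of one tracking run against ground truth."""

    precision: float | None
    recall: float | None
    occlusion_rate: float | None
    detection_rate_from_occlusions: float | None
    ctr: float | None
    cir: float | None
    ids: int

    def rounded(self, ndigits: int = 2) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            out[k] = round(v, ndigits) if isinstance(v, float) else v
        return out


def precision_recall(counts: DetectionCounts) -> tuple[float | None, float | None]:
    """Precision = tp/(tp+fp), recall = tp/(tp+fn), as percentages."""
    precision = 100.0 * counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else None
    recall = 100.0 * counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else None
    return precision, recall


def occlusion_rate(n_occlusions: int, n_individuals: int, n_frames: int) -> float:
    """Occlusion events per individual per frame, as a percentage."""
    if n_individuals <= 0 or n_frames <= 0:
        raise ValueError("n_individuals and n_frames must be positive")
    return 100.0 * n_occlusions / (n_individuals * n_frames)


def detection_rate_from_occlusions(n_correct: int, n_occlusions: int) -> float | None:
    """Fraction of occluded individuals still detected, as a percentage."""
    if n_occlusions == 0:
        return None
    return 100.0 * n_correct / n_occlusions


def ctr(correct_frames_per_target: list[int], n_individuals: int, n_frames: int) -> float:
    """Correct tracking ratio: correctly tracked fish-frames over all fish-frames."""
    if len(correct_frames_per_target) != n_individuals:
        raise ValueError("one entry per individual required")
    if any(c > n_frames for c in correct_frames_per_target):
        raise ValueError("correct frames cannot exceed n_frames")
    return 100.0 * sum(correct_frames_per_target) / (n_individuals * n_frames)


def cir(n_all_correct_after_occlusion: int, n_occlusions: int) -> float | None:
    """Correct identification ratio over occlusion events, as a percentage."""
    if n_occlusions == 0:
        return None
    return 100.0 * n_all_correct_after_occlusion / n_occlusions


def _match_frame(pred_xy: np.ndarray, truth_xy: np.ndarray, dist_max: float):
    """Greedy-optimal point matching: Hungarian on distance, gated."""
    if len(pred_xy) == 0 or len(truth_xy) == 0:
        return []
    D = np.linalg.norm(pred_xy[:, None, :] - truth_xy[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(D)
    return [(int(r), int(c)) for r, c in zip(rows, cols) if D[r, c] <= dist_max]


@dataclass
class MatchResult:
    """Output of match_pred_to_truth."""

    counts: DetectionCounts
    # per truth id: list of (frame, matched pred id or None)
    correspondence: dict[int, list[tuple[int, int | None]]]
    # per truth id: number of frames matched with the established pred id
    correct_frames: dict[int, int]
    # per occlusion event: (frame range, involved truth ids, outcome);
    # outcome None = unjudgeable (no post-event frame in the data)
    events: list[tuple[tuple[int, int], tuple[int, ...], bool | None]]


def _occlusion_events(truth: pd.DataFrame) -> list[tuple[tuple[int, int], tuple[int, ...]]]:
    """Maximal runs of consecutive frames with any occlusion flags set.

    Each event carries the union of fish ids flagged during the run.
    """
    occ = truth[truth["occluded"]]
    if occ.empty:
        return []
    frames = sorted(occ["frame"].unique())
    events = []
    start = prev = frames[0]
    for f in frames[1:]:
        if f == prev + 1:
            prev = f
            continue
        events.append((start, prev))
        start = prev = f
    events.append((start, prev))
    out = []
    for a, b in events:
        ids = tuple(sorted(occ[(occ["frame"] >= a) & (occ["frame"] <= b)]["id"].unique()))
        out.append(((int(a), int(b)), ids))
    return out


def match_pred_to_truth(
    pred: pd.DataFrame,
    truth: pd.DataFrame,
    dist_max: float = 30.0,
    start_frame: int = 0,
) -> MatchResult:
    """Associate predicted head points with ground truth, frame by frame.

    Per frame, predictions and truth head points are matched by
    minimum-cost Euclidean assignment; pairs farther than ``dist_max`` are
    rejected.  Matched pairs are true positives, unmatched predictions
    false positives, unmatched truth rows false negatives.  A truth fish's
    *established* predicted ID is the first ID ever matched to it; a frame
    counts as correct for CTR only when the matched ID equals the
    established one.  Occlusion events are maximal runs of truth occlusion
    flags; an event is identity-correct if, at the first post-event frame
    where all involved fish are matched, each carries its pre-event
    established ID.

    ``start_frame`` restricts scoring to frames >= it (used to skip the
    tracker's confirmation burn-in).
    """
    truth = truth[truth["frame"] >= start_frame]
    pred = pred[pred["frame"] >= start_frame]
    t0, t1 = int(truth["frame"].min()), int(truth["frame"].max())
    pf0, pf1 = (int(pred["frame"].min()), int(pred["frame"].max())) if len(pred) else (t0, t1)
    if pf0 < t0 or pf1 > t1:
        raise ValueError("prediction frames outside the truth frame range")

    truth_ids = sorted(truth["id"].unique())
    correspondence: dict[int, list[tuple[int, int | None]]] = {i: [] for i in truth_ids}
    established: dict[int, int] = {}
    correct_frames = {i: 0 for i in truth_ids}
    tp = fp = fn = 0

    pred_by_frame = dict(tuple(pred.groupby("frame"))) if len(pred) else {}
    truth_by_frame = dict(tuple(truth.groupby("frame")))

    matched_id_by_frame: dict[tuple[int, int], int] = {}  # (frame, truth id) -> pred id
    for f in range(t0, t1 + 1):
        tf = truth_by_frame.get(f)
        pf = pred_by_frame.get(f)
        t_ids = tf["id"].to_numpy() if tf is not None else np.empty(0, dtype=int)
        t_xy = tf[["head_x", "head_y"]].to_numpy() if tf is not None else np.empty((0, 2))
        p_ids = pf["id"].to_numpy() if pf is not None else np.empty(0, dtype=int)
        p_xy = pf[["head_x", "head_y"]].to_numpy() if pf is not None else np.empty((0, 2))
        pairs = _match_frame(p_xy, t_xy, dist_max)
        tp += len(pairs)
        fp += len(p_ids) - len(pairs)
        fn += len(t_ids) - len(pairs)
        matched_truth = set()
        for r, c in pairs:
            tid, pid = int(t_ids[c]), int(p_ids[r])
            matched_truth.add(tid)
            matched_id_by_frame[(f, tid)] = pid
            correspondence[tid].append((f, pid))
            if tid not in established:
                established[tid] = pid
            if established[tid] == pid:
                correct_frames[tid] += 1
        for tid in t_ids:
            if int(tid) not in matched_truth:
                correspondence[int(tid)].append((f, None))

    # occlusion events: detection outcome (every involved fish found in at
    # least half the event's frames) and identity outcome (all involved
    # fish carry their pre-event established ID at the first post-event
    # frame where all are matched)
    events = []
    n_occ_detected = 0
    raw_events = _occlusion_events(truth)
    for (a, b), ids in raw_events:
        found = [
            sum(1 for f in range(a, b + 1) if (f, tid) in matched_id_by_frame) for tid in ids
        ]
        if all(2 * n >= (b - a + 1) for n in found):
            n_occ_detected += 1
        ok: bool | None = False if b < t1 else None
        for f in range(b + 1, t1 + 1):
            got = {tid: matched_id_by_frame.get((f, tid)) for tid in ids}
            if all(v is not None for v in got.values()):
                ok = all(got[tid] == established.get(tid) for tid in ids)
                break
        events.append(((a, b), ids, ok))

    counts = DetectionCounts(
        tp=tp,
        fp=fp,
        fn=fn,
        n_occlusions=len(raw_events),
        n_occ_detected=n_occ_detected,
        n_individuals=len(truth_ids),
        n_frames=t1 - t0 + 1,
    )
    return MatchResult(
        counts=counts,
        correspondence=correspondence,
        correct_frames=correct_frames,
        events=events,
    )


def count_id_switches(correspondence: dict[int, list[tuple[int, int | None]]]) -> int:
    """Standard MOT ID switches: changes of a truth fish's matched predicted ID."""
    switches = 0
    for rows in correspondence.values():
        prev = None
        for _, pid in rows:
            if pid is None:
                continue
            if prev is not None and pid != prev:
                switches += 1
            prev = pid
    return switches


def evaluate_tracking(
    pred: pd.DataFrame,
    truth: pd.DataFrame,
    dist_max: float = 30.0,
    start_frame: int = 0,
) -> EvalReport:
    """Full evaluation of a predicted trajectory against ground truth."""
    res = match_pred_to_truth(pred, truth, dist_max=dist_max, start_frame=start_frame)
    c = res.counts
    precision, recall = precision_recall(c)
    occ_rate = occlusion_rate(c.n_occlusions, c.n_individuals, c.n_frames)
    det_occ = detection_rate_from_occlusions(c.n_occ_detected, c.n_occlusions)
    ctr_val = ctr(
        [res.correct_frames[i] for i in sorted(res.correct_frames)],
        c.n_individuals,
        c.n_frames,
    )
    judged = [ok for _, _, ok in res.events if ok is not None]
    cir_val = cir(sum(judged), len(judged))
    return EvalReport(
        precision=precision,
        recall=recall,
        occlusion_rate=occ_rate,
        detection_rate_from_occlusions=det_occ,
        ctr=ctr_val,
        cir=cir_val,
        ids=count_id_switches(res.correspondence),
    )
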