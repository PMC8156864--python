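"""Parallel head/body tracking with Kalman prediction and Hungarian assignment.

Two cooperating SORT-style trackers run per frame, online (no future
frames).  The *head* tracker is primary: confirmed head tracks predict a
box around their Kalman position, head detections are assigned by
minimum-cost intersection-over-union (cost = 1 - IOU) with a gate, and
unassigned detections feed a temporary-track pool that must associate for
``min_hits`` consecutive frames before earning an identity — either a
recycled lost ID (nearest last-known position) or a fresh one.  The *body*
tracker runs the same machinery on boxes centered at the body point R and
additionally carries the motion state omega; a body track becomes paired
with the head identity whose track center it encloses while both are
matched.  When a head detection is missing but the paired body is matched,
the head position is recovered as body center plus the last observed
head-minus-body offset ("body fallback"); when both are missing the track
coasts on its Kalman prediction for up to ``max_age`` frames before the ID
is retired to the lost pool.

Box sizes inflate linearly with omega: a turning fish (large omega) is
harder to predict, so its association gate widens with its motion state.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .detection import BodyDetection, DetectionConfig, HeadDetection, detect_frame
from .kalman import PointKalman
from .segmentation import build_background

__all__ = [
    "TrackerConfig",
    "KalmanTrack",
    "AssignmentResult",
    "box_from_state",
    "iou",
    "build_cost_matrix",
    "assign",
    "ParallelTracker",
    "track_video",
    "TRAJECTORY_COLUMNS",
]

logger = logging.getLogger(__name__)

TRAJECTORY_COLUMNS = ["frame", "id", "head_x", "head_y", "body_x", "body_y", "omega", "provenance"]


@dataclass
class TrackerConfig:
    """Lifecycle and motion parameters of the parallel tracker."""

    iou_min: float = 0.1  # association gate: matches below this IOU are cancelled
    max_age: int = 5  # frames a track may go unassociated before removal
    min_hits: int = 3  # consecutive associations before a temporary track is confirmed
    omega_gain: float = 1.0  # box inflation per unit omega/180
    head_box_size: tuple[float, float] = (24.0, 24.0)
    body_box_size: tuple[float, float] = (40.0, 40.0)
    process_noise: float = 1.0  # px/frame^2, ~expected per-frame speed change
    measurement_noise: float = 1.0  # px^2

    def __post_init__(self) -> None:
        if self.max_age < 1 or self.min_hits < 1:
            raise ValueError("max_age and min_hits must be >= 1")
        if not (0.0 <= self.iou_min <= 1.0):
            raise ValueError("iou_min must lie in [0, 1]")


def box_from_state(
    center: tuple[float, float],
    base_size: tuple[float, float],
    omega: float = 0.0,
    k: float = 1.0,
) -> tuple[float, float, float, float]:
    """Axis-aligned box around ``center`` inflated by the motion state.

    Sides are base_size * (1 + k * omega / 180): a straight fish keeps its
    base box, a fish turning hard gets a proportionally larger association
    region.  Returns (x0, y0, x1, y1).
    """
    if omega < 0:
        raise ValueError("omega must be >= 0")
    scale = 1.0 + k * omega / 180.0
    w, h = base_size[0] * scale, base_size[1] * scale
    cx, cy = center
    return (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)


def iou(boxA: tuple, boxB: tuple) -> float:
    """Intersection-over-union of two (x0, y0, x1, y1) boxes; 0 if disjoint."""
    ax0, ay0, ax1, ay1 = boxA
    bx0, by0, bx1, by1 = boxB
    areaA = max(0.0, ax1 - ax0) * max(0.0, ay1 - ay0)
    areaB = max(0.0, bx1 - bx0) * max(0.0, by1 - by0)
    if areaA == 0.0 or areaB == 0.0:
        return 0.0
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (areaA + areaB - inter)


def build_cost_matrix(preds: list[tuple], dets: list[tuple]) -> np.ndarray:
    """IOU-distance cost matrix: C[n, m] = 1 - iou(pred_n, det_m)."""
    C = np.ones((len(preds), len(dets)))
    for n, p in enumerate(preds):
        for m, d in enumerate(dets):
            C[n, m] = 1.0 - iou(p, d)
    return C


@dataclass
class AssignmentResult:
    matches: list[tuple[int, int]]
    unmatched_trks: list[int]
    unmatched_dets: list[int]
    cost: float


def assign(C: np.ndarray, iou_min: float = 0.0) -> AssignmentResult:
    """Minimum-cost matching of trackers (rows) to detections (columns).

    Solves the rectangular assignment problem, then cancels matches whose
    IOU falls below ``iou_min`` (cost above 1 - iou_min), reporting both
    sides unmatched — the SORT gate.  The reported cost is the summed cost
    of the surviving matches.
    """
    n, m = C.shape
    if n == 0 or m == 0:
        return AssignmentResult([], list(range(n)), list(range(m)), 0.0)
    rows, cols = linear_sum_assignment(C)
    matches = []
    cost = 0.0
    gate = 1.0 - iou_min
    for r, c in sorted(zip(rows, cols)):
        if C[r, c] > gate + 1e-12:
            continue
        matches.append((int(r), int(c)))
        cost += float(C[r, c])
    matched_r = {r for r, _ in matches}
    matched_c = {c for _, c in matches}
    return AssignmentResult(
        matches=matches,
        unmatched_trks=[r for r in range(n) if r not in matched_r],
        unmatched_dets=[c for c in range(m) if c not in matched_c],
        cost=cost,
    )


class KalmanTrack:
    """One tracked feature (head or body) with SORT lifecycle state."""

    __slots__ = (
        "id",
        "kind",
        "kf",
        "base_size",
        "omega_last",
        "hits",
        "time_since_update",
        "status",
        "omega_gain",
        "paired_head",
        "head_offset",
        "offset_axis",
        "axis_last",
        "matched_now",
    )

    def __init__(
        self,
        xy: tuple[float, float],
        kind: str,
        base_size: tuple[float, float],
        cfg: TrackerConfig,
        track_id: int | None = None,
    ):
        self.id = track_id
        self.kind = kind
        self.kf = PointKalman(xy, cfg.process_noise, cfg.measurement_noise)
        self.base_size = base_size
        self.omega_last = 0.0
        self.hits = 1
        self.time_since_update = 0
        self.status = "temporary"
        self.omega_gain = cfg.omega_gain
        self.paired_head: int | None = None  # body tracks: paired head ID
        self.head_offset: tuple[float, float] | None = None  # head - body, px
        self.offset_axis: float | None = None  # body axis when offset was stored
        self.axis_last: float | None = None  # body tracks: latest along-body axis
        self.matched_now = False

    def predict(self) -> tuple[float, float, float, float]:
        """Kalman-predict one frame ahead; returns the predicted box."""
        center = self.kf.predict()
        self.time_since_update += 1
        self.matched_now = False
        return box_from_state(center, self.base_size, self.omega_last, self.omega_gain)

    def update(self, xy: tuple[float, float], omega: float | None = None) -> None:
        self.kf.update(xy)
        self.hits += 1
        self.time_since_update = 0
        self.matched_now = True
        if omega is not None:
            self.omega_last = omega

    @property
    def position(self) -> tuple[float, float]:
        return self.kf.position


class ParallelTracker:
    """Online multi-fish tracker state machine.

    Feed frames (or pre-computed detections) in order with
    :meth:`process_frame` / :meth:`step`; collect the trajectory with
    :meth:`trajectory`.  Output for frame t depends only on frames <= t
    and the fixed background image.
    """

    def __init__(self, cfg: TrackerConfig | None = None, detection: DetectionConfig | None = None):
        self.cfg = cfg or TrackerConfig()
        self.detection = detection or DetectionConfig()
        self.head_tracks: list[KalmanTrack] = []  # confirmed
        self.temp_tracks: list[KalmanTrack] = []
        self.body_tracks: list[KalmanTrack] = []  # confirmed
        self.temp_body_tracks: list[KalmanTrack] = []
        # (id, last position, last velocity, frame of loss): relinking
        # extrapolates the lost track to the promotion frame
        self.lost_ids: list[tuple[int, tuple[float, float], tuple[float, float], int]] = []
        self._next_id = 1
        self._used_lost: set[int] = set()
        self.records: list[tuple] = []

    # -- head stage ---------------------------------------------------

    def _step_feature(
        self,
        dets_xy: list[tuple[float, float]],
        det_boxes: list[tuple],
        confirmed: list[KalmanTrack],
        temporary: list[KalmanTrack],
        kind: str,
        base_size: tuple[float, float],
    ) -> tuple[list[tuple[KalmanTrack, int]], list[int]]:
        """Shared predict/assign/update cycle for one feature kind.

        Returns (matched (track, det index) pairs over confirmed+promoted
        tracks, indices of detections left unassigned after the temporary
        pass).
        """
        cfg = self.cfg
        pred_boxes = [trk.predict() for trk in confirmed]
        res = assign(build_cost_matrix(pred_boxes, det_boxes), cfg.iou_min)
        matched_pairs = [(confirmed[r], c) for r, c in res.matches]
        for trk, c in matched_pairs:
            trk.update(dets_xy[c])

        # second pass: remaining detections vs temporary tracks
        rem = res.unmatched_dets
        temp_boxes = [trk.predict() for trk in temporary]
        res2 = assign(
            build_cost_matrix(temp_boxes, [det_boxes[c] for c in rem]), cfg.iou_min
        )
        for r, c in res2.matches:
            temporary[r].update(dets_xy[rem[c]])
        unassigned = [rem[c] for c in res2.unmatched_dets]
        for c in unassigned:
            temporary.append(KalmanTrack(dets_xy[c], kind, base_size, cfg))
        return matched_pairs, unassigned

    def _promote_and_prune_temps(
        self,
        temporary: list[KalmanTrack],
        confirmed: list[KalmanTrack],
        assign_ids: bool,
        t: int = 0,
    ) -> list[KalmanTrack]:
        """Promote ripe temporary tracks, drop stale ones as noise.

        A ripe temporary track that sits within a duplicate radius of a
        live confirmed track is not a new individual but the same fish
        re-appearing after a detection gap (the confirmed track meanwhile
        survived on body fallback or coasting, drifting slightly).  Instead
        of minting a duplicate identity, the confirmed track adopts the
        temporary track's freshly measured state.
        """
        cfg = self.cfg
        dup_radius = 1.5 * math.hypot(*cfg.head_box_size)
        # while any confirmed track is starving (no feature match this
        # frame) and no ID is waiting in the lost pool, hold ripe
        # temporaries back: the starving track is probably the same fish
        # mid-recovery, and promoting now would mint a duplicate identity
        # instead of relinking the one about to be lost
        hold_new_ids = (
            assign_ids
            and not self.lost_ids
            and any(not c.matched_now for c in confirmed)
        )
        promoted = []
        keep = []
        for trk in temporary:
            if trk.time_since_update > cfg.max_age:
                continue  # noise
            if trk.matched_now and trk.hits >= cfg.min_hits:
                # only tracks that failed to match their own feature this
                # frame are candidates: adopting into a matched track would
                # steal a neighbouring fish's detection during crossings
                starving = [c for c in confirmed if not c.matched_now]
                near = None
                if starving:
                    dists = [math.dist(trk.position, c.position) for c in starving]
                    k = int(np.argmin(dists))
                    if dists[k] <= dup_radius:
                        near = starving[k]
                if near is not None:
                    near.kf = trk.kf  # re-acquire: snap onto the real feature
                    near.time_since_update = 0
                    near.matched_now = True
                    continue
                if hold_new_ids:
                    keep.append(trk)
                    continue
                trk.status = "confirmed"
                if assign_ids:
                    trk.id = self._take_identity(trk.position, t)
                promoted.append(trk)
            else:
                keep.append(trk)
        temporary[:] = keep
        return promoted

    def _take_identity(self, xy: tuple[float, float], t: int) -> int:
        """Recycle the nearest lost ID, else mint a fresh one.

        "Nearest" extrapolates each lost track from its point of loss by
        its last velocity: during a crossing two fish die close together,
        and only the motion direction tells their identities apart.
        """
        if self.lost_ids:
            dists = []
            for _, pos, vel, t_lost in self.lost_ids:
                dt = max(0, t - t_lost)
                dists.append(math.dist(xy, (pos[0] + vel[0] * dt, pos[1] + vel[1] * dt)))
            k = int(np.argmin(dists))
            lost_id = self.lost_ids.pop(k)[0]
            return lost_id
        new_id = self._next_id
        self._next_id += 1
        return new_id

    # -- one full frame ------------------------------------------------

    def step(
        self,
        head_dets: list[HeadDetection],
        body_dets: list[BodyDetection],
        t: int,
    ) -> list[tuple]:
        """Advance the tracker by one frame of detections; returns new records."""
        cfg = self.cfg

        # --- head tracking (primary) ---
        head_xy = [d.center for d in head_dets]
        head_boxes = [
            box_from_state(d.center, cfg.head_box_size, 0.0, cfg.omega_gain) for d in head_dets
        ]
        self._step_feature(
            head_xy, head_boxes, self.head_tracks, self.temp_tracks, "head", cfg.head_box_size
        )
        promoted = self._promote_and_prune_temps(
            self.temp_tracks, self.head_tracks, assign_ids=True, t=t
        )
        self.head_tracks.extend(promoted)

        # --- body tracking (secondary, same machinery) ---
        body_xy = [d.R for d in body_dets]
        body_boxes = [
            box_from_state(d.R, cfg.body_box_size, d.omega, cfg.omega_gain) for d in body_dets
        ]
        matched_bodies, _ = self._step_feature(
            body_xy, body_boxes, self.body_tracks, self.temp_body_tracks, "body", cfg.body_box_size
        )
        for trk, c in matched_bodies:
            trk.omega_last = body_dets[c].omega
            trk.axis_last = body_dets[c].axis
        self.body_tracks.extend(
            self._promote_and_prune_temps(self.temp_body_tracks, self.body_tracks, assign_ids=False)
        )

        # --- pair body tracks to head identities by co-location ---
        by_id = {trk.id: trk for trk in self.head_tracks}
        for btrk in self.body_tracks:
            if not btrk.matched_now:
                continue
            bx, by = btrk.position
            bbox = box_from_state((bx, by), cfg.body_box_size, btrk.omega_last, cfg.omega_gain)
            for htrk in self.head_tracks:
                if not htrk.matched_now:
                    continue
                hx, hy = htrk.position
                if bbox[0] <= hx <= bbox[2] and bbox[1] <= hy <= bbox[3]:
                    btrk.paired_head = htrk.id
                    btrk.head_offset = (hx - bx, hy - by)
                    btrk.offset_axis = btrk.axis_last
                    htrk.omega_last = btrk.omega_last
                    break

        # --- body fallback for unmatched head tracks ---
        paired: dict[int, KalmanTrack] = {}
        for trk in self.body_tracks:
            if trk.paired_head is None:
                continue
            prev = paired.get(trk.paired_head)
            if prev is None or (trk.matched_now and not prev.matched_now):
                paired[trk.paired_head] = trk
        fallback_gate = math.hypot(*cfg.head_box_size) * 1.5
        for htrk in self.head_tracks:
            if htrk.matched_now:
                continue
            btrk = paired.get(htrk.id)
            if btrk is not None and btrk.matched_now and btrk.head_offset is not None:
                bx, by = btrk.position
                dx, dy = btrk.head_offset
                # the fish may have turned while its head was unseen: rotate
                # the stored offset by the change of the body axis (mod pi,
                # resolved to the smaller rotation)
                if btrk.offset_axis is not None and btrk.axis_last is not None:
                    dpsi = (btrk.axis_last - btrk.offset_axis + math.pi / 2) % math.pi - math.pi / 2
                    ca, sa = math.cos(dpsi), math.sin(dpsi)
                    dx, dy = ca * dx - sa * dy, sa * dx + ca * dy
                est = (bx + dx, by + dy)
                # plausibility gate: a stale pairing must not drag the head
                # track away from its own prediction — better to coast, die
                # and have the identity relinked than to follow a wrong body
                if math.dist(est, htrk.position) <= fallback_gate:
                    htrk.kf.update(est)
                    htrk.time_since_update = 0
                    htrk.omega_last = btrk.omega_last
                    htrk.status = "recovered"  # provenance marker for this frame
            # else: coasting on the Kalman prediction

        # --- emit records for confirmed head tracks ---
        new_records = []
        for htrk in self.head_tracks:
            hx, hy = htrk.position
            btrk = paired.get(htrk.id)
            if btrk is not None:
                bx, by = btrk.position
            else:
                bx = by = float("nan")
            if htrk.matched_now:
                prov = "head_tracked"
            elif htrk.status == "recovered":
                prov = "body_fallback"
                htrk.status = "confirmed"
            else:
                prov = "coasted"
            new_records.append((t, htrk.id, hx, hy, bx, by, htrk.omega_last, prov))

        # --- retire stale tracks ---
        for trk in list(self.head_tracks):
            if trk.time_since_update > cfg.max_age:
                trk.status = "removed"
                self.head_tracks.remove(trk)
                self.lost_ids.append((trk.id, trk.position, trk.kf.velocity, t))
        for trk in list(self.body_tracks):
            if trk.time_since_update > cfg.max_age:
                self.body_tracks.remove(trk)

        logger.debug(
            "frame %d: %d head dets, %d body dets, %d confirmed, %d temp, %d lost",
            t, len(head_dets), len(body_dets), len(self.head_tracks),
            len(self.temp_tracks), len(self.lost_ids),
        )
        self.records.extend(new_records)
        return new_records

    def process_frame(self, frame: np.ndarray, background: np.ndarray, t: int) -> list[tuple]:
        """Detect then track one frame."""
        heads, bodies = detect_frame(frame, background, self.detection, t=t)
        return self.step(heads, bodies, t)

    def trajectory(self) -> pd.DataFrame:
        """All emitted records as a trajectory table."""
        return pd.DataFrame(self.records, columns=TRAJECTORY_COLUMNS)


def track_video(
    frames,
    cfg: TrackerConfig | None = None,
    detection: DetectionConfig | None = None,
    n_background: int = 50,
    background: np.ndarray | None = None,
) -> pd.DataFrame:
    """Track a full frame sequence and return the trajectory table.

    The static background is the per-pixel temporal median of the first
    ``n_background`` frames unless one is supplied.  Tracking itself is
    online: each frame's output depends only on frames up to it (plus the
    fixed background).
    """
    frames = list(frames) if not isinstance(frames, list) else frames
    if not frames:
        return pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    if background is None:
        background = build_background(frames, min(n_background, len(frames)))
    tracker = ParallelTracker(cfg, detection)
    for t, frame in enumerate(frames):
        tracker.process_frame(frame, background, t)
    return tracker.trajectory()
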