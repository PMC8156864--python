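"""Synthetic fish-school video generator with exact ground truth.

Emulates the footage the tracker is built for: dark elongated fish with a
darker head blob swimming over a bright backlit arena.  Each fish is a
capsule-stroked 5-segment polyline (the body) plus a darker disk at the
front end (the head); body bend is distributed evenly over the polyline
joints, so a turning fish bends smoothly and a straight fish has a
collinear centerline.  Kinematics are a smoothed random walk in heading at
near-constant speed with specular reflection at the arena walls; scripted
crossing events steer a chosen pair of fish through a common point so that
occlusions happen in a known frame range.

Everything is deterministic for a fixed seed: one RNG drives kinematics and
pixel noise.  The ground truth records, per frame and fish: head point,
body center (arc midpoint of the centerline), bend angle, and an occlusion
flag set when the fish's rendered mask shares at least one pixel with
another fish's mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FishPose",
    "SchoolSimConfig",
    "simulate_school",
    "render_fish",
    "fish_mask",
    "centerline_points",
    "head_point",
    "write_truth",
    "read_truth",
]

TRUTH_COLUMNS = ["frame", "id", "head_x", "head_y", "body_x", "body_y", "bend", "occluded"]

N_SEGMENTS = 5


@dataclass
class FishPose:
    """Instantaneous state of one fish.

    center is the body center (arc midpoint of the centerline) in arena
    pixels; heading is the swim direction in radians (x rightward,
    y downward, angle measured from +x toward +y); bend is the total signed
    body-bend angle spread evenly over the polyline joints.
    """

    center: tuple[float, float]
    heading: float
    bend: float = 0.0
    length: float = 60.0
    width: float = 12.0
    speed: float = 2.5
    heading_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (self.length > self.width > 0):
            raise ValueError("need length > width > 0")
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if abs(self.bend) > math.pi / 2 + 1e-9:
            raise ValueError("|bend| must be <= pi/2")


@dataclass
class SchoolSimConfig:
    """Study conditions for one simulated school."""

    n_fish: int = 5
    n_frames: int = 100
    arena: tuple[int, int] = (512, 512)  # (width, height) px
    background_level: int = 230
    body_level: int = 160
    head_level: int = 30
    noise_sd: float = 2.0
    seed: int = 0
    fish_length: float = 60.0
    fish_width: float = 12.0
    speed: float = 2.5
    # short-range collision avoidance: fish steer away from neighbours
    # closer than avoid_radius (px); scripted crossing pairs ignore it
    avoid_radius: float = 90.0
    # list of ((frame_start, frame_end), (id_a, id_b)) forced path crossings
    crossing_script: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.head_level < self.body_level < self.background_level):
            raise ValueError("need head_level < body_level < background_level")
        if self.n_fish < 1:
            raise ValueError("n_fish must be >= 1")


def _chain(pose: FishPose) -> np.ndarray:
    """Centerline polyline vertices from head to tail, (N_SEGMENTS+1, 2).

    Built head-first: the first segment points backward from the head along
    -heading, and each joint adds bend / (N_SEGMENTS - 1); the chain is then
    translated so its arc midpoint sits at pose.center.
    """
    seg = pose.length / N_SEGMENTS
    per_joint = pose.bend / (N_SEGMENTS - 1)
    pts = [np.zeros(2)]
    ang = pose.heading + math.pi  # backward
    for k in range(N_SEGMENTS):
        if k > 0:
            ang += per_joint
        pts.append(pts[-1] + seg * np.array([math.cos(ang), math.sin(ang)]))
    pts = np.asarray(pts)
    # arc midpoint = middle of the center segment (odd segment count)
    mid = 0.5 * (pts[N_SEGMENTS // 2] + pts[N_SEGMENTS // 2 + 1])
    return pts - mid + np.asarray(pose.center, dtype=float)


def centerline_points(pose: FishPose, step: float = 1.0) -> np.ndarray:
    """Dense (x, y) samples along the body centerline, head to tail."""
    pts = _chain(pose)
    out = []
    for a, b in zip(pts[:-1], pts[1:]):
        n = max(2, int(math.ceil(np.linalg.norm(b - a) / step)) + 1)
        t = np.linspace(0.0, 1.0, n, endpoint=False)[:, None]
        out.append(a + t * (b - a))
    out.append(pts[-1][None, :])
    return np.vstack(out)


def head_point(pose: FishPose) -> tuple[float, float]:
    """Frame coordinates of the head center (front endpoint of the chain)."""
    p = _chain(pose)[0]
    return float(p[0]), float(p[1])


def _head_radius(pose: FishPose) -> float:
    return 0.58 * pose.width


def _masks(pose: FishPose, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray, tuple]:
    """Body and head boolean masks restricted to a local window.

    Returns (body_mask, head_mask, (y0, y1, x0, x1)) with masks over the
    window frame[y0:y1, x0:x1].
    """
    H, W = shape
    pts = _chain(pose)
    r_body = pose.width / 2.0
    r_head = _head_radius(pose)
    pad = max(r_body, r_head) + 2.0
    x0 = max(0, int(math.floor(pts[:, 0].min() - pad)))
    x1 = min(W, int(math.ceil(pts[:, 0].max() + pad)) + 1)
    y0 = max(0, int(math.floor(pts[:, 1].min() - pad)))
    y1 = min(H, int(math.ceil(pts[:, 1].max() + pad)) + 1)
    if x0 >= x1 or y0 >= y1:
        empty = np.zeros((0, 0), dtype=bool)
        return empty, empty, (y0, y0, x0, x0)
    xs = np.arange(x0, x1, dtype=float)
    ys = np.arange(y0, y1, dtype=float)
    X, Y = np.meshgrid(xs, ys)
    # min distance from each pixel to the polyline segments
    dmin = np.full(X.shape, np.inf)
    for a, b in zip(pts[:-1], pts[1:]):
        ab = b - a
        den = float(ab @ ab)
        t = ((X - a[0]) * ab[0] + (Y - a[1]) * ab[1]) / den
        t = np.clip(t, 0.0, 1.0)
        dx = X - (a[0] + t * ab[0])
        dy = Y - (a[1] + t * ab[1])
        dmin = np.minimum(dmin, np.hypot(dx, dy))
    body = dmin <= r_body
    hx, hy = pts[0]
    head = (X - hx) ** 2 + (Y - hy) ** 2 <= r_head**2
    return body, head, (y0, y1, x0, x1)


def render_fish(pose: FishPose, canvas: np.ndarray, body_level: int = 160, head_level: int = 30) -> np.ndarray:
    """Draw one fish onto ``canvas`` in place (darker pixel wins) and return it.

    The body is a capsule stroke of intensity ``body_level`` along the bent
    centerline; the head is a disk of intensity ``head_level`` at the front
    end.  Where fish overlap, the minimum-intensity rule means the darker
    structure shows, matching how backlit silhouettes stack.
    """
    body, head, (y0, y1, x0, x1) = _masks(pose, canvas.shape)
    if body.size == 0:
        return canvas
    win = canvas[y0:y1, x0:x1]
    win[body] = np.minimum(win[body], body_level)
    win[head] = np.minimum(win[head], head_level)
    return canvas


def fish_mask(pose: FishPose, shape: tuple[int, int]) -> np.ndarray:
    """Full-frame boolean silhouette (body plus head) of one fish."""
    body, head, (y0, y1, x0, x1) = _masks(pose, shape)
    m = np.zeros(shape, dtype=bool)
    if body.size:
        m[y0:y1, x0:x1] = body | head
    return m


#: hardest turn a fish makes in one frame (rad); wall avoidance and scripted
#: crossings steer within this limit so the head point moves continuously
MAX_TURN = 0.35


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2 * math.pi) - math.pi


def _steer_toward(heading: float, target: float, max_turn: float = MAX_TURN) -> float:
    """Rotate ``heading`` toward ``target`` by at most ``max_turn`` rad."""
    d = _wrap_angle(target - heading)
    return heading + float(np.clip(d, -max_turn, max_turn))


def _wall_target(pose: FishPose, arena: tuple[int, int], margin: float) -> float | None:
    """Specular-reflection heading when the next step would leave the arena.

    Returns the reflected heading to steer toward, or None away from walls.
    The turn itself is rate-limited by the caller: a real fish turns along
    the wall over a few frames instead of snapping its body around.
    """
    W, H = arena
    cx, cy = pose.center
    hx, hy = math.cos(pose.heading), math.sin(pose.heading)
    nx, ny = cx + pose.speed * hx, cy + pose.speed * hy
    rx = (nx < margin and hx < 0) or (nx > W - margin and hx > 0)
    ry = (ny < margin and hy < 0) or (ny > H - margin and hy > 0)
    if not rx and not ry:
        return None
    return math.atan2(-hy if ry else hy, -hx if rx else hx)


class _CrossingPlan:
    """Scripted choreography steering a pair of fish into an oblique crossing.

    At engagement a crossing point X is fixed half a gap ahead on the
    first fish's path.  The first fish keeps cruising toward X (slowing if
    its partner is running late); the second fish turns toward X and
    adjusts speed so both reach X together, which makes the paths cross at
    whatever oblique angle the initial geometry dictates rather than
    head-on.  Once the silhouettes are in contact range both lock their
    headings and swim straight through; the script then releases them.
    The scripted range must be long enough for the initial separation —
    roughly ``separation / speed`` frames.
    """

    def __init__(self, start: int, end: int, pair: tuple[int, int]):
        if end <= start:
            raise ValueError("crossing frame range must have end > start")
        self.start, self.end, self.pair = int(start), int(end), tuple(pair)
        self.through = False
        self.staging = True
        self.side = 1.0

    def engage(self, poses: dict[int, FishPose]) -> None:
        self.through = False
        self.staging = True
        leader, striker = poses[self.pair[0]], poses[self.pair[1]]
        u = np.array([math.cos(leader.heading), math.sin(leader.heading)])
        perp = np.array([-u[1], u[0]])
        rel = np.asarray(striker.center) - np.asarray(leader.center)
        self.side = math.copysign(1.0, float(perp @ rel) or 1.0)

    def steer(
        self,
        fid: int,
        pose: FishPose,
        poses: dict[int, FishPose],
        cruise: float,
        arena: tuple[int, int],
        margin: float,
    ) -> FishPose:
        """One scripted kinematics step for one member of the pair."""
        leader_id, striker_id = self.pair
        leader = poses[leader_id]
        other = poses[striker_id if fid == leader_id else leader_id]
        gap = math.dist(pose.center, other.center)
        contact = 0.7 * (pose.length + other.length) / 2
        if gap < contact:
            self.through = True
        if self.through:
            heading, speed = pose.heading, cruise
        elif fid == leader_id:
            # leader just cruises
            heading, speed = pose.heading, cruise
        else:
            u = np.array([math.cos(leader.heading), math.sin(leader.heading)])
            perp = np.array([-u[1], u[0]])
            if self.staging:
                # get abeam of the cruising leader on the striker's side,
                # leading the target by its expected travel (intercept course)
                abeam = np.asarray(leader.center) + self.side * 1.2 * leader.length * perp
                eta = math.dist(pose.center, tuple(abeam)) / (1.5 * cruise)
                target_pt = abeam + leader.speed * eta * u
                if math.dist(pose.center, tuple(abeam)) < 15.0:
                    self.staging = False
            if not self.staging:
                # cut across the leader's mid-body from the side
                target_pt = np.asarray(leader.center) - 0.2 * leader.length * u
            d = target_pt - np.asarray(pose.center)
            dist = float(np.linalg.norm(d))
            heading = (
                _steer_toward(pose.heading, math.atan2(d[1], d[0])) if dist > 1e-6 else pose.heading
            )
            speed = (1.5 if self.staging else 1.3) * cruise
        # walls win over choreography in every phase
        wall = _wall_target(replace(pose, heading=heading, speed=speed), arena, margin)
        if wall is not None:
            heading = _steer_toward(heading, wall)
        applied = _wrap_angle(heading - pose.heading)
        bend = 0.6 * pose.bend + 0.4 * float(np.clip(5.0 * applied, -0.6, 0.6))
        return replace(pose, heading=heading, speed=speed, heading_rate=applied, bend=bend)


def simulate_school(config: SchoolSimConfig) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Simulate a school and return (frames, ground truth).

    Frames are uint8 arrays of shape (arena_height, arena_width).  The
    ground-truth table has one row per (frame, fish) with columns
    frame, id, head_x, head_y, body_x, body_y, bend, occluded.
    """
    rng = np.random.default_rng(config.seed)
    W, H = config.arena
    margin = config.fish_length / 2.0 + 6.0
    if W - 2 * margin < 1 or H - 2 * margin < 1:
        raise ValueError("arena too small for the configured fish length")

    # initial non-overlapping placement by rejection sampling
    poses: dict[int, FishPose] = {}
    min_sep = config.fish_length * 1.2
    attempts = 0
    for fid in range(config.n_fish):
        while True:
            attempts += 1
            if attempts > 1000 * config.n_fish:
                raise ValueError("arena too small to place fish without initial overlap")
            c = (
                float(rng.uniform(margin, W - margin)),
                float(rng.uniform(margin, H - margin)),
            )
            if all(math.dist(c, p.center) >= min_sep for p in poses.values()):
                break
        poses[fid] = FishPose(
            center=c,
            heading=float(rng.uniform(-math.pi, math.pi)),
            length=config.fish_length,
            width=config.fish_width,
            speed=config.speed,
        )

    plans = [_CrossingPlan(fr[0], fr[1], pair) for fr, pair in config.crossing_script]

    frames: list[np.ndarray] = []
    rows: list[tuple] = []
    for t in range(config.n_frames):
        # engage / release scripted crossings
        scripted: dict[int, _CrossingPlan] = {}
        for plan in plans:
            if t == plan.start:
                plan.engage(poses)
            if plan.start <= t <= plan.end:
                for fid in plan.pair:
                    scripted[fid] = plan

        # kinematics update (fixed rng draw order: one normal per fish)
        steer = rng.normal(0.0, 0.03, size=config.n_fish)
        for fid in range(config.n_fish):
            p = poses[fid]
            if fid in scripted:
                p = scripted[fid].steer(fid, p, poses, config.speed, config.arena, margin)
            else:
                rate = float(np.clip(0.85 * p.heading_rate + steer[fid], -0.15, 0.15))
                heading = p.heading + rate
                # collision avoidance: turn away from the nearest close neighbour
                if config.avoid_radius > 0 and config.n_fish > 1:
                    others = [
                        (math.dist(p.center, poses[g].center), g)
                        for g in range(config.n_fish)
                        if g != fid
                    ]
                    dist, g = min(others)
                    if dist < config.avoid_radius:
                        away = math.atan2(
                            p.center[1] - poses[g].center[1],
                            p.center[0] - poses[g].center[0],
                        )
                        w = (config.avoid_radius - dist) / config.avoid_radius
                        heading = _steer_toward(heading, away, MAX_TURN * w)
                wall = _wall_target(replace(p, heading=heading), config.arena, margin)
                if wall is not None:
                    heading = _steer_toward(heading, wall)
                applied = _wrap_angle(heading - p.heading)
                bend_target = float(np.clip(5.0 * applied, -0.6, 0.6))
                bend = 0.6 * p.bend + 0.4 * bend_target
                p = replace(
                    p,
                    heading=heading,
                    heading_rate=applied,
                    bend=bend,
                    speed=config.speed,
                )
            cx = p.center[0] + p.speed * math.cos(p.heading)
            cy = p.center[1] + p.speed * math.sin(p.heading)
            cx = float(np.clip(cx, margin / 2, W - margin / 2))
            cy = float(np.clip(cy, margin / 2, H - margin / 2))
            poses[fid] = replace(p, center=(cx, cy))

        # render and flag occlusions by pairwise mask intersection
        canvas = np.full((H, W), config.background_level, dtype=np.float64)
        masks = {}
        for fid in range(config.n_fish):
            render_fish(poses[fid], canvas, config.body_level, config.head_level)
            masks[fid] = fish_mask(poses[fid], (H, W))
        occluded = {fid: False for fid in range(config.n_fish)}
        for a in range(config.n_fish):
            for b in range(a + 1, config.n_fish):
                if np.any(masks[a] & masks[b]):
                    occluded[a] = occluded[b] = True

        if config.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, config.noise_sd, size=canvas.shape)
        frames.append(np.clip(np.round(canvas), 0, 255).astype(np.uint8))

        for fid in range(config.n_fish):
            p = poses[fid]
            hx, hy = head_point(p)
            rows.append((t, fid, hx, hy, p.center[0], p.center[1], p.bend, occluded[fid]))

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth["occluded"] = truth["occluded"].astype(bool)
    return frames, truth


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write ground truth to CSV (lossless round-trip via read_truth)."""
    truth.to_csv(path, index=False, columns=TRUTH_COLUMNS)


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRUTH_COLUMNS) - set(truth.columns)
    if missing:
        raise ValueError(f"truth file missing columns: {sorted(missing)}")
    truth["occluded"] = truth["occluded"].astype(bool)
    return truth[TRUTH_COLUMNS]
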