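"""Head boxes, ridge lines, line clustering and per-frame detection."""

import math

import numpy as np
import pytest

from schooltrack.detection import (
    BodyDetection,
    ClusterParams,
    DetectionConfig,
    RidgeLine,
    body_from_cluster,
    cluster_lines,
    detect_frame,
    detect_heads,
    detect_ridge_lines,
)
from schooltrack.segmentation import Blob, segment_blobs
from schooltrack.synthetic import centerline_points, head_point
from tests.conftest import brute_force_dbscan, make_fish_frame


def fish_blob(heading=0.3, bend=0.0, noise_sd=2.0, seed=0):
    frame, background, pose = make_fish_frame(heading=heading, bend=bend,
                                              noise_sd=noise_sd, seed=seed)
    blobs = segment_blobs(frame, background, context_margin=32)
    assert len(blobs) == 1
    return blobs[0], pose


class TestDetectHeads:
    def test_blank_patch_yields_nothing(self):
        patch = np.full((40, 40), 230, dtype=np.uint8)
        P = np.array([[5, 5], [6, 5]])
        blob = Blob(t=0, i=0, box=(5, 5, 2, 1), P=P, patch=patch[5:6, 5:7])
        assert detect_heads(blob) == []

    def test_single_fish_head_box_contains_truth(self):
        blob, pose = fish_blob()
        heads = detect_heads(blob)
        assert len(heads) == 1
        hx, hy = head_point(pose)
        x0, y0, x1, y1 = heads[0].box
        assert x0 <= hx <= x1 and y0 <= hy <= y1

    def test_head_box_lies_inside_blob_box(self):
        blob, _ = fish_blob(heading=1.1)
        (head,) = detect_heads(blob)
        bx, by, bw, bh = blob.box
        x0, y0, x1, y1 = head.box
        assert bx <= x0 <= x1 <= bx + bw - 1
        assert by <= y0 <= y1 <= by + bh - 1

    def test_two_separated_heads_in_one_blob(self):
        # two touching fish, heads at opposite ends, well over 2 sigma apart
        from schooltrack.synthetic import FishPose, render_fish

        canvas = np.full((120, 260), 230.0)
        p1 = FishPose(center=(100, 60), heading=math.pi)  # head at left
        p2 = FishPose(center=(150, 60), heading=0.0)  # head at right
        render_fish(p1, canvas)
        render_fish(p2, canvas)
        blobs = segment_blobs(canvas.astype(np.uint8),
                              np.full(canvas.shape, 230, dtype=np.uint8), context_margin=32)
        assert len(blobs) == 1
        heads = detect_heads(blobs[0])
        assert len(heads) == 2
        centers = sorted(h.center[0] for h in heads)
        h1, h2 = head_point(p1)[0], head_point(p2)[0]
        assert abs(centers[0] - h1) < 8 and abs(centers[1] - h2) < 8


class TestDetectRidgeLines:
    def test_blank_mask_yields_nothing(self):
        patch = np.full((30, 30), 230, dtype=np.uint8)
        P = np.array([[2, 2]])
        blob = Blob(t=0, i=0, box=(2, 2, 1, 1), P=P, patch=patch[2:3, 2:3])
        assert detect_ridge_lines(blob) == []

    def test_horizontal_fish_gives_lines_near_theta_90(self):
        blob, pose = fish_blob(heading=0.0, noise_sd=0.0)
        lines = detect_ridge_lines(blob)
        assert len(lines) >= 3
        # centerline is horizontal: normal angle theta = 90 degrees, rho = y
        y_local = head_point(pose)[1] - blob.box[1]
        for ln in lines:
            assert abs(math.degrees(ln.theta) - 90) < 3
            assert abs(ln.rho - y_local) < 3

    def test_translation_equivariance_of_body_point(self):
        # shifting the fish shifts R (in frame coordinates) by the same amount
        cfg = DetectionConfig()
        results = []
        for cx, cy in [(90.0, 90.0), (110.0, 115.0)]:
            frame, background, _ = make_fish_frame(heading=0.7, center=(cx, cy), noise_sd=0.0)
            _, bodies = detect_frame(frame, background, cfg)
            assert len(bodies) == 1
            results.append(bodies[0].R)
        dx = results[1][0] - results[0][0]
        dy = results[1][1] - results[0][1]
        assert dx == pytest.approx(20.0, abs=1.5)
        assert dy == pytest.approx(25.0, abs=1.5)


class TestClusterLines:
    def test_fewer_than_min_samples_is_noise(self):
        lines = [RidgeLine(0.0, 0.1), RidgeLine(1.0, 0.12)]
        assert cluster_lines(lines, ClusterParams(min_samples=3)) == []

    def test_duplicate_lines_form_one_cluster(self):
        lines = [RidgeLine(5.0, 0.3)] * 4
        clusters = cluster_lines(lines, ClusterParams(min_samples=3))
        assert len(clusters) == 1 and len(clusters[0]) == 4

    def test_two_distant_bundles_split(self):
        bundle1 = [RidgeLine(10.0 + 0.1 * k, 0.2 + 0.001 * k) for k in range(5)]
        bundle2 = [RidgeLine(150.0 + 0.1 * k, 1.7 + 0.001 * k) for k in range(5)]
        clusters = cluster_lines(bundle1 + bundle2)
        assert len(clusters) == 2
        assert {len(c) for c in clusters} == {5}

    def test_seam_straddling_bundle_stays_together(self):
        # nearly-vertical centerline: theta wraps around 0/pi
        lines = [RidgeLine(20.0, 0.01), RidgeLine(20.2, 0.02),
                 RidgeLine(-20.1, math.pi - 0.01), RidgeLine(-20.0, math.pi - 0.02)]
        clusters = cluster_lines(lines, ClusterParams(min_samples=3))
        assert len(clusters) == 1 and len(clusters[0]) == 4

    def test_matches_definition_dbscan(self, rng):
        params = ClusterParams()

        def metric(a, b):
            dr = (a[0] - b[0]) / params.rho_scale
            dt = (math.degrees(a[1]) - math.degrees(b[1])) / params.theta_scale
            half = 180.0 / params.theta_scale
            direct = dr * dr + dt * dt
            flipped = ((a[0] + b[0]) / params.rho_scale) ** 2 + (half - abs(dt)) ** 2
            return math.sqrt(min(direct, flipped))

        for _ in range(5):
            lines = [
                RidgeLine(float(rng.uniform(-40, 40)), float(rng.uniform(0, math.pi)))
                for _ in range(12)
            ]
            ours = cluster_lines(lines, params)
            X = [(ln.rho, ln.theta) for ln in lines]
            labels = brute_force_dbscan(X, params.eps, params.min_samples, metric)
            n_oracle = len({l for l in labels if l >= 0})
            assert len(ours) == n_oracle
            sizes_oracle = sorted(
                sum(1 for l in labels if l == c) for c in set(labels) if c >= 0
            )
            assert sorted(len(c) for c in ours) == sizes_oracle


class TestBodyFromCluster:
    def test_coordinate_axes_intersect_at_origin(self):
        det = body_from_cluster([RidgeLine(0.0, 0.0), RidgeLine(0.0, math.pi / 2)])
        assert det.R == pytest.approx((0.0, 0.0), abs=1e-9)
        assert det.omega == pytest.approx(90.0, abs=1e-9)

    def test_omega_is_max_minus_min_angle(self):
        lines = [RidgeLine(5.0, math.radians(t)) for t in (10, 25, 40)]
        assert body_from_cluster(lines).omega == pytest.approx(30.0, abs=1e-9)

    def test_parallel_bundle_falls_back_to_foot_points(self):
        lines = [RidgeLine(rho, math.radians(30)) for rho in (9.8, 9.9, 10.0, 10.1, 10.2)]
        det = body_from_cluster(lines)
        assert det.omega == pytest.approx(0.0, abs=1e-9)
        # R lies on the middle line x cos30 + y sin30 = 10
        residual = det.R[0] * math.cos(math.radians(30)) + det.R[1] * math.sin(math.radians(30))
        assert residual == pytest.approx(10.0, abs=0.05)

    def test_single_line_cluster_has_zero_omega(self):
        det = body_from_cluster([RidgeLine(3.0, 1.0)])
        assert det.omega == 0.0 and det.n_lines == 1

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            body_from_cluster([])

    def test_omega_capped_at_180(self):
        assert 0 <= body_from_cluster(
            [RidgeLine(0.0, 0.0), RidgeLine(0.0, 1.5), RidgeLine(0.0, 3.0)]
        ).omega <= 180


class TestDetectFrame:
    def test_background_only_frame_is_empty(self):
        frame = np.full((100, 100), 230, dtype=np.uint8)
        heads, bodies = detect_frame(frame, frame.copy())
        assert heads == [] and bodies == []

    def test_single_fish_full_pipeline(self):
        frame, background, pose = make_fish_frame(heading=2.1, noise_sd=2.0, seed=5)
        heads, bodies = detect_frame(frame, background)
        assert len(heads) == 1 and len(bodies) == 1
        hx, hy = head_point(pose)
        x0, y0, x1, y1 = heads[0].box
        assert x0 <= hx <= x1 and y0 <= hy <= y1
        cl = centerline_points(pose, step=0.5)
        d = np.hypot(cl[:, 0] - bodies[0].R[0], cl[:, 1] - bodies[0].R[1]).min()
        assert d <= 5.0

    def test_straight_fish_omega_small_bent_fish_larger(self):
        cfg = DetectionConfig()
        omegas = {}
        for bend in (0.0, math.radians(30)):
            frame, background, _ = make_fish_frame(heading=0.9, bend=bend,
                                                   noise_sd=2.0, seed=3)
            _, bodies = detect_frame(frame, background, cfg)
            assert len(bodies) == 1
            omegas[bend] = bodies[0].omega
        assert omegas[math.radians(30)] > omegas[0.0]

    def test_well_separated_school_fully_detected(self):
        from schooltrack.synthetic import FishPose, render_fish

        canvas = np.full((400, 400), 230.0)
        poses = [
            FishPose(center=(80, 80), heading=0.3),
            FishPose(center=(300, 90), heading=2.0),
            FishPose(center=(90, 300), heading=-1.2),
            FishPose(center=(310, 310), heading=2.8),
            FishPose(center=(200, 200), heading=1.0),
        ]
        for p in poses:
            render_fish(p, canvas)
        frame = np.clip(canvas, 0, 255).astype(np.uint8)
        background = np.full(canvas.shape, 230, dtype=np.uint8)
        heads, bodies = detect_frame(frame, background)
        assert len(heads) == 5 and len(bodies) == 5
        for p in poses:
            hx, hy = head_point(p)
            assert min(math.dist((hx, hy), h.center) for h in heads) <= 5
            cl = centerline_points(p, step=0.5)
            assert min(
                np.hypot(cl[:, 0] - b.R[0], cl[:, 1] - b.R[1]).min() for b in bodies
            ) <= 5


def test_body_detection_validates_fields():
    with pytest.raises(ValueError):
        BodyDetection(t=0, R=(0, 0), omega=-1.0, n_lines=1)
    with pytest.raises(ValueError):
        BodyDetection(t=0, R=(0, 0), omega=0.0, n_lines=0)
    with pytest.raises(ValueError):
        RidgeLine(rho=0.0, theta=math.pi)
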