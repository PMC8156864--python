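import math

import numpy as np
import pytest

from schooltrack.synthetic import FishPose, render_fish

ARENA_BG = 230


@pytest.fixture
def blank_frame():
    return np.full((200, 200), float(ARENA_BG))


def make_fish_frame(heading=0.3, bend=0.0, center=(100.0, 100.0), shape=(200, 200),
                    noise_sd=0.0, seed=0):
    """One rendered fish on a uniform background, optionally with pixel noise."""
    canvas = np.full(shape, float(ARENA_BG))
    pose = FishPose(center=center, heading=heading, bend=bend)
    render_fish(pose, canvas)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        canvas = canvas + rng.normal(0.0, noise_sd, canvas.shape)
    frame = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    background = np.full(shape, ARENA_BG, dtype=np.uint8)
    return frame, background, pose


@pytest.fixture
def single_fish():
    return make_fish_frame()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def brute_force_dbscan(X, eps, min_samples, metric):
    """Textbook DBSCAN by definition: core points + density reachability."""
    n = len(X)
    D = np.array([[metric(X[i], X[j]) for j in range(n)] for i in range(n)])
    neighbors = [set(np.flatnonzero(D[i] <= eps)) for i in range(n)]
    core = [len(nb) >= min_samples for nb in neighbors]
    labels = [-1] * n
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        # expand cluster from this core point
        stack = [i]
        labels[i] = cluster
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in neighbors[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                    stack.append(k)
        cluster += 1
    return labels


def flood_fill_components(mask):
    """Exhaustive 8-connected component labelling by BFS (oracle)."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for sy, sx in zip(*np.nonzero(mask)):
        if labels[sy, sx]:
            continue
        current += 1
        queue = [(sy, sx)]
        labels[sy, sx] = current
        while queue:
            y, x = queue.pop()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    yy, xx = y + dy, x + dx
                    if (0 <= yy < mask.shape[0] and 0 <= xx < mask.shape[1]
                            and mask[yy, xx] and not labels[yy, xx]):
                        labels[yy, xx] = current
                        queue.append((yy, xx))
    return labels, current


def brute_force_assignment_cost(C):
    """Exhaustive minimum assignment cost over all injections (oracle)."""
    import itertools

    n, m = C.shape
    if n == 0 or m == 0:
        return 0.0
    best = math.inf
    if n <= m:
        for perm in itertools.permutations(range(m), n):
            best = min(best, sum(C[i, perm[i]] for i in range(n)))
    else:
        for perm in itertools.permutations(range(n), m):
            best = min(best, sum(C[perm[j], j] for j in range(m)))
    return best
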