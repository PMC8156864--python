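"""Frame readers and trajectory/detection CSV writers.

Frame sources are either a directory of numbered images (PNG/TIFF; sorted
by filename) or a video file readable by imageio.  Frames are returned as
2-D uint8 grayscale arrays; color input is converted by the Rec. 601 luma
weighting.  All tables are plain CSV.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .tracking import TRAJECTORY_COLUMNS

__all__ = [
    "read_frames",
    "write_frames",
    "write_trajectory",
    "read_trajectory",
    "write_detections",
]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}
_LUMA = np.array([0.299, 0.587, 0.114])


def _to_gray(frame: np.ndarray) -> np.ndarray:
    if frame.ndim == 3:
        frame = frame[..., :3] @ _LUMA
        frame = np.clip(np.round(frame), 0, 255).astype(np.uint8)
    return np.asarray(frame, dtype=np.uint8)


def read_frames(path: str | Path):
    """Yield grayscale frames from a video file or an image directory in order."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES)
        if not files:
            raise FileNotFoundError(f"no PNG/TIFF frames in {path}")
        shape = None
        for f in files:
            frame = _to_gray(iio.imread(f))
            if shape is None:
                shape = frame.shape
            elif frame.shape != shape:
                raise ValueError(f"inconsistent frame shape in {f.name}: {frame.shape} vs {shape}")
            yield frame
    elif path.is_file():
        for frame in iio.imiter(path):
            yield _to_gray(np.asarray(frame))
    else:
        raise FileNotFoundError(path)


def write_frames(frames, out_dir: str | Path) -> list[Path]:
    """Write frames as zero-padded numbered PNGs (frame_000001.png ...)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, frame in enumerate(frames, start=1):
        p = out_dir / f"frame_{i:06d}.png"
        iio.imwrite(p, np.asarray(frame, dtype=np.uint8))
        paths.append(p)
    return paths


def write_trajectory(traj: pd.DataFrame, path: str | Path) -> None:
    traj.to_csv(path, index=False, columns=TRAJECTORY_COLUMNS)


def read_trajectory(path: str | Path) -> pd.DataFrame:
    traj = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRAJECTORY_COLUMNS) - set(traj.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns: {sorted(missing)}")
    return traj[TRAJECTORY_COLUMNS]


def write_detections(heads, bodies, path: str | Path) -> None:
    """Detections as CSV: head rows carry the box, body rows carry (R, omega)."""
    rows = []
    for h in heads:
        rows.append((h.t, "head", *h.box, "", "", ""))
    for b in bodies:
        rows.append((b.t, "body", "", "", "", "", b.R[0], b.R[1], b.omega))
    pd.DataFrame(
        rows, columns=["frame", "kind", "x0", "y0", "x1", "y1", "rx", "ry", "omega"]
    ).to_csv(path, index=False)
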