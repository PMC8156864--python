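"""Constant-velocity Kalman filter for planar point tracking.

State is (u, v, du, dv): image-plane position in pixels and velocity in
pixels/frame; only the position is observed.  Box size is deliberately not
part of the state — a fish head keeps a near-constant apparent size in
top-view footage, so the tracker handles box geometry separately from the
motion filter.
"""

from __future__ import annotations

import numpy as np

__all__ = ["PointKalman"]

_F = np.array(
    [
        [1.0, 0.0, 1.0, 0.0],
        [0.0, 1.0, 0.0, 1.0],
        [0.0, 0.0, 1.0, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)
_H = np.array([[1.0, 0.0, 0.0, 0.0], [0.0, 1.0, 0.0, 0.0]])


class PointKalman:
    """Linear Kalman filter with a constant-velocity motion model (dt = 1 frame).

    Parameters
    ----------
    xy : initial observed position (px)
    process_noise : scale of the white-acceleration process noise, in
        px/frame^2; set to roughly the expected per-frame speed change
    measurement_noise : position measurement variance, px^2
    """

    def __init__(
        self,
        xy: tuple[float, float],
        process_noise: float = 1.0,
        measurement_noise: float = 1.0,
    ):
        self.x = np.array([xy[0], xy[1], 0.0, 0.0])
        # velocity unknown at birth: large variance lets the second
        # observation set it almost exactly
        self.P = np.diag([measurement_noise, measurement_noise, 1e3, 1e3])
        q = process_noise**2
        # discrete white-acceleration model, dt = 1
        self.Q = q * np.array(
            [
                [0.25, 0.0, 0.5, 0.0],
                [0.0, 0.25, 0.0, 0.5],
                [0.5, 0.0, 1.0, 0.0],
                [0.0, 0.5, 0.0, 1.0],
            ]
        )
        self.R = measurement_noise * np.eye(2)

    def predict(self) -> tuple[float, float]:
        """Advance one frame; returns the predicted position."""
        self.x = _F @ self.x
        self.P = _F @ self.P @ _F.T + self.Q
        return float(self.x[0]), float(self.x[1])

    def update(self, xy: tuple[float, float]) -> None:
        """Fold in an observed position."""
        z = np.asarray(xy, dtype=float)
        y = z - _H @ self.x
        S = _H @ self.P @ _H.T + self.R
        K = self.P @ _H.T @ np.linalg.inv(S)
        self.x = self.x + K @ y
        self.P = (np.eye(4) - K @ _H) @ self.P

    @property
    def position(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[1])

    @property
    def velocity(self) -> tuple[float, float]:
        return float(self.x[2]), float(self.x[3])

    def shift(self, dx: float, dy: float) -> None:
        """Translate the state without touching velocity or covariance.

        Used when an external cue (the body-fallback path) relocates a
        track whose own feature went undetected.
        """
        self.x[0] += dx
        self.x[1] += dy
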