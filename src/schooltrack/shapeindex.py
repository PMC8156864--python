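"""Hessian-based shape index and Koenderink surface-type classification.

The grayscale frame is treated as a height field.  At a Gaussian scale
``sigma`` the local second-order structure is the Hessian of the smoothed
image; its eigenvalues ``K1 >= K2`` describe the principal curvatures, and
the shape index

    s = (2/pi) * arctan((K1 + K2) / (K2 - K1))

maps the local geometry onto [-1, 1] independently of curvature magnitude.
With this sign convention a dark local minimum (both eigenvalues positive,
e.g. a fish head on a bright background) scores s = -1 ("spherical cup")
and a dark line (one positive, one near-zero eigenvalue, e.g. the fish body
centerline) scores s = -1/2 ("rut"); bright structures mirror to +1/2 and
+1.  Flat regions (K1 = K2 = 0) have no defined shape and are masked out.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d

__all__ = [
    "ShapeCategory",
    "HessianField",
    "ShapeIndexMap",
    "hessian_response",
    "hessian_eigenvalues",
    "shape_index",
    "classify_shape_category",
    "shape_index_map",
]


class ShapeCategory(enum.IntEnum):
    """The nine Koenderink surface types plus an explicit undefined marker.

    Ordered by shape-index interval from s = -1 (spherical cup, a dark
    local minimum) to s = +1 (spherical cap, a bright local maximum).
    """

    UNDEFINED = -1
    SPHERICAL_CUP = 0
    TROUGH = 1
    RUT = 2
    SADDLE_RUT = 3
    SADDLE = 4
    SADDLE_RIDGE = 5
    RIDGE = 6
    DOME = 7
    SPHERICAL_CAP = 8


#: Left edges of the nine category intervals on [-1, 1].  Intervals are
#: half-open, closed on the left; the last interval is closed on both ends.
CATEGORY_EDGES = np.array(
    [-1.0, -7 / 8, -5 / 8, -3 / 8, -1 / 8, 1 / 8, 3 / 8, 5 / 8, 7 / 8]
)


@dataclass(frozen=True)
class HessianField:
    """Second-order Gaussian derivative responses of an image at one scale."""

    Lxx: np.ndarray
    Lxy: np.ndarray
    Lyy: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        if not (self.Lxx.shape == self.Lxy.shape == self.Lyy.shape):
            raise ValueError("Lxx, Lxy, Lyy must share a shape")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass(frozen=True)
class ShapeIndexMap:
    """Per-pixel shape index, eigenvalue fields and category labels."""

    s: np.ndarray
    K1: np.ndarray
    K2: np.ndarray
    category: np.ndarray
    defined: np.ndarray
    sigma: float


def _gaussian_derivative_kernels(sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampled Gaussian and its first two derivatives, moment-corrected.

    Truncating a sampled Gaussian derivative leaves small non-zero low-order
    moments, so the raw kernels neither annihilate constants exactly nor
    report the curvature of x^2 as exactly 2.  The corrections below restore
    the defining discrete moment conditions:

    * smoothing kernel: sum = 1
    * first derivative: odd, response to the ramp f(x) = x equals 1
    * second derivative: even, zero mean, response to f(x) = x^2 equals 2
    """
    radius = max(1, int(math.ceil(4.0 * sigma)))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-0.5 * (x / sigma) ** 2)
    g /= g.sum()
    g1 = -x / sigma**2 * g
    g1 -= g1.mean()  # enforce odd-moment exactness under truncation
    # convolution response to f(x) = x is -sum(k * x)
    g1 /= -(g1 @ x)
    g2 = (x**2 - sigma**2) / sigma**4 * g
    g2 -= g2.mean()  # annihilate constants exactly
    g2 *= 2.0 / (g2 @ x**2)  # curvature of x^2 is exactly 2
    return g, g1, g2


def hessian_response(image: np.ndarray, sigma: float) -> HessianField:
    """Convolve ``image`` with the second-order derivatives of a Gaussian.

    x is the column axis, y the row axis.  Boundary handling is mirror
    reflection; kernels are truncated at 4 sigma and moment-corrected so
    that polynomial test images give exact responses.

    Parameters
    ----------
    image : 2-D array
        Grayscale image; converted to float64 internally.
    sigma : float
        Standard deviation of the Gaussian, in pixels.  Must be > 0.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    g, g1, g2 = _gaussian_derivative_kernels(sigma)

    def sep(kernel_y, kernel_x):
        out = convolve1d(img, kernel_y, axis=0, mode="reflect")
        return convolve1d(out, kernel_x, axis=1, mode="reflect")

    Lxx = sep(g, g2)
    Lyy = sep(g2, g)
    Lxy = sep(g1, g1)
    return HessianField(Lxx=Lxx, Lxy=Lxy, Lyy=Lyy, sigma=float(sigma))


def hessian_eigenvalues(field: HessianField) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form eigenvalues of the 2x2 Hessian, ordered K1 >= K2 pointwise."""
    tr = field.Lxx + field.Lyy
    disc = np.sqrt((field.Lxx - field.Lyy) ** 2 + 4.0 * field.Lxy**2)
    K1 = 0.5 * (tr + disc)
    K2 = 0.5 * (tr - disc)
    return K1, K2


def shape_index(K1: np.ndarray, K2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape index s = (2/pi) arctan((K1+K2)/(K2-K1)) with an undefined mask.

    Umbilic points (K1 == K2 != 0) take the directional limit s = -sign(K1):
    equal positive eigenvalues are a dark local minimum, s = -1.  Fully flat
    points (K1 == K2 == 0) are undefined.

    Returns
    -------
    s : float array, NaN where undefined
    defined : bool array
    """
    K1 = np.asarray(K1, dtype=np.float64)
    K2 = np.asarray(K2, dtype=np.float64)
    if np.any(K1 < K2 - 1e-9 * np.maximum(1.0, np.abs(K1) + np.abs(K2))):
        raise ValueError("requires K1 >= K2 pointwise")
    denom = K2 - K1
    umbilic = denom == 0
    flat = umbilic & (K1 == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = (2.0 / np.pi) * np.arctan((K2 + K1) / denom)
    s = np.where(umbilic, -np.sign(K1), s)
    s = np.where(flat, np.nan, s)
    defined = ~flat
    return s, defined


def classify_shape_category(
    s: np.ndarray, defined: np.ndarray | None = None
) -> np.ndarray:
    """Label each pixel with its Koenderink category.

    Intervals are closed on the left: [-1,-7/8) cup, [-7/8,-5/8) trough,
    [-5/8,-3/8) rut, [-3/8,-1/8) saddle rut, [-1/8,1/8) saddle,
    [1/8,3/8) saddle ridge, [3/8,5/8) ridge, [5/8,7/8) dome,
    [7/8,1] spherical cap.  Undefined pixels stay UNDEFINED.
    """
    s = np.asarray(s, dtype=np.float64)
    if defined is None:
        defined = ~np.isnan(s)
    vals = np.where(defined, s, 0.0)
    if np.any((vals < -1) | (vals > 1)):
        raise ValueError("shape index values must lie in [-1, 1]")
    # searchsorted(side='right') - 1 gives left-closed bins; s = 1 falls in
    # the last bin because the top edge 7/8 is the final left edge.
    idx = np.searchsorted(CATEGORY_EDGES, vals, side="right") - 1
    cat = idx.astype(np.int8)
    cat[~defined] = int(ShapeCategory.UNDEFINED)
    return cat


def shape_index_map(image: np.ndarray, sigma: float) -> ShapeIndexMap:
    """Full pipeline: Hessian -> eigenvalues -> shape index -> categories."""
    field = hessian_response(image, sigma)
    K1, K2 = hessian_eigenvalues(field)
    s, defined = shape_index(K1, K2)
    cat = classify_shape_category(s, defined)
    return ShapeIndexMap(s=s, K1=K1, K2=K2, category=cat, defined=defined, sigma=float(sigma))
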