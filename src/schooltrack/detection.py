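"""Multi-feature fish detection: cup-region heads and ridge-line bodies.

Two redundant appearance features are extracted per blob, each from the
shape index at its own scale:

* **Heads** — connected components of the "spherical cup" category at
  ``sigma_head``, size-filtered; each yields a bounding box in frame
  coordinates.  The fish head is an opaque dark blob, hence a concave
  local minimum of the backlit image.
* **Bodies** — the body centerline is a dark line ("rut" category, or
  "ridge" for bright-on-dark footage) at ``sigma_ridge``; a Hough
  transform over the centerline mask yields a bundle of (rho, theta)
  lines per fish, which DBSCAN groups into one cluster per individual.
  Each cluster is summarised as a body point R (least-squares
  intersection of its lines) and a motion state omega, the angular
  spread max(theta) - min(theta) in degrees: small omega means a
  straight, steadily swimming fish, large omega a bending or turning
  one.

Heads and bodies are deliberately *not* paired here; identity association
is the tracker's job, which lets either feature recover a fish the other
missed (e.g. a head hidden during an occlusion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.transform import hough_line
from sklearn.cluster import DBSCAN

from .segmentation import Blob, segment_blobs
from .shapeindex import (
    ShapeCategory,
    classify_shape_category,
    hessian_eigenvalues,
    hessian_response,
    shape_index,
    shape_index_map,
)

__all__ = [
    "HeadDetection",
    "RidgeLine",
    "BodyDetection",
    "HoughParams",
    "ClusterParams",
    "DetectionConfig",
    "detect_heads",
    "detect_ridge_lines",
    "cluster_lines",
    "body_from_cluster",
    "detect_frame",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class HeadDetection:
    """A fish-head candidate: bounding box of one cup component."""

    t: int
    box: tuple[float, float, float, float]  # (x0, y0, x1, y1), frame coords
    area: int

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.box
        return (0.5 * (x0 + x1), 0.5 * (y0 + y1))


@dataclass(frozen=True)
class RidgeLine:
    """A centerline candidate in normal form x cos(theta) + y sin(theta) = rho.

    rho is the signed perpendicular distance from the (blob-local) origin
    in pixels; theta is the normal angle in [0, pi).  votes is the Hough
    accumulator count, kept for diagnostics.
    """

    rho: float
    theta: float
    votes: int = 0
    # centroid of the inlier pixels the line was refined on (blob-local);
    # anchors the parallel-bundle fallback in body_from_cluster
    anchor: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.theta < math.pi):
            raise ValueError("theta must lie in [0, pi)")


@dataclass(frozen=True)
class BodyDetection:
    """A fish-body candidate: cluster point R, motion state omega, body axis.

    axis is the along-body direction in radians modulo pi (the circular
    mean of the cluster's line directions); it lets the tracker rotate the
    head-minus-body offset when a fish turns while its head is unseen.
    """

    t: int
    R: tuple[float, float]  # frame coordinates
    omega: float  # degrees, >= 0
    n_lines: int
    axis: float = 0.0  # radians, mod pi

    def __post_init__(self) -> None:
        if not (0 <= self.omega <= 180):
            raise ValueError("omega must lie in [0, 180]")
        if self.n_lines < 1:
            raise ValueError("n_lines must be >= 1")


@dataclass
class HoughParams:
    """Hough transform settings for centerline lines.

    The vote threshold is relative: all accumulator *peaks* (3x3
    plateau-inclusive local maxima) with at least ``vote_min_frac`` of the
    blob's maximum vote are returned, so the line count adapts to fish
    length.  theta resolution is 1 degree, rho resolution 1 px.
    """

    theta_res_deg: float = 1.0
    vote_min_frac: float = 0.25
    vote_min_abs: int = 5  # absolute floor, rejects near-empty masks


@dataclass
class ClusterParams:
    """DBSCAN settings over normalised (rho/rho_scale, theta/theta_scale)."""

    rho_scale: float = 10.0  # px
    theta_scale: float = 10.0  # degrees
    eps: float = 1.0
    min_samples: int = 3


@dataclass
class DetectionConfig:
    """Everything the per-frame detector needs."""

    sigma_head: float = 8.0
    sigma_ridge: float = 4.0
    centerline_polarity: str = "dark"  # "dark" fish on bright bg, or "bright"
    head_area_min: int = 18
    head_area_max: int = 400
    diff_threshold: float = 25.0
    area_min: int = 100
    area_max: int = 50_000
    hough: HoughParams = field(default_factory=HoughParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)

    def __post_init__(self) -> None:
        if self.centerline_polarity not in ("dark", "bright"):
            raise ValueError("centerline_polarity must be 'dark' or 'bright'")
        if self.sigma_head <= 0 or self.sigma_ridge <= 0:
            raise ValueError("sigmas must be positive")


def _blob_category(blob: Blob, sigma: float) -> np.ndarray:
    """Shape categories over the blob's tight box.

    The shape index is computed on the context patch (box plus margin) so
    that the Gaussian sees real image content beyond the tight box, then
    cropped back to the box.
    """
    smap = shape_index_map(blob.context, sigma)
    ox, oy = blob.context_offset
    x0, y0, w, h = blob.box
    return smap.category[y0 - oy : y0 - oy + h, x0 - ox : x0 - ox + w]


def _blob_category_mask(blob: Blob, sigma: float, category: ShapeCategory) -> np.ndarray:
    """Category mask over the blob's tight box, restricted to its pixels P."""
    if blob.patch.size == 0:
        return np.zeros((0, 0), dtype=bool)
    return (_blob_category(blob, sigma) == category) & blob.mask


def _valley_nms(Lxx, Lxy, Lyy, K1, K2, band, polarity: str):
    """Thin a valley (or crest) band to its centerline by non-maximum suppression.

    A dark line's cross-section is a valley: the strong positive eigenvalue
    K1 peaks exactly on the valley floor, along its own eigenvector (the
    across-line direction).  Keeping only band pixels where that curvature
    is a local maximum along the eigen-direction yields a one- to two-pixel
    centerline that, unlike a medial axis, does not fork at blunt band
    ends.  For bright polarity the roles of K1 and K2 swap.
    """
    strength = K1 if polarity == "dark" else -K2
    k = K1 if polarity == "dark" else K2
    # eigenvector of the selected eigenvalue: (Lxy, k - Lxx); when the
    # Hessian is already diagonal pick the matching coordinate axis
    vx = np.where(np.abs(Lxy) > 1e-12, Lxy, np.where(np.abs(Lxx - k) <= np.abs(Lyy - k), 1.0, 0.0))
    vy = np.where(np.abs(Lxy) > 1e-12, k - Lxx, np.where(np.abs(Lxx - k) <= np.abs(Lyy - k), 0.0, 1.0))
    norm = np.hypot(vx, vy)
    norm[norm < 1e-12] = 1.0
    vx, vy = vx / norm, vy / norm

    H, W = strength.shape
    yy, xx = np.mgrid[0:H, 0:W]

    def _sample(dx, dy):
        sx = np.clip(xx + dx, 0, W - 1)
        sy = np.clip(yy + dy, 0, H - 1)
        x0, y0 = np.floor(sx).astype(int), np.floor(sy).astype(int)
        x1, y1 = np.minimum(x0 + 1, W - 1), np.minimum(y0 + 1, H - 1)
        fx, fy = sx - x0, sy - y0
        return (
            strength[y0, x0] * (1 - fx) * (1 - fy)
            + strength[y0, x1] * fx * (1 - fy)
            + strength[y1, x0] * (1 - fx) * fy
            + strength[y1, x1] * fx * fy
        )

    ahead = _sample(vx, vy)
    behind = _sample(-vx, -vy)
    return band & (strength >= ahead) & (strength >= behind)


def _centerline_mask(blob: Blob, sigma_ridge: float, polarity: str) -> np.ndarray:
    """Thin body-centerline mask in blob-local (tight box) coordinates.

    Starts from the line category at ``sigma_ridge`` (rut for dark fish,
    ridge for bright), restricted to the blob pixels.  Two cleanups follow:

    * Every dark blob (head disk, tail cap) is wrapped by a ring of
      line-category pixels at its inflection radius; chords through such a
      ring masquerade as body lines at arbitrary angles.  Rings encircle a
      concave region at the same scale, so line pixels within 1.5 sigma of
      a blob-scale cup/trough component (dome/cap for bright polarity) are
      removed; speckle-sized concave components are curvature noise and
      cast no halo.
    * The surviving band is thinned to the valley floor by eigen-direction
      non-maximum suppression, so Hough votes measure centerline length,
      not band width.
    """
    if blob.patch.size == 0:
        return np.zeros((0, 0), dtype=bool)
    field = hessian_response(blob.context, sigma_ridge)
    K1f, K2f = hessian_eigenvalues(field)
    s, defined = shape_index(K1f, K2f)
    cats_full = classify_shape_category(s, defined)
    ox, oy = blob.context_offset
    x0, y0, w, h = blob.box
    crop = (slice(y0 - oy, y0 - oy + h), slice(x0 - ox, x0 - ox + w))
    cats = cats_full[crop]
    if polarity == "dark":
        line_cat, blob_cats = ShapeCategory.RUT, (ShapeCategory.SPHERICAL_CUP, ShapeCategory.TROUGH)
    else:
        line_cat, blob_cats = ShapeCategory.RIDGE, (ShapeCategory.SPHERICAL_CAP, ShapeCategory.DOME)
    mask = (cats == line_cat) & blob.mask
    concave = np.isin(cats, blob_cats)
    # only blob-scale concave components cast halos; isolated speckle
    # pixels along the band edge are curvature noise, not blobs
    labels, n = ndimage.label(concave, structure=_STRUCT8)
    if n:
        areas = ndimage.sum_labels(np.ones_like(labels, dtype=float), labels, range(1, n + 1))
        keep = np.flatnonzero(areas >= 2 * sigma_ridge**2) + 1
        concave = np.isin(labels, keep)
    if concave.any():
        r = int(math.ceil(1.5 * sigma_ridge))
        dy, dx = np.ogrid[-r : r + 1, -r : r + 1]
        halo = ndimage.binary_dilation(concave, structure=dx**2 + dy**2 <= r**2)
        mask &= ~halo
    if mask.any():
        mask = _valley_nms(
            field.Lxx[crop], field.Lxy[crop], field.Lyy[crop],
            K1f[crop], K2f[crop], mask, polarity,
        )
    return mask


def _refine_line(
    mask_points: np.ndarray, rho: float, theta: float, tol: float = 1.5, n_iter: int = 2
) -> tuple[float, float, tuple[float, float] | None]:
    """Snap a quantized Hough line onto its inlier pixels by iterated PCA.

    Accumulator bins are 1 px x 1 degree; the principal axis of the pixels
    within ``tol`` of the line recovers rho and theta to sub-bin precision.
    Iterating the fit lets every collinear chord of one straight centerline
    converge onto the same refined line, while chords of a bent centerline
    settle on their local tangent.  Returns (rho, theta, inlier centroid).
    """
    anchor = None
    for _ in range(n_iter):
        d = np.abs(mask_points[:, 0] * math.cos(theta) + mask_points[:, 1] * math.sin(theta) - rho)
        inl = mask_points[d <= tol]
        if len(inl) < 3:
            break
        c = inl.mean(axis=0)
        cov = np.cov((inl - c).T)
        _, vecs = np.linalg.eigh(cov)
        vx, vy = vecs[:, 1]  # principal (along-line) direction
        theta = (math.atan2(vy, vx) + math.pi / 2) % math.pi
        rho = float(c[0] * math.cos(theta) + c[1] * math.sin(theta))
        anchor = (float(c[0]), float(c[1]))
    return rho, theta % math.pi, anchor


def detect_heads(
    blob: Blob,
    sigma_head: float = 8.0,
    head_area_min: int = 18,
    head_area_max: int = 400,
) -> list[HeadDetection]:
    """Detect fish heads in one blob as size-filtered cup components.

    The cup mask is morphologically closed (disk of radius ~sigma_head/4)
    before labelling: a strongly bent fish can pinch its concave head
    region into two fragments, and closing restores one component per
    head without bridging distinct heads, which sit much farther apart.
    """
    mask = _blob_category_mask(blob, sigma_head, ShapeCategory.SPHERICAL_CUP)
    if mask.size == 0 or not mask.any():
        return []
    r = max(1, int(round(sigma_head / 4)))
    dy, dx = np.ogrid[-r : r + 1, -r : r + 1]
    mask = ndimage.binary_closing(mask, structure=dx**2 + dy**2 <= r**2)
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    x0b, y0b = blob.box[0], blob.box[1]
    out = []
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        comp = labels[sl] == lab
        area = int(comp.sum())
        if not (head_area_min <= area <= head_area_max):
            continue
        ys, xs = sl
        out.append(
            HeadDetection(
                t=blob.t,
                box=(
                    float(x0b + xs.start),
                    float(y0b + ys.start),
                    float(x0b + xs.stop - 1),
                    float(y0b + ys.stop - 1),
                ),
                area=area,
            )
        )
    return out


def _accumulator_peaks(acc: np.ndarray, vote_min: float) -> list[tuple[int, int, int]]:
    """(rho_idx, theta_idx, votes) of per-column local maxima above vote_min.

    Maxima are plateau-inclusive along the rho axis within each theta
    column: a digital straight line spreads its votes over neighbouring
    theta bins, and keeping each column's rho-peaks (rather than one global
    peak) supplies the redundant line bundle the clustering stage expects;
    the PCA refinement later collapses duplicates of one physical line.
    """
    if acc.size == 0:
        return []
    local_max = acc == ndimage.maximum_filter(acc, size=(3, 1), mode="constant")
    peaks = np.argwhere(local_max & (acc >= vote_min))
    return [(int(i), int(j), int(acc[i, j])) for i, j in peaks]


def detect_ridge_lines(
    blob: Blob,
    sigma_ridge: float = 4.0,
    centerline_polarity: str = "dark",
    hough: HoughParams | None = None,
) -> list[RidgeLine]:
    """Detect the fish-body centerline as a bundle of Hough lines.

    Lines are expressed in blob-local coordinates (origin at the blob box
    top-left); ``detect_frame`` translates the derived body point back to
    frame coordinates.  Many lines per fish are expected and wanted — the
    clustering step aggregates the bundle and its angular spread is the
    motion state.
    """
    hough = hough or HoughParams()
    mask = _centerline_mask(blob, sigma_ridge, centerline_polarity)
    if mask.size == 0 or not mask.any():
        return []
    thetas = np.deg2rad(np.arange(0.0, 180.0, hough.theta_res_deg))
    acc, theta_vals, rho_vals = hough_line(mask, theta=thetas)
    vote_min = max(hough.vote_min_abs, hough.vote_min_frac * acc.max())
    yy, xx = np.nonzero(mask)
    pts = np.column_stack([xx, yy]).astype(float)
    out = []
    for i, j, votes in _accumulator_peaks(acc, vote_min):
        rho, theta, anchor = _refine_line(pts, float(rho_vals[i]), float(theta_vals[j]))
        out.append(RidgeLine(rho=rho, theta=theta, votes=votes, anchor=anchor))
    return out


def _line_distance_matrix(lines: list[RidgeLine], params: ClusterParams) -> np.ndarray:
    """Pairwise distance in normalised (rho, theta) space, seam-aware.

    A line (rho, theta) equals (-rho, theta +/- pi); the distance takes the
    minimum over the two representations so bundles straddling the 0/pi
    seam stay together.
    """
    rho = np.array([ln.rho for ln in lines]) / params.rho_scale
    th = np.array([math.degrees(ln.theta) for ln in lines]) / params.theta_scale
    half_turn = 180.0 / params.theta_scale
    d_rho = rho[:, None] - rho[None, :]
    d_th = th[:, None] - th[None, :]
    direct = d_rho**2 + d_th**2
    flipped = (rho[:, None] + rho[None, :]) ** 2 + (half_turn - np.abs(d_th)) ** 2
    return np.sqrt(np.minimum(direct, flipped))


def cluster_lines(
    lines: list[RidgeLine], params: ClusterParams | None = None
) -> list[list[RidgeLine]]:
    """Group ridge lines into one cluster per fish with DBSCAN.

    Features are (rho/rho_scale, theta/theta_scale); lines labelled noise
    are discarded.  Clusters are returned in order of their smallest
    member index, for determinism.
    """
    params = params or ClusterParams()
    if len(lines) < params.min_samples:
        return []
    D = _line_distance_matrix(lines, params)
    labels = DBSCAN(eps=params.eps, min_samples=params.min_samples, metric="precomputed").fit_predict(D)
    clusters: dict[int, list[RidgeLine]] = {}
    order: dict[int, int] = {}
    for idx, (lab, ln) in enumerate(zip(labels, lines)):
        if lab < 0:
            continue
        clusters.setdefault(lab, []).append(ln)
        order.setdefault(lab, idx)
    return [clusters[lab] for lab in sorted(clusters, key=order.get)]


def _unwrap_thetas(lines: list[RidgeLine]) -> np.ndarray:
    """Thetas (radians) unwrapped across the 0/pi seam about the circular mean.

    The circular mean is taken with period pi (doubled-angle trick); members
    more than pi/2 away are shifted by pi so max-min is meaningful.
    """
    th = np.array([ln.theta for ln in lines])
    mean = 0.5 * math.atan2(np.sin(2 * th).sum(), np.cos(2 * th).sum()) % math.pi
    dev = (th - mean + math.pi / 2) % math.pi - math.pi / 2
    return mean + dev


def body_from_cluster(cluster: list[RidgeLine], t: int = 0) -> BodyDetection:
    """Summarise one line cluster as a body point R and motion state omega.

    R minimises the summed squared line residuals
    sum_j (x cos(theta_j) + y sin(theta_j) - rho_j)^2.  When the normal
    equations are singular (all lines parallel within tolerance) R falls
    back to the centroid of the per-line foot points
    (rho cos(theta), rho sin(theta)).  omega = max(theta) - min(theta) in
    degrees after seam unwrapping, capped at 180.
    """
    if not cluster:
        raise ValueError("empty cluster")
    th = _unwrap_thetas(cluster)
    omega = min(180.0, math.degrees(float(th.max() - th.min())))
    axis = (float(th.mean()) + math.pi / 2) % math.pi  # along-body direction

    cos = np.array([math.cos(ln.theta) for ln in cluster])
    sin = np.array([math.sin(ln.theta) for ln in cluster])
    rho = np.array([ln.rho for ln in cluster])
    A = np.array([[np.sum(cos * cos), np.sum(cos * sin)], [np.sum(cos * sin), np.sum(sin * sin)]])
    b = np.array([np.sum(rho * cos), np.sum(rho * sin)])
    # normal-equation conditioning: parallel bundles are rank 1
    w = np.linalg.eigvalsh(A)
    if w[0] < 1e-4 * max(w[1], 1e-12):
        # parallel bundle: the intersection is unconstrained along the line;
        # anchor on the lines' own pixel support when available, else on the
        # per-line foot points of the origin
        anchors = [ln.anchor for ln in cluster if ln.anchor is not None]
        if anchors:
            R = np.mean(anchors, axis=0)
        else:
            foot = np.column_stack([rho * cos, rho * sin])
            R = foot.mean(axis=0)
    else:
        R = np.linalg.solve(A, b)
    return BodyDetection(
        t=t, R=(float(R[0]), float(R[1])), omega=omega, n_lines=len(cluster), axis=axis
    )


def detect_frame(
    frame: np.ndarray,
    background: np.ndarray,
    config: DetectionConfig | None = None,
    t: int = 0,
) -> tuple[list[HeadDetection], list[BodyDetection]]:
    """Run the full detection stage on one frame.

    Segments moving blobs, then per blob detects head boxes and ridge-line
    clusters; each cluster's body point is translated from blob-local to
    frame coordinates.
    """
    config = config or DetectionConfig()
    heads: list[HeadDetection] = []
    bodies: list[BodyDetection] = []
    blobs = segment_blobs(
        frame,
        background,
        diff_threshold=config.diff_threshold,
        area_min=config.area_min,
        area_max=config.area_max,
        t=t,
        context_margin=int(math.ceil(4 * max(config.sigma_head, config.sigma_ridge))),
    )
    for blob in blobs:
        heads.extend(
            detect_heads(blob, config.sigma_head, config.head_area_min, config.head_area_max)
        )
        lines = detect_ridge_lines(
            blob, config.sigma_ridge, config.centerline_polarity, config.hough
        )
        for cl in cluster_lines(lines, config.cluster):
            det = body_from_cluster(cl, t=t)
            bodies.append(
                BodyDetection(
                    t=t,
                    R=(det.R[0] + blob.box[0], det.R[1] + blob.box[1]),
                    omega=det.omega,
                    n_lines=det.n_lines,
                    axis=det.axis,
                )
            )
    return heads, bodies
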