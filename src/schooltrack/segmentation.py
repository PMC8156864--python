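"""Background modelling and moving-blob segmentation.

A static background is built by per-pixel temporal median filtering over the
first ``n`` frames of a sequence (fish occupy any given pixel only briefly,
so the median recovers the empty arena).  Moving regions are then the
connected components of the thresholded absolute difference between a frame
and the background, size-filtered to reject noise specks and non-fish
artifacts.

Coordinate convention, used throughout the package: origin at the top-left,
x rightward (columns), y downward (rows), 0-based; boxes are half-open
[x, x+w) x [y, y+h).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = ["Blob", "build_background", "segment_blobs"]

#: 8-connectivity structuring element for component labelling (merges
#: diagonally-touching fin pixels into one blob).
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class Blob:
    """A segmented moving region within one frame.

    Attributes
    ----------
    t : frame index
    i : blob index within the frame, assigned in raster order of the
        bounding-box top-left corner
    box : (x, y, w, h) tight bounding box of the foreground pixels
    P : (n, 2) int array of foreground pixel coordinates as (x, y) pairs
    patch : grayscale sub-image of the frame over the box
    context : grayscale sub-image over the box inflated by ``margin`` px
        (clipped to the frame); gives scale-space filters real image
        content beyond the tight box instead of reflection artifacts
    context_offset : (x, y) frame coordinates of the context's top-left
    """

    t: int
    i: int
    box: tuple[int, int, int, int]
    P: np.ndarray
    patch: np.ndarray
    context: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    context_offset: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.context is None:
            self.context = self.patch
            self.context_offset = (self.box[0], self.box[1])

    @property
    def mask(self) -> np.ndarray:
        """Boolean foreground mask over the tight box."""
        x, y, w, h = self.box
        m = np.zeros((h, w), dtype=bool)
        m[self.P[:, 1] - y, self.P[:, 0] - x] = True
        return m


def build_background(frames, n: int | None = None) -> np.ndarray:
    """Per-pixel temporal median over the first ``n`` frames.

    For an even number of frames the lower of the two central values is
    taken, so an integer input yields an exactly representable integer
    background.

    Parameters
    ----------
    frames : iterable of 2-D arrays, all the same shape
    n : number of frames to use; default all supplied frames
    """
    stack = []
    for k, f in enumerate(frames):
        if n is not None and k >= n:
            break
        stack.append(np.asarray(f))
    if not stack:
        raise ValueError("no frames supplied to build_background")
    arr = np.stack(stack, axis=0)
    if arr.ndim != 3:
        raise ValueError("frames must all be 2-D and share a shape")
    m = arr.shape[0]
    # lower median: element at index (m-1)//2 of the sorted stack
    part = np.partition(arr, (m - 1) // 2, axis=0)
    return part[(m - 1) // 2]


def segment_blobs(
    frame: np.ndarray,
    background: np.ndarray,
    diff_threshold: float = 25.0,
    area_min: int = 100,
    area_max: int = 50_000,
    t: int = 0,
    context_margin: int = 32,
) -> list[Blob]:
    """Extract size-filtered moving blobs from one frame.

    Foreground is ``|background - frame| > diff_threshold`` (absolute
    difference, so both dark-on-bright and bright-on-dark footage work);
    8-connected components with pixel count outside [area_min, area_max]
    are discarded.
    """
    frame = np.asarray(frame)
    background = np.asarray(background)
    if frame.shape != background.shape:
        raise ValueError("frame and background must share a shape")
    if not (0 < area_min < area_max):
        raise ValueError("need 0 < area_min < area_max")

    diff = np.abs(background.astype(np.int64) - frame.astype(np.int64))
    fg = diff > diff_threshold
    labels, n_labels = ndimage.label(fg, structure=_STRUCT8)
    if n_labels == 0:
        return []

    # context windows may extend past the frame edge; out there the scene
    # is just arena background (no fish outside the imaged area), so the
    # extension is filled with background content rather than a mirror of
    # the fish, which would corrupt scale-space responses at the wall
    M = context_margin
    ext = np.pad(np.asarray(background), M, mode="edge")
    ext[M : M + frame.shape[0], M : M + frame.shape[1]] = frame

    blobs: list[Blob] = []
    H, W = frame.shape
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        ys, xs = sl
        comp = labels[sl] == lab
        area = int(comp.sum())
        if not (area_min <= area <= area_max):
            continue
        yy, xx = np.nonzero(comp)
        P = np.column_stack([xx + xs.start, yy + ys.start]).astype(np.int64)
        x0, y0 = xs.start, ys.start
        w, h = xs.stop - xs.start, ys.stop - ys.start
        cx0, cy0 = x0 - M, y0 - M
        cx1, cy1 = x0 + w + M, y0 + h + M
        blobs.append(
            Blob(
                t=t,
                i=0,
                box=(x0, y0, w, h),
                P=P,
                patch=frame[y0 : y0 + h, x0 : x0 + w].copy(),
                context=ext[cy0 + M : cy1 + M, cx0 + M : cx1 + M].copy(),
                context_offset=(cx0, cy0),
            )
        )
    # raster order of box top-left, then assign indices
    blobs.sort(key=lambda b: (b.box[1], b.box[0]))
    for i, b in enumerate(blobs):
        b.i = i
    return blobs
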