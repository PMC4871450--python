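"""Closed-outline extraction, smoothing, resampling and caliper measures.

The outline — an ordered, implicitly closed sequence of (x, y) points in
micrometres — is the currency between the image stage and the Fourier
stage.  Coordinates use x rightward and y upward (image rows are flipped on
extraction), so positive signed area means counterclockwise orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .exceptions import DegenerateShapeError, ParameterError
from .io import SampleMeta, SilhouetteMask


@dataclass
class Outline:
    """Closed polygonal outline in physical units.

    ``points`` is an (N, 2) float array, N >= 3, implicitly closed (the last
    point connects back to the first); consecutive duplicate points are
    disallowed.  Outputs of :func:`extract_outline` are counterclockwise.
    """

    points: np.ndarray
    meta: SampleMeta | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise DegenerateShapeError(
                f"outline needs >= 3 (x, y) points, got shape {pts.shape}"
            )
        seg = np.roll(pts, -1, axis=0) - pts
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0.0):
            raise DegenerateShapeError("outline has consecutive duplicate points")
        self.points = pts

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def signed_area(self) -> float:
        """Shoelace signed area; > 0 for counterclockwise outlines."""
        x, y = self.points[:, 0], self.points[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def perimeter(self) -> float:
        seg = np.roll(self.points, -1, axis=0) - self.points
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def centroid(self) -> np.ndarray:
        """Vertex-mean centroid (matches the smoothing kernel's fixed point)."""
        return self.points.mean(axis=0)


@dataclass
class LWRecord:
    """Traditional length/width morphometrics for one silhouette."""

    length: float
    width: float
    ratio: float
    meta: SampleMeta | None = None


# Moore neighbourhood in clockwise order for (row, col) indexing with row
# increasing downward: E, SE, S, SW, W, NW, N, NE.
_MOORE = (
    (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1),
)


def _moore_trace(fg: np.ndarray) -> np.ndarray:
    """Trace the outer boundary pixels of the single foreground component.

    Moore-neighbour tracing with 8-connectivity; returns (row, col) pairs of
    boundary pixels in trace order.  Termination by state recurrence: the
    walk stops when it returns to the start pixel with the same backtrack
    direction it began with, which closes the boundary exactly once.
    """
    padded = np.pad(fg, 1)
    rows, cols = np.nonzero(padded)
    first = np.lexsort((cols, rows))[0]
    start = (int(rows[first]), int(cols[first]))

    contour: list[tuple[int, int]] = []
    p = start
    d_back = 4  # the West neighbour of the start pixel is background
    started = False
    limit = 4 * int(fg.sum()) + 8
    for _ in range(limit):
        if started and p == start and d_back == 4:
            break
        started = True
        contour.append(p)
        for k in range(1, 9):
            nd = (d_back + k) % 8
            q = (p[0] + _MOORE[nd][0], p[1] + _MOORE[nd][1])
            if padded[q]:
                break
        else:
            break  # isolated single pixel
        # Backtrack becomes the background cell examined just before q;
        # consecutive cells on the Moore ring are 8-adjacent, so it is a
        # neighbour of q.
        prev_bg = (
            p[0] + _MOORE[(d_back + k - 1) % 8][0],
            p[1] + _MOORE[(d_back + k - 1) % 8][1],
        )
        p = q
        d_back = _MOORE.index((prev_bg[0] - p[0], prev_bg[1] - p[1]))
    return np.array(contour, dtype=np.intp) - 1  # undo padding


def extract_outline(mask: SilhouetteMask) -> Outline:
    """Trace the boundary of a silhouette mask as a closed polygon.

    Boundary pixels are traced with Moore-neighbour tracing (8-connected
    foreground), keeping integer pixel-centre coordinates, then scaled to
    micrometres and flipped so y points upward.  Clockwise traces are
    reversed, so the result is always counterclockwise.
    """
    trace = _moore_trace(mask.pixels)
    if trace.shape[0] < 3:
        raise DegenerateShapeError(
            f"boundary has {trace.shape[0]} pixel(s); need >= 3"
        )
    h = mask.pixels.shape[0]
    x = trace[:, 1].astype(np.float64) * mask.um_per_px
    y = (h - 1 - trace[:, 0]).astype(np.float64) * mask.um_per_px
    pts = np.column_stack([x, y])
    # drop consecutive duplicates (a spur pixel revisited immediately)
    keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)
    if keep.sum() < 3:
        raise DegenerateShapeError("fewer than 3 distinct boundary points")
    outline = Outline(points=pts[keep], meta=mask.meta)
    if outline.signed_area() < 0:
        outline = Outline(points=outline.points[::-1].copy(), meta=mask.meta)
    return outline


def ensure_ccw(outline: Outline) -> Outline:
    """Return the outline with counterclockwise orientation."""
    if outline.signed_area() < 0:
        return replace(outline, points=outline.points[::-1].copy())
    return outline


def smooth_outline(outline: Outline, iterations: int) -> Outline:
    """Cyclic moving-average smoothing.

    Each iteration replaces every point by ¼·previous + ½·itself + ¼·next
    (cyclic neighbours), the standard outline-smoothing kernel used ahead of
    elliptical Fourier decomposition.  Point count and closure are
    preserved; the vertex centroid is a fixed point of the kernel.
    """
    if iterations < 0:
        raise ParameterError("iterations must be non-negative")
    pts = outline.points
    for _ in range(iterations):
        pts = 0.25 * np.roll(pts, 1, axis=0) + 0.5 * pts + 0.25 * np.roll(pts, -1, axis=0)
    if iterations == 0:
        return outline
    return replace(outline, points=pts)


def resample_outline(outline: Outline, n_points: int) -> Outline:
    """Resample to ``n_points`` equally spaced by cumulative arc length.

    The first point of the input is retained as the first output point.
    """
    if n_points < 3:
        raise ParameterError("n_points must be >= 3")
    pts = outline.points
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    cum = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    total = cum[-1]
    if total == 0:
        raise DegenerateShapeError("outline has zero perimeter")
    targets = np.arange(n_points) * (total / n_points)
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    return replace(outline, points=np.column_stack([x, y]))


def max_feret_axis(points: np.ndarray) -> tuple[float, int, int]:
    """Maximum pairwise point distance and the indices attaining it.

    Uses the convex hull to shrink the candidate set (the diameter of a
    point set is attained on its hull); falls back to all points for tiny
    or degenerate inputs.
    """
    try:
        hull_idx = ConvexHull(points).vertices
    except QhullError:
        hull_idx = np.arange(points.shape[0])
    hp = points[hull_idx]
    diff = hp[:, None, :] - hp[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    return float(np.sqrt(d2[i, j])), int(hull_idx[i]), int(hull_idx[j])


def measure_length_width(outline: Outline) -> LWRecord:
    """Length, width and L:W ratio of an outline.

    Length is the maximum Feret (caliper) diameter — the largest pairwise
    point distance.  Width is the maximum extent measured perpendicular to
    the length axis.  Both definitions are rotation-invariant, so the ratio
    does not depend on how the silhouette was oriented on the slide.
    """
    pts = outline.points
    length, i, j = max_feret_axis(pts)
    if length == 0.0:
        raise DegenerateShapeError("all outline points coincide")
    axis = (pts[j] - pts[i]) / length
    perp = np.array([-axis[1], axis[0]])
    proj = pts @ perp
    width = float(proj.max() - proj.min())
    if width == 0.0:
        raise DegenerateShapeError("outline is collinear; width is zero")
    return LWRecord(length=length, width=width, ratio=length / width, meta=outline.meta)


def outlines_to_frame(outlines: list[Outline]) -> "np.ndarray | object":
    """Long-format export table: specimen_id, face, point_index, x_um, y_um."""
    import pandas as pd

    rows = []
    for o in outlines:
        sid = o.meta.specimen_id if o.meta else ""
        face = o.meta.face if o.meta else ""
        for k, (x, y) in enumerate(o.points):
            rows.append((sid, face, k, x, y))
    return pd.DataFrame(
        rows, columns=["specimen_id", "face", "point_index", "x_um", "y_um"]
    )
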