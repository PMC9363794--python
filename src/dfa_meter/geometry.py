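"""Center extraction from class-labeled masks.

A predicted mask may fragment a structure into several blobs; the largest
8-connected component of each class is kept and its geometric center is taken
either as the center of the minimum enclosing circle (default, the "minimum
outer circle") or of the axis-aligned bounding rectangle.  Both agree for the
near-circular disc and virtual-macula regions this package deals with.

Coordinates are ``(x, y)`` = (column, row), 0-based; centers are continuous
(sub-pixel) and only rounded at report time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError

__all__ = [
    "CircleFit",
    "PredictedCenters",
    "MissingClassError",
    "largest_component",
    "min_enclosing_circle",
    "extract_centers",
]

BACKGROUND, DISC, MACULA = 0, 1, 2

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


class MissingClassError(ValueError):
    """A required class has no pixels in the mask (segmentation failure)."""

    def __init__(self, class_code: int):
        self.class_code = class_code
        name = {DISC: "optic disc", MACULA: "virtual macula"}.get(
            class_code, str(class_code)
        )
        super().__init__(f"mask contains no pixels of class {class_code} ({name})")


@dataclass(frozen=True)
class CircleFit:
    """Minimum enclosing circle: center ``(cx, cy)`` and ``radius`` in pixels."""

    cx: float
    cy: float
    radius: float

    @property
    def center(self) -> tuple:
        return (self.cx, self.cy)


@dataclass(frozen=True)
class PredictedCenters:
    """Disc center ``(ox, oy)`` and macula center ``(mx, my)``, pixels."""

    ox: float
    oy: float
    mx: float
    my: float


def _validate_mask(mask) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError(f"label mask must be 2-D, got shape {mask.shape}")
    if not np.isin(mask, (BACKGROUND, DISC, MACULA)).all():
        raise ValueError("label mask may only contain class codes {0, 1, 2}")
    return mask


def largest_component(mask, class_code: int) -> np.ndarray:
    """Pixels of the largest 8-connected component of ``class_code``.

    Returns an ``(n, 2)`` integer array of ``(x, y)`` coordinates; empty
    (shape ``(0, 2)``) when the class is absent from the mask.
    """
    mask = _validate_mask(mask)
    binary = mask == class_code
    labeled, n_components = ndimage.label(binary, structure=_EIGHT_CONNECTED)
    if n_components == 0:
        return np.empty((0, 2), dtype=np.int64)
    counts = np.bincount(labeled.ravel())[1:]
    best = int(np.argmax(counts)) + 1  # ties -> lowest label (first in raster order)
    rows, cols = np.nonzero(labeled == best)
    return np.column_stack([cols, rows]).astype(np.int64)


def _circle_two(p, q) -> CircleFit:
    cx = (p[0] + q[0]) / 2.0
    cy = (p[1] + q[1]) / 2.0
    r = math.hypot(p[0] - q[0], p[1] - q[1]) / 2.0
    return CircleFit(cx, cy, r)


def _circumcircle(a, b, c):
    """Circumcircle of a non-degenerate triangle, or None if collinear."""
    d = 2.0 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
    if d == 0.0:
        return None
    a2 = a[0] * a[0] + a[1] * a[1]
    b2 = b[0] * b[0] + b[1] * b[1]
    c2 = c[0] * c[0] + c[1] * c[1]
    ux = (a2 * (b[1] - c[1]) + b2 * (c[1] - a[1]) + c2 * (a[1] - b[1])) / d
    uy = (a2 * (c[0] - b[0]) + b2 * (a[0] - c[0]) + c2 * (b[0] - a[0])) / d
    return CircleFit(ux, uy, math.hypot(a[0] - ux, a[1] - uy))


def _circle_from_boundary(boundary) -> CircleFit:
    if len(boundary) == 0:
        return CircleFit(0.0, 0.0, 0.0)
    if len(boundary) == 1:
        return CircleFit(boundary[0][0], boundary[0][1], 0.0)
    if len(boundary) == 2:
        return _circle_two(boundary[0], boundary[1])
    circ = _circumcircle(*boundary)
    if circ is None:  # collinear support: widest pair suffices
        best = None
        for i in range(3):
            for j in range(i + 1, 3):
                c = _circle_two(boundary[i], boundary[j])
                if best is None or c.radius > best.radius:
                    best = c
        return best
    return circ


def _contains(circle: CircleFit, p, eps: float = 1e-7) -> bool:
    return math.hypot(p[0] - circle.cx, p[1] - circle.cy) <= circle.radius + eps


def _welzl(points) -> CircleFit:
    """Welzl's move-to-front minimum enclosing circle, iterative support growth."""
    pts = list(points)
    rng = np.random.default_rng(0)  # fixed shuffle: deterministic output
    rng.shuffle(pts)
    circle = CircleFit(pts[0][0], pts[0][1], 0.0)
    for i, p in enumerate(pts):
        if _contains(circle, p):
            continue
        circle = CircleFit(p[0], p[1], 0.0)
        for j in range(i):
            q = pts[j]
            if _contains(circle, q):
                continue
            circle = _circle_two(p, q)
            for k in range(j):
                r = pts[k]
                if _contains(circle, r):
                    continue
                circle = _circle_from_boundary([p, q, r])
    return circle


def min_enclosing_circle(points) -> CircleFit:
    """Smallest circle containing every point of a non-empty point set.

    Runs Welzl's randomized algorithm on the convex hull of the input (the
    minimum enclosing circle of a set equals that of its hull), so large
    rasterized regions cost one hull computation plus expected-linear work
    on the hull vertices.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1 and pts.size == 2:
        pts = pts[None, :]
    if pts.size == 0:
        raise ValueError("min_enclosing_circle requires a non-empty point set")
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"points must have shape (n, 2), got {pts.shape}")
    pts = np.unique(pts, axis=0)
    if len(pts) == 1:
        return CircleFit(float(pts[0, 0]), float(pts[0, 1]), 0.0)
    if len(pts) > 3:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (collinear) input: Welzl handles it directly
    return _welzl([tuple(p) for p in pts])


def _component_center(points: np.ndarray, method: str) -> tuple:
    if method == "circle":
        fit = min_enclosing_circle(points)
        return fit.cx, fit.cy
    if method == "rectangle":
        xmin, ymin = points.min(axis=0)
        xmax, ymax = points.max(axis=0)
        return (xmin + xmax) / 2.0, (ymin + ymax) / 2.0
    raise ValueError(f"unknown center method {method!r}; use 'circle' or 'rectangle'")


def extract_centers(mask, method: str = "circle") -> PredictedCenters:
    """Disc and macula centers from a three-class label mask.

    Parameters
    ----------
    mask : array-like of {0, 1, 2}
        Label mask (0 background, 1 optic disc, 2 virtual macula).
    method : {'circle', 'rectangle'}
        'circle': center of the minimum enclosing circle of the largest
        component.  'rectangle': center of its axis-aligned bounding box.

    Raises
    ------
    MissingClassError
        When the disc or macula class has no pixels; callers treat the image
        as unmeasurable.
    """
    mask = _validate_mask(mask)
    disc_pts = largest_component(mask, DISC)
    if disc_pts.shape[0] == 0:
        raise MissingClassError(DISC)
    macula_pts = largest_component(mask, MACULA)
    if macula_pts.shape[0] == 0:
        raise MissingClassError(MACULA)
    ox, oy = _component_center(disc_pts, method)
    mx, my = _component_center(macula_pts, method)
    return PredictedCenters(ox=ox, oy=oy, mx=mx, my=my)
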