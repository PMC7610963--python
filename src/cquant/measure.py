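"""Anatomical landmark measurements: distances and ring area/perimeter.

A ring of >= 3 landmarks is treated as a closed polygon; its area is the
planar polygon area after projecting onto the ring's best-fit plane, while
the perimeter is the true 3-D closed-loop edge length.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import CollinearRingWarning, PreconditionError
from .types import LandmarkSet

__all__ = ["landmark_distance", "landmark_area_perimeter", "best_fit_plane"]


def landmark_distance(a, b) -> float:
    """Euclidean distance between two world-mm points."""
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def best_fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares plane through points: returns (centroid, unit normal)."""
    pts = np.asarray(points, float)
    c = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - c)
    return c, vt[-1]


def landmark_area_perimeter(ring: LandmarkSet) -> tuple[float, float]:
    """Area (mm^2) and perimeter (mm) of a closed landmark ring.

    Raises an arity error below 3 points. A collinear ring gives a
    zero-area warning; the perimeter is still returned.
    """
    pts = ring.points
    if len(pts) < 3:
        raise PreconditionError("area needs at least 3 landmarks")
    perimeter = float(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum())

    c = pts.mean(axis=0)
    q = pts - c
    _, s, vt = np.linalg.svd(q)
    if s[1] < 1e-9 * max(s[0], 1e-30):
        warnings.warn("collinear landmark ring: area is zero", CollinearRingWarning)
        return 0.0, perimeter
    # project onto the best-fit plane spanned by the two leading axes
    uv = q @ vt[:2].T
    x, y = uv[:, 0], uv[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(area), perimeter
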