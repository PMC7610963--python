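"""Green--Lagrange strain from tracked surface meshes, directional strains,
area change, and 16-segment regional aggregation.

The per-triangle deformation gradient F is the unique linear map sending
the two reference edge vectors to the deformed edge vectors and the
reference unit normal to the deformed unit normal (surface-deformation
convention: the normal direction carries no strain claim). Then
``E = (F^T F - I) / 2`` vanishes for rigid motion, a directional strain is
``d^T E d``, and the local area change is the deformed/reference triangle
area ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CorrespondenceError, PreconditionError, SingularElementError
from .types import SurfaceMesh

__all__ = [
    "deformation_gradient", "green_lagrange", "directional_strain",
    "area_change", "StrainResult", "compute_strain", "SegmentModel",
    "assign_segments_16", "segment_curves", "local_directions",
]


def _edge_frames(mesh: SurfaceMesh) -> np.ndarray:
    """Per-triangle 3x3 matrices [e1 e2 n] with unit normal as 3rd column."""
    p = mesh.vertices[mesh.triangles]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    n = np.cross(e1, e2)
    norms = np.linalg.norm(n, axis=1, keepdims=True)
    return np.stack([e1, e2, n / norms], axis=-1)


def deformation_gradient(ref: SurfaceMesh, deformed: SurfaceMesh) -> np.ndarray:
    """Per-triangle deformation gradient F, shape (M, 3, 3).

    Requires identical connectivity. ``F @ e_ref = e_def`` exactly for both
    in-plane edges and F maps the reference unit normal to the deformed
    unit normal.
    """
    if ref.n_triangles != deformed.n_triangles or \
            not np.array_equal(ref.triangles, deformed.triangles):
        raise CorrespondenceError("meshes must share identical connectivity")
    a = _edge_frames(ref)
    b = _edge_frames(deformed)
    det = np.linalg.det(a)
    if np.any(np.abs(det) < 1e-12):
        bad = int(np.argmin(np.abs(det)))
        raise SingularElementError(
            f"degenerate reference triangle {bad}", triangle_index=bad)
    return b @ np.linalg.inv(a)


def green_lagrange(F: np.ndarray) -> np.ndarray:
    """Green--Lagrange strain tensor E = (F^T F - I)/2, symmetrised."""
    F = np.asarray(F, float)
    single = F.ndim == 2
    F = F.reshape(-1, 3, 3)
    E = 0.5 * (np.einsum("tji,tjk->tik", F, F) - np.eye(3))
    E = 0.5 * (E + np.swapaxes(E, 1, 2))  # kill numerical asymmetry
    return E[0] if single else E


def directional_strain(E: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Normal strain along direction d: ``d^T E d`` (d is normalised with a
    warning if it is not unit)."""
    E = np.asarray(E, float)
    d = np.asarray(d, float)
    single = E.ndim == 2
    E = E.reshape(-1, 3, 3)
    d = np.broadcast_to(d, (E.shape[0], 3)).copy()
    norms = np.linalg.norm(d, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-8):
        warnings.warn("direction not unit; normalising")
        d /= norms[:, None]
    out = np.einsum("ti,tij,tj->t", d, E, d)
    return float(out[0]) if single else out


def area_change(ref: SurfaceMesh, deformed: SurfaceMesh) -> np.ndarray:
    """Per-triangle |deformed area| / |reference area|."""
    if not np.array_equal(ref.triangles, deformed.triangles):
        raise CorrespondenceError("meshes must share identical connectivity")
    return deformed.triangle_areas() / ref.triangle_areas()


def local_directions(mesh: SurfaceMesh, long_axis: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-triangle unit longitudinal and circumferential directions.

    Longitudinal is the long-axis component tangent to the triangle plane;
    circumferential is normal x longitudinal. Triangles whose plane is
    orthogonal to the axis (apex caps) get NaN directions.
    """
    axis = np.asarray(long_axis, float)
    axis = axis / np.linalg.norm(axis)
    n = mesh.triangle_normals()
    lon = axis - n * (n @ axis)[:, None]
    norms = np.linalg.norm(lon, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        lon = np.where(norms > 1e-9, lon / norms, np.nan)
    circ = np.cross(n, lon)
    return lon, circ


@dataclass
class StrainResult:
    """Strain quantities for one deformed frame relative to the reference."""

    F: np.ndarray            # (M, 3, 3)
    E: np.ndarray            # (M, 3, 3)
    Ecc: np.ndarray          # circumferential strain per triangle
    Ell: np.ndarray          # longitudinal strain per triangle
    area_ratio: np.ndarray   # per triangle
    frame: int = 0


def compute_strain(ref: SurfaceMesh, deformed: SurfaceMesh,
                   long_axis: np.ndarray, frame: int = 0) -> StrainResult:
    """Full strain computation for one frame: F, E, Ecc, Ell, area ratio."""
    F = deformation_gradient(ref, deformed)
    E = green_lagrange(F)
    lon, circ = local_directions(ref, long_axis)
    with np.errstate(invalid="ignore"):
        Ell = np.einsum("ti,tij,tj->t", lon, E, lon)
        Ecc = np.einsum("ti,tij,tj->t", circ, E, circ)
    return StrainResult(F, E, Ecc, Ell, area_change(ref, deformed), frame)


# ---------------------------------------------------------------------------
# 16-segment model

@dataclass
class SegmentModel:
    """AHA-style 16-segment assignment: 6 basal, 6 mid, 4 apical sectors."""

    segment_ids: np.ndarray  # per triangle, in 1..16
    long_axis: np.ndarray
    apex: np.ndarray
    base: np.ndarray


def assign_segments_16(mesh: SurfaceMesh, apex, base,
                       reference_direction) -> SegmentModel:
    """Assign every triangle to one of 16 segments.

    The long-axis fraction lambda of the triangle centroid (0 at base, 1 at
    apex) selects the ring: basal (lambda < 1/3, segments 1-6), mid-cavity
    (1/3 <= lambda < 2/3, segments 7-12), apical (lambda >= 2/3, segments
    13-16). Within a ring the circumferential angle from
    ``reference_direction`` (counter-clockwise about the base->apex axis)
    selects 60-degree (basal/mid) or 90-degree (apical) sectors. Boundary
    angles and fractions tie-break to the lower-index segment.
    """
    apex = np.asarray(apex, float)
    base = np.asarray(base, float)
    axis = apex - base
    axis_len = np.linalg.norm(axis)
    if axis_len < 1e-9:
        raise PreconditionError("apex and base coincide: degenerate long axis")
    axis = axis / axis_len
    ref = np.asarray(reference_direction, float)
    ref = ref - axis * (ref @ axis)
    if np.linalg.norm(ref) < 1e-9:
        raise PreconditionError("reference_direction parallel to the long axis")
    ref = ref / np.linalg.norm(ref)
    perp = np.cross(axis, ref)

    c = mesh.triangle_centroids()
    lam = np.clip((c - base) @ axis / axis_len, 0.0, 1.0)
    ang = np.degrees(np.arctan2((c - base) @ perp, (c - base) @ ref)) % 360.0

    tol = 1e-9
    ring = np.where(lam < 1.0 / 3.0 + tol, 0,
                    np.where(lam < 2.0 / 3.0 + tol, 1, 2))
    seg = np.empty(mesh.n_triangles, dtype=np.int64)
    for r, (width, start, count) in enumerate([(60.0, 1, 6), (60.0, 7, 6),
                                               (90.0, 13, 4)]):
        sel = ring == r
        a = ang[sel]
        sector = np.floor(a / width).astype(np.int64)
        on_boundary = (np.abs(a - sector * width) <= 1e-9) & (sector > 0)
        sector[on_boundary] -= 1
        seg[sel] = start + np.minimum(sector, count - 1)
    return SegmentModel(seg, axis, apex, base)


def segment_curves(values: np.ndarray, seg: SegmentModel,
                   mesh: SurfaceMesh) -> pd.DataFrame:
    """Area-weighted mean of per-triangle values per segment per frame.

    Parameters
    ----------
    values
        (M,) for one frame or (T, M) for T frames.
    seg, mesh
        Segment model and the mesh it was built on (for triangle areas).

    Returns
    -------
    DataFrame with 16 rows (segments 1..16) and one column per frame;
    directly writable as the deformation-curve CSV.
    """
    vals = np.atleast_2d(np.asarray(values, float))
    if vals.shape[1] != mesh.n_triangles:
        raise CorrespondenceError(
            f"values per frame ({vals.shape[1]}) != triangle count "
            f"({mesh.n_triangles})")
    areas = mesh.triangle_areas()
    out = np.full((16, vals.shape[0]), np.nan)
    for s in range(1, 17):
        sel = seg.segment_ids == s
        if sel.any():
            w = areas[sel]
            out[s - 1] = vals[:, sel] @ w / w.sum()
    return pd.DataFrame(out, index=pd.Index(range(1, 17), name="segment"),
                        columns=[f"frame_{t}" for t in range(vals.shape[0])])
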