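"""LGE scar quantification on a chamber surface mesh.

A maximum-intensity projection along the surface normals interrogates the
LGE volume a few mm either side of the wall; scores are normalised by the
blood-pool mean intensity (image intensity ratio, IIR) and thresholded into
a per-triangle scar label. Higher-level analyses: scar burden and area,
peri-vein corridor gap counting for pulmonary vein isolation assessment,
and pre/post-ablation map comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import (ClampedSampleWarning, CorrespondenceError,
                     EmptyResultError, NormalisationError, TopologyError)
from .types import SurfaceMesh, Volume

__all__ = [
    "project_mip", "normalize_iir", "ScarMap", "threshold_scar",
    "Corridor", "build_corridor", "count_gaps", "compare_pre_post",
]

#: default IIR thresholds exposed as configuration
DEFAULT_IIR_THRESHOLDS = (1.2, 1.32)


def project_mip(mesh: SurfaceMesh, lge: Volume, inward: float = 1.0,
                outward: float = 3.0, step: float = 0.25,
                on_clamp: str = "warn") -> np.ndarray:
    """Maximum-intensity projection of the LGE volume along mesh normals.

    For every triangle, the image is sampled by linear interpolation at
    ``centroid + t * n_hat`` for ``t`` from ``-inward`` to ``+outward`` mm
    in increments of ``step`` (outward = surface-normal direction; the
    default probes 3 mm externally and 1 mm internally). The raw score is
    the maximum sample.

    ``on_clamp`` controls behaviour when samples leave the volume:
    "warn" clamps to the border with a warning, "error" raises.
    """
    if inward < 0 or outward < 0:
        raise ValueError("inward and outward must be >= 0")
    oriented = mesh.oriented_outward() if mesh.is_closed() else mesh
    centroids = oriented.triangle_centroids()
    normals = oriented.triangle_normals()
    ts = np.arange(-inward, outward + step / 2.0, step)
    pts = centroids[None, :, :] + ts[:, None, None] * normals[None, :, :]
    idx = lge.world_to_index(pts.reshape(-1, 3))
    upper = np.array(lge.shape, float) - 1.0
    out_of_bounds = np.any((idx < 0) | (idx > upper), axis=1)
    if out_of_bounds.any():
        msg = (f"{int(out_of_bounds.sum())} projection samples outside the "
               "volume were clamped to the border")
        if on_clamp == "error":
            raise EmptyResultError(msg)
        warnings.warn(msg, ClampedSampleWarning)
    samples = map_coordinates(np.asarray(lge.data, float), idx.T, order=1,
                              mode="nearest")
    return samples.reshape(len(ts), -1).max(axis=0)


def normalize_iir(raw_scores: np.ndarray, blood_pool_mean: float) -> np.ndarray:
    """Image-intensity-ratio normalisation: raw score / blood-pool mean."""
    if not blood_pool_mean > 0:
        raise NormalisationError(
            f"blood pool mean must be positive, got {blood_pool_mean}")
    return np.asarray(raw_scores, float) / float(blood_pool_mean)


@dataclass
class ScarMap:
    """Per-triangle scar scoring of one mesh against one LGE volume."""

    mesh: SurfaceMesh
    raw_score: np.ndarray
    normalized_score: np.ndarray
    threshold: float
    label: np.ndarray          # bool: normalized_score > threshold

    @property
    def burden_percent(self) -> float:
        areas = self.mesh.triangle_areas()
        return float(100.0 * areas[self.label].sum() / areas.sum())

    @property
    def scar_area_mm2(self) -> float:
        return float(self.mesh.triangle_areas()[self.label].sum())


def threshold_scar(mesh: SurfaceMesh, normalized_scores: np.ndarray,
                   threshold: float,
                   raw_scores: np.ndarray | None = None) -> ScarMap:
    """Label triangles with score strictly above ``threshold`` as scar and
    report burden (% of total area) and scar area (mm^2) via the returned
    :class:`ScarMap`."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    scores = np.asarray(normalized_scores, float)
    if len(scores) != mesh.n_triangles:
        raise CorrespondenceError("one score per triangle required")
    label = scores > threshold
    raw = np.asarray(raw_scores, float) if raw_scores is not None else scores
    return ScarMap(mesh, raw, scores, float(threshold), label)


# ---------------------------------------------------------------------------
# Peri-vein corridor and gap analysis

@dataclass
class Corridor:
    """An exploration corridor around a vein ostium rim.

    ``rim_vertices`` is the ordered closed vertex loop; ``arc_length`` its
    cumulative arc-length parametrisation (same length); ``triangles`` are
    the corridor triangle indices and ``triangle_arc`` the arc-length
    coordinate of each triangle's nearest rim vertex.
    """

    mesh: SurfaceMesh
    rim_vertices: np.ndarray
    arc_length: np.ndarray
    loop_length: float
    triangles: np.ndarray
    triangle_arc: np.ndarray
    triangle_rim_index: np.ndarray  # index into rim_vertices per triangle
    width: float


def _check_closed_loop(mesh: SurfaceMesh, rim: np.ndarray) -> None:
    if len(rim) < 3 or len(np.unique(rim)) != len(rim):
        raise TopologyError("rim must be a closed loop of distinct vertices")
    edge_set = {tuple(sorted(e)) for e in mesh.edges().tolist()}
    for a, b in zip(rim, np.roll(rim, -1)):
        if tuple(sorted((int(a), int(b)))) not in edge_set:
            raise TopologyError(
                f"rim edge ({a}, {b}) is not an edge of the mesh: open or "
                "invalid loop")


def build_corridor(mesh: SurfaceMesh, rim: np.ndarray, width: float) -> Corridor:
    """Corridor of triangles within geodesic ``width`` mm of a rim loop.

    Geodesic distance is edge-graph Dijkstra from all rim vertices; a
    triangle belongs to the corridor when its centroid distance (nearest
    vertex geodesic + vertex-to-centroid hop) is at most ``width``. Each
    corridor triangle is assigned the arc-length coordinate of its nearest
    rim vertex.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    rim = np.asarray(rim, dtype=np.int64)
    _check_closed_loop(mesh, rim)

    rim_pts = mesh.vertices[rim]
    seg_lens = np.linalg.norm(np.roll(rim_pts, -1, axis=0) - rim_pts, axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_lens[:-1])])
    loop_length = float(seg_lens.sum())

    e = np.unique(np.sort(mesh.edges(), axis=1), axis=0)
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    g = coo_matrix((np.r_[w, w], (np.r_[e[:, 0], e[:, 1]],
                                  np.r_[e[:, 1], e[:, 0]])), shape=(n, n)).tocsr()
    dist, _, sources = dijkstra(g, directed=False, indices=rim,
                                min_only=True, return_predecessors=True)
    rim_pos = {int(v): k for k, v in enumerate(rim)}

    centroids = mesh.triangle_centroids()
    tri_vert_dist = dist[mesh.triangles]  # (M, 3)
    hop = np.linalg.norm(centroids[:, None, :] - mesh.vertices[mesh.triangles],
                         axis=2)
    total = tri_vert_dist + hop
    best_corner = np.argmin(total, axis=1)
    tri_dist = total[np.arange(len(total)), best_corner]
    inside = tri_dist <= width
    # triangles incident to the rim always belong, however small the width
    inside |= np.isin(mesh.triangles, rim).any(axis=1)
    tris = np.flatnonzero(inside)
    if tris.size == 0:
        raise EmptyResultError("no triangles within the corridor width")
    best_vertex = mesh.triangles[tris, best_corner[tris]]
    rim_source = sources[best_vertex]
    rim_idx = np.array([rim_pos[int(v)] for v in rim_source])
    return Corridor(mesh, rim, arc, loop_length, tris, arc[rim_idx],
                    rim_idx, width)


def count_gaps(corridor: Corridor, labels: np.ndarray) -> tuple[int, float]:
    """Count lesion gaps on the circular rim of a corridor.

    Corridor triangles project to their nearest rim vertex; a rim vertex is
    scar-covered when at least one of its triangles is scar. Gaps are the
    maximal circular arcs of rim vertices covered only by non-scar
    triangles; each rim vertex owns half of each adjacent loop segment, and
    the gap fraction is the owned-length sum over the loop length. A fully
    non-scar corridor is a single gap of fraction 1.
    """
    labels = np.asarray(labels, bool)
    if len(labels) == corridor.mesh.n_triangles:
        labels = labels[corridor.triangles]
    elif len(labels) != len(corridor.triangles):
        raise CorrespondenceError(
            "labels must cover the whole mesh or exactly the corridor triangles")
    if len(corridor.triangles) == 0:
        raise EmptyResultError("empty corridor")

    n = len(corridor.rim_vertices)
    covered = np.zeros(n, dtype=bool)
    has_tri = np.zeros(n, dtype=bool)
    np.logical_or.at(covered, corridor.triangle_rim_index, labels)
    has_tri[corridor.triangle_rim_index] = True
    # rim vertices with no assigned triangle inherit their neighbours' state
    # by counting as covered only if both neighbours are; treat as non-scar
    scarred = covered

    if scarred.all():
        return 0, 0.0
    # owned length of each rim vertex: half of each adjacent segment
    rim_pts = corridor.mesh.vertices[corridor.rim_vertices]
    seg = np.linalg.norm(np.roll(rim_pts, -1, axis=0) - rim_pts, axis=1)
    owned = 0.5 * (seg + np.roll(seg, 1))
    if not scarred.any():
        return 1, 1.0
    # count circular runs of non-scar vertices
    transitions = np.flatnonzero(scarred != np.roll(scarred, 1))
    n_gaps = len(transitions) // 2
    gap_fraction = float(owned[~scarred].sum() / corridor.loop_length)
    return n_gaps, gap_fraction


# ---------------------------------------------------------------------------
# Pre/post ablation comparison

def compare_pre_post(labels_pre: np.ndarray, labels_post: np.ndarray,
                     mesh: SurfaceMesh) -> dict[str, float]:
    """Area-weighted Dice and change fractions between two scar maps on one
    mesh (correspondence by triangle index).

    Returns ``overlap_dice`` = 2|A∩B|/(|A|+|B|), ``new_scar_fraction`` =
    area(post - pre)/area(post) and ``regressed_fraction`` =
    area(pre - post)/area(pre); empty denominators give 0.
    """
    a = np.asarray(labels_pre, bool)
    b = np.asarray(labels_post, bool)
    if len(a) != len(b) or len(a) != mesh.n_triangles:
        raise CorrespondenceError("label sets must match the mesh triangle count")
    areas = mesh.triangle_areas()
    area_a = areas[a].sum()
    area_b = areas[b].sum()
    inter = areas[a & b].sum()
    dice = 2.0 * inter / (area_a + area_b) if (area_a + area_b) > 0 else 0.0
    new = areas[b & ~a].sum() / area_b if area_b > 0 else 0.0
    reg = areas[a & ~b].sum() / area_a if area_a > 0 else 0.0
    return {"overlap_dice": float(dice), "new_scar_fraction": float(new),
            "regressed_fraction": float(reg)}
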