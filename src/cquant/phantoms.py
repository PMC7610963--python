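"""Deterministic synthetic phantoms for every pipeline in the toolkit.

Each generator is a pure function of its parameters and seed and ships its
ground truth alongside the data (in world mm, never voxel indices), so the
modules under test never share the phantom's discretisation.

Conventions
-----------
Wall phantoms label the wall 1 and place single-voxel endo (2) / epi (3)
marker layers immediately *outside* the wall, so the wall/marker voxel
faces coincide with the continuum endocardial and epicardial surfaces. The
Laplace solver pins its Dirichlet values at those faces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree

from .errors import PreconditionError, ResolutionError
from .ffd import BSplineFFD, make_lattice
from .types import SurfaceMesh, Volume

__all__ = [
    "VeinSpec", "make_slab_wall", "make_spherical_shell",
    "make_chamber_with_veins", "make_lge_surface_phantom", "make_ffd_motion",
    "geodesic_vertex_distances",
]

WALL, ENDO, EPI = 1, 2, 3


def _axis_affine(spacing: float, origin: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.eye(3) * spacing
    aff[:3, 3] = origin
    return aff


def make_slab_wall(thickness: float, extent: float, spacing: float) -> Volume:
    """Parallel-plate wall of exact thickness ``thickness`` (mm).

    The wall (label 1) occupies ``z in (0, thickness)``; endo (2) and epi
    (3) marker layers are the single voxel layers just below z=0 and just
    above z=thickness. The analytic thickness field is ``thickness``
    everywhere and the analytic potential is ``u(z) = z / thickness``.
    """
    if thickness < 3 * spacing:
        raise ResolutionError(
            f"thickness {thickness} < 3 x spacing {spacing}: too coarse")
    n_wall = int(round(thickness / spacing))
    if abs(n_wall * spacing - thickness) > 1e-9:
        raise ResolutionError("thickness must be an integer number of voxels")
    nxy = int(round(extent / spacing))
    nz = n_wall + 2
    data = np.zeros((nxy, nxy, nz), dtype=np.uint8)
    data[:, :, 1:1 + n_wall] = WALL
    data[:, :, 0] = ENDO
    data[:, :, -1] = EPI
    # voxel k=1 centre sits at z = spacing/2
    origin = np.array([spacing / 2, spacing / 2, -spacing / 2])
    return Volume(data, _axis_affine(spacing, origin))


def make_spherical_shell(r_in: float, r_out: float, spacing: float) -> Volume:
    """Spherical shell wall: label 1 where ``r_in <= r <= r_out`` (voxel
    centres), endo/epi marker layers adjacent inside/outside.

    Analytic thickness is ``r_out - r_in``; the analytic potential is the
    3-D harmonic ``u(r) = (1/r_in - 1/r) / (1/r_in - 1/r_out)``.
    """
    if r_out <= r_in + 2 * spacing:
        raise ResolutionError(
            f"shell r_out={r_out} must exceed r_in={r_in} by > 2 x spacing")
    half = r_out + 2 * spacing
    n = 2 * int(np.ceil(half / spacing)) + 1
    origin = -spacing * (n - 1) / 2.0
    coords = origin + spacing * np.arange(n)
    x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")
    r = np.sqrt(x * x + y * y + z * z)
    wall = (r >= r_in) & (r <= r_out)
    data = np.zeros((n, n, n), dtype=np.uint8)
    data[wall] = WALL
    grown = ndimage.binary_dilation(wall, ndimage.generate_binary_structure(3, 1))
    data[grown & (r < r_in)] = ENDO
    data[grown & (r > r_out)] = EPI
    return Volume(data, _axis_affine(spacing, np.full(3, origin)))


@dataclass
class VeinSpec:
    """A tubular vein attached to the chamber: unit direction from the
    chamber centre, radius and length (both mm, length measured from the
    sphere--cylinder junction outward)."""
    direction: np.ndarray
    radius: float
    length: float

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, float)
        self.direction = d / np.linalg.norm(d)


def make_chamber_with_veins(R: float, veins: list[VeinSpec], spacing: float
                            ) -> tuple[Volume, list[dict]]:
    """Blood pool of a spherical chamber with cylindrical veins.

    Returns the binary blood-pool volume and, per vein, the exact
    ground-truth geometry in world mm: the sphere-cylinder ``junction``
    point (on the vein axis at distance ``sqrt(R^2 - r^2)`` from the
    centre), the ``distal`` end point, direction, radius and length.
    """
    for v in veins:
        if v.radius >= R / 3:
            raise PreconditionError(
                f"vein radius {v.radius} must be < R/3 = {R / 3}")
        if v.length <= 4 * v.radius:
            raise PreconditionError(
                f"vein length {v.length} must be > 4 x radius")
    reach = R + max((np.sqrt(R**2 - v.radius**2) - R + v.length
                     for v in veins), default=0.0)
    half = max(R, reach) + 2 * spacing
    n = 2 * int(np.ceil(half / spacing)) + 1
    origin = -spacing * (n - 1) / 2.0
    coords = origin + spacing * np.arange(n)
    x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")
    pts = np.stack([x, y, z], axis=-1)
    r2 = np.einsum("...i,...i->...", pts, pts)
    blood = r2 <= R * R
    truth: list[dict] = []
    for v in veins:
        t_j = float(np.sqrt(R**2 - v.radius**2))
        axial = pts @ v.direction
        radial2 = r2 - axial**2
        blood |= (radial2 <= v.radius**2) & (axial >= 0) & (axial <= t_j + v.length)
        truth.append({
            "junction": (t_j * v.direction).tolist(),
            "distal": ((t_j + v.length) * v.direction).tolist(),
            "direction": v.direction.tolist(),
            "radius": v.radius,
            "length": v.length,
        })
    vol = Volume(blood.astype(np.uint8), _axis_affine(spacing, np.full(3, origin)))
    return vol, truth


def geodesic_vertex_distances(mesh: SurfaceMesh, source_vertices) -> np.ndarray:
    """Geodesic distance (edge-graph Dijkstra, mm) from a set of source
    vertices to every vertex."""
    from scipy.sparse import coo_matrix
    e = np.unique(np.sort(mesh.edges(), axis=1), axis=0)
    w = np.linalg.norm(mesh.vertices[e[:, 0]] - mesh.vertices[e[:, 1]], axis=1)
    n = mesh.n_vertices
    g = coo_matrix((np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
                   shape=(n, n)).tocsr()
    src = np.atleast_1d(np.asarray(source_vertices, dtype=np.int64))
    return dijkstra(g, directed=False, indices=src, min_only=True)


def _point_triangle_distance(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Exact distance from points p (N,3) to triangles tri (N,3,3)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    n = np.cross(ab, ac)
    nn = np.einsum("ij,ij->i", n, n)
    ap = p - a
    # barycentric coordinates of the in-plane projection
    d1 = np.einsum("ij,ij->i", ab, ab)
    d2 = np.einsum("ij,ij->i", ab, ac)
    d3 = np.einsum("ij,ij->i", ac, ac)
    e1 = np.einsum("ij,ij->i", ap, ab)
    e2 = np.einsum("ij,ij->i", ap, ac)
    det = d1 * d3 - d2 * d2
    det = np.where(np.abs(det) < 1e-30, 1e-30, det)
    u = (d3 * e1 - d2 * e2) / det
    v = (d1 * e2 - d2 * e1) / det
    inside = (u >= 0) & (v >= 0) & (u + v <= 1)
    dist_plane = np.abs(np.einsum("ij,ij->i", ap, n)) / np.sqrt(
        np.where(nn < 1e-30, 1e-30, nn))

    def seg_dist(p0, q0, q1):
        d = q1 - q0
        t = np.einsum("ij,ij->i", p0 - q0, d) / np.einsum("ij,ij->i", d, d)
        t = np.clip(t, 0.0, 1.0)
        return np.linalg.norm(p0 - (q0 + t[:, None] * d), axis=1)

    edge = np.minimum(np.minimum(seg_dist(p, a, b), seg_dist(p, b, c)),
                      seg_dist(p, c, a))
    return np.where(inside, dist_plane, edge)


def make_lge_surface_phantom(mesh: SurfaceMesh,
                             scar_patches: list[tuple[int, float]],
                             blood_mean: float, scar_ratio: float,
                             noise_sd: float, seed: int,
                             spacing: float = 0.5,
                             band: float = 2.0) -> tuple[Volume, np.ndarray]:
    """LGE-like intensity volume around a surface mesh with planted
    hyper-enhanced patches.

    Intensity is ``blood_mean`` inside the mesh, ``blood_mean * scar_ratio``
    in a ``band``-mm-thick band straddling the surface over the patch
    triangles, 0 outside, plus seeded Gaussian noise. A patch is the set of
    triangles whose mean vertex geodesic distance from the patch centre
    vertex is at most the patch radius.

    Returns the volume and the ground-truth boolean per-triangle scar label.
    """
    if scar_ratio < 1:
        raise PreconditionError("scar_ratio must be >= 1")
    truth = np.zeros(mesh.n_triangles, dtype=bool)
    if scar_ratio > 1:
        for centre_vertex, radius in scar_patches:
            d = geodesic_vertex_distances(mesh, centre_vertex)
            tri_d = d[mesh.triangles].mean(axis=1)
            truth |= tri_d <= radius
    lo = mesh.vertices.min(0) - (band + 2 * spacing)
    hi = mesh.vertices.max(0) + (band + 2 * spacing)
    n = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = [lo[k] + spacing * np.arange(n[k]) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    oriented = mesh.oriented_outward() if mesh.is_closed() else mesh
    centroids = oriented.triangle_centroids()
    normals = oriented.triangle_normals()
    tree = cKDTree(centroids)
    dist, nearest = tree.query(grid, workers=-1)
    signed = np.einsum("ij,ij->i", grid - centroids[nearest], normals[nearest])
    data = np.where(signed <= 0, float(blood_mean), 0.0)
    # near the surface, resolve the nearest triangle exactly (closest point
    # on triangle over k centroid candidates) so the planted band edges
    # match the per-triangle truth instead of blurring across centroids
    near = np.abs(signed) <= band / 2.0 + float(np.max(spacing))
    if near.any() and truth.any():
        k = min(12, oriented.n_triangles)
        _, cand = tree.query(grid[near], k=k, workers=-1)
        cand = np.atleast_2d(cand)
        tri_pts = oriented.vertices[oriented.triangles]
        best_d = np.full(cand.shape[0], np.inf)
        best_t = cand[:, 0].copy()
        for j in range(cand.shape[1]):
            t_ids = cand[:, j]
            dj = _point_triangle_distance(grid[near], tri_pts[t_ids])
            closer = dj < best_d
            best_d[closer] = dj[closer]
            best_t[closer] = t_ids[closer]
        exact_sign = np.einsum("ij,ij->i", grid[near] - centroids[best_t],
                               normals[best_t])
        in_band = (best_d <= band / 2.0) & truth[best_t]
        vals = data[near]
        vals[in_band] = blood_mean * scar_ratio
        data[near] = vals
        # refine inside/outside near the surface with the exact triangle
        outside_fix = (~in_band) & (exact_sign > 0)
        inside_fix = (~in_band) & (exact_sign <= 0)
        vals = data[near]
        vals[outside_fix] = 0.0
        vals[inside_fix & (vals == 0.0)] = blood_mean
        data[near] = vals
    data = data.reshape(tuple(n))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return Volume(data, _axis_affine(spacing, lo)), truth


def make_ffd_motion(grid_spacing: float, amplitude: float, n_frames: int,
                    seed: int, domain_lo=(0.0, 0.0, 0.0),
                    domain_hi=(64.0, 64.0, 64.0)) -> list[BSplineFFD]:
    """Smooth seeded random B-spline motion sequence; frame 0 is identity.

    Control displacements are smoothed white noise rescaled so the maximum
    control vector norm is ``amplitude``; since the cubic B-spline basis is
    a positive partition of unity, no material point moves farther than
    ``amplitude`` mm. A half-sine temporal envelope makes the motion leave
    and return like a cardiac cycle.
    """
    if not amplitude < grid_spacing / 2:
        raise PreconditionError(
            f"amplitude {amplitude} must be < grid_spacing/2 = {grid_spacing / 2} "
            "(diffeomorphic-by-construction margin)")
    if n_frames < 1:
        raise PreconditionError("need n_frames >= 1")
    lattice = make_lattice(np.asarray(domain_lo, float), np.asarray(domain_hi, float),
                           grid_spacing)
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((*lattice.shape, 3))
    for c in range(3):
        base[..., c] = ndimage.gaussian_filter(base[..., c], sigma=1.0)
    norms = np.linalg.norm(base, axis=-1)
    peak = norms.max()
    if peak > 0 and amplitude > 0:
        base *= amplitude / peak
    else:
        base[:] = 0.0
    frames = []
    for t in range(n_frames):
        envelope = np.sin(np.pi * t / n_frames) if n_frames > 1 else 0.0
        frames.append(BSplineFFD(lattice.origin.copy(), lattice.spacing.copy(),
                                 base * envelope, level=0))
    return frames
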