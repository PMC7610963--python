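"""Vessel identification and truncation.

The blood pool's medial radius field (maximal-inscribed-sphere radius, the
discrete analogue of the embedded Voronoi radius) guides centerlines from
user seeds at the distal vessel ends to the chamber body centre. Along a
centerline the surrounding cross-sectional area (pi r^2, a medial-radius
proxy) stays flat inside the vessel and rises sharply at the chamber
opening; that inflection locates the ostium, where a finite-disk clip plane
truncates the vessel. Automatic, semi-automatic (user disk radius) and
manual (plane from picked seeds) modes are provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.ndimage import map_coordinates
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .errors import (ConnectivityError, EmptyResultError, LocationError,
                     NoIntersectionError, NoOpeningError, PreconditionError)
from .types import LandmarkSet, SurfaceMesh, Volume

__all__ = [
    "medial_radius_field", "Centerline", "centerline", "detect_opening",
    "ClipPlane", "plane_at", "plane_from_seeds", "plane_semi_auto",
    "ClipResult", "clip",
]


def medial_radius_field(blood: Volume) -> Volume:
    """Per-voxel Euclidean distance (mm) to the nearest background voxel:
    the radius of the largest inscribed sphere centred there."""
    mask = blood.data > 0
    if not mask.any():
        raise EmptyResultError("empty blood-pool label")
    dist = ndimage.distance_transform_edt(mask, sampling=blood.spacing)
    return Volume(dist, blood.affine.copy())


@dataclass
class Centerline:
    """Ordered centerline with per-point medial radius and area proxy."""

    points: np.ndarray       # (K, 3) world mm
    radius: np.ndarray       # (K,) mm
    arc_length: np.ndarray   # (K,) cumulative mm, starts at 0
    seed: np.ndarray
    target: np.ndarray

    @property
    def area(self) -> np.ndarray:
        """Cross-sectional area proxy pi r^2 (mm^2)."""
        return np.pi * self.radius ** 2

    def __len__(self) -> int:
        return len(self.points)


_OFFSETS_26 = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                        for k in (-1, 0, 1) if (i, j, k) > (0, 0, 0)])


def centerline(blood: Volume, seed, target,
               smoothing_window: int = 5) -> Centerline:
    """Medially-weighted shortest path from ``seed`` to ``target`` (world mm).

    Dijkstra on the 26-connected interior voxel graph with edge cost
    ``step length / medial_radius^2``, which pulls the path onto the medial
    axis; followed by a moving-average smoothing (window 5). Radius is the
    medial field sampled along the path.
    """
    seed = np.asarray(seed, float)
    target = np.asarray(target, float)
    mask = blood.data > 0
    rad = medial_radius_field(blood)
    inv = np.linalg.inv(blood.affine)

    def to_voxel(p, name):
        idx = np.round(p @ inv[:3, :3].T + inv[:3, 3]).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(mask.shape)) or \
                not mask[tuple(idx)]:
            raise LocationError(f"{name} point {p.tolist()} outside the blood pool")
        return idx

    vi = to_voxel(seed, "seed")
    vt = to_voxel(target, "target")
    if np.array_equal(vi, vt):
        raise PreconditionError("seed equals target: degenerate centerline")

    ids = -np.ones(mask.shape, dtype=np.int64)
    vox = np.argwhere(mask)
    ids[tuple(vox.T)] = np.arange(len(vox))
    rvals = np.maximum(rad.data[tuple(vox.T)], 0.25 * blood.spacing.min())

    rows, cols, costs = [], [], []
    for off in _OFFSETS_26:
        nb = vox + off
        ok = np.all((nb >= 0) & (nb < np.array(mask.shape)), axis=1)
        ok[ok] = mask[tuple(nb[ok].T)]
        a = ids[tuple(vox[ok].T)]
        b = ids[tuple(nb[ok].T)]
        steplen = float(np.linalg.norm(off * blood.spacing))
        rmid = 0.5 * (rvals[a] + rvals[b])
        rows.append(a); cols.append(b)
        costs.append(steplen / rmid ** 2)
    rows = np.concatenate(rows); cols = np.concatenate(cols)
    costs = np.concatenate(costs)
    n = len(vox)
    g = coo_matrix((costs, (rows, cols)), shape=(n, n)).tocsr()
    sid, tid = ids[tuple(vi)], ids[tuple(vt)]
    dist, pred = dijkstra(g, directed=False, indices=sid,
                          return_predecessors=True)
    if not np.isfinite(dist[tid]):
        raise ConnectivityError("no path between seed and target in the blood pool")
    path = [tid]
    while path[-1] != sid:
        path.append(pred[path[-1]])
    path = np.array(path[::-1])
    pts_idx = vox[path].astype(float)
    pts = pts_idx @ blood.affine[:3, :3].T + blood.affine[:3, 3]

    if smoothing_window > 1 and len(pts) > smoothing_window:
        w = smoothing_window
        pad = w // 2
        padded = np.concatenate([pts[:1].repeat(pad, 0), pts,
                                 pts[-1:].repeat(pad, 0)])
        kernel = np.ones(w) / w
        pts = np.stack([np.convolve(padded[:, c], kernel, mode="valid")
                        for c in range(3)], axis=1)

    coords = (pts @ inv[:3, :3].T + inv[:3, 3]).T
    radius = map_coordinates(rad.data, coords, order=1, mode="nearest")
    arc = np.concatenate([[0.0], np.cumsum(
        np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    return Centerline(pts, radius, arc, seed, target)


def detect_opening(cl: Centerline, rise_factor: float = 1.5,
                   window: float | None = None) -> int:
    """Index of the chamber opening along a centerline.

    Walking from the seed toward the target, the opening is the first point
    where the forward moving-median of the area (over ``window`` mm ahead)
    exceeds ``rise_factor`` times the running baseline median of the vessel
    segment traversed so far. With ``rise_factor=1.0`` this degenerates to
    triggering at the first positive fluctuation.
    """
    if len(cl) < 10:
        raise PreconditionError("centerline needs >= 10 points")
    step = float(np.mean(np.diff(cl.arc_length)))
    if window is None:
        window = 4.0 * step
    wn = max(3, int(round(window / step)) | 1)  # odd window, median-friendly
    area = cl.area
    forward = np.array([np.median(area[i:i + wn]) for i in range(len(cl))])
    trigger = None
    baseline = float(area[0])
    for i in range(2, len(cl)):
        baseline = float(np.median(area[:i + 1]))
        if forward[i] > rise_factor * baseline:
            trigger = i
            break
    if trigger is None:
        raise NoOpeningError("area profile never rises: no opening found")
    # refine to the onset of the rise: back off while the forward median is
    # still elevated (it leads the rise by ~half a window), then advance on
    # the raw profile to the last sample within 5% of the baseline
    onset = trigger
    while onset > 0 and forward[onset - 1] > 1.05 * baseline:
        onset -= 1
    # a tight 2% flatness gate keeps the opening on the vessel side of the
    # junction, where the calibre still equals the vessel's
    while onset + 1 <= trigger and area[onset + 1] <= 1.02 * baseline:
        onset += 1
    return onset


@dataclass
class ClipPlane:
    """A (possibly finite-disk) clipping plane."""

    origin: np.ndarray
    normal: np.ndarray
    radius: float | None = None   # disk extent; None = infinite plane
    mode: str = "automatic"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        n = np.asarray(self.normal, float)
        self.normal = n / np.linalg.norm(n)
        if self.radius is not None and self.radius <= 0:
            raise PreconditionError("disk radius must be positive")

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts, float) - self.origin) @ self.normal

    def inplane_distance(self, pts: np.ndarray) -> np.ndarray:
        v = np.asarray(pts, float) - self.origin
        d = v @ self.normal
        return np.linalg.norm(v - d[:, None] * self.normal, axis=-1)


def plane_at(cl: Centerline, index: int, radius_scale: float = 1.5) -> ClipPlane:
    """Automatic clip plane at a centerline point: origin there, normal the
    local tangent (central difference, pointing toward the target), disk
    radius ``radius_scale`` x the local medial radius."""
    i = int(index)
    if not 0 <= i < len(cl):
        raise PreconditionError(f"index {i} outside centerline")
    lo, hi = max(i - 1, 0), min(i + 1, len(cl) - 1)
    tangent = cl.points[hi] - cl.points[lo]
    return ClipPlane(cl.points[i], tangent, radius_scale * float(cl.radius[i]),
                     mode="automatic")


def plane_semi_auto(cl: Centerline, index: int, radius: float) -> ClipPlane:
    """As :func:`plane_at` but with a user-set disk radius."""
    p = plane_at(cl, index)
    return ClipPlane(p.origin, p.normal, float(radius), mode="semi_automatic")


def plane_from_seeds(seeds: LandmarkSet) -> ClipPlane:
    """Manual plane: least-squares fit through >= 3 non-collinear seeds;
    disk radius = max seed distance from the centroid."""
    pts = seeds.points
    if len(pts) < 3:
        raise PreconditionError("manual plane needs >= 3 seeds")
    c = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - c)
    if s[1] < 1e-9 * max(s[0], 1e-30):
        raise PreconditionError("collinear seeds: degenerate plane")
    radius = float(np.linalg.norm(pts - c, axis=1).max())
    return ClipPlane(c, vt[-1], radius, mode="manual")


@dataclass
class ClipResult:
    """Outcome of a clip: the truncated object, the rim loop (mesh clips
    only) and vessel metrics."""

    mesh: SurfaceMesh | None = None
    volume: Volume | None = None
    rim: np.ndarray | None = None          # ordered vertex indices (mesh)
    metrics: dict = field(default_factory=dict)


def _clip_volume(vol: Volume, plane: ClipPlane, keep_side: int) -> ClipResult:
    mask = vol.data > 0
    centers = vol.voxel_centers_world().reshape(-1, 3)
    d = plane.signed_distance(centers).reshape(vol.shape)
    discard = mask & (keep_side * d < 0)
    if not discard.any():
        raise NoIntersectionError("plane does not intersect the object")
    near = np.abs(d) <= 1.0 * float(vol.spacing.max())
    if plane.radius is not None:
        inplane = plane.inplane_distance(centers).reshape(vol.shape)
        near &= inplane <= plane.radius
    struct = ndimage.generate_binary_structure(3, 3)
    comps, ncomp = ndimage.label(discard, structure=struct)
    severed = np.zeros(vol.shape, dtype=bool)
    touched = np.unique(comps[discard & near])
    for c in touched:
        if c > 0:
            severed |= comps == c
    if not severed.any():
        raise NoIntersectionError("disk does not reach the object")
    out = mask & ~severed
    removed = int(severed.sum())
    voxvol = float(np.prod(vol.spacing))
    return ClipResult(volume=Volume(out.astype(np.uint8), vol.affine.copy()),
                      metrics={"removed_voxels": removed,
                               "removed_volume_mm3": removed * voxvol})


def _order_loop(edges: list[tuple[int, int]]) -> np.ndarray:
    adj: dict[int, list[int]] = {}
    for a, b in edges:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    start = edges[0][0]
    loop = [start]
    prev = None
    cur = start
    while True:
        nxt = [v for v in adj[cur] if v != prev]
        if not nxt:
            break
        prev, cur = cur, nxt[0]
        if cur == start:
            break
        loop.append(cur)
    return np.array(loop, dtype=np.int64)


def _polygon_area(pts: np.ndarray, normal: np.ndarray) -> float:
    c = pts.mean(axis=0)
    cross = np.cross(pts - c, np.roll(pts, -1, axis=0) - c)
    return float(abs(0.5 * cross.sum(axis=0) @ normal))


def _clip_mesh(mesh: SurfaceMesh, plane: ClipPlane, keep_side: int) -> ClipResult:
    verts = mesh.vertices
    d = keep_side * plane.signed_distance(verts)
    eps = 1e-9
    sign = np.where(d > eps, 1, np.where(d < -eps, -1, 0))
    tri_sign = sign[mesh.triangles]
    has_neg = (tri_sign < 0).any(axis=1)
    keep_any = (tri_sign >= 0).any(axis=1)
    # a triangle is cut when it has discard-side vertices and any keep-side
    # (or exactly on-plane) vertex; on-plane cut points snap to the
    # existing vertex so rim edges remain edges of the mesh
    crossing = has_neg & keep_any
    if plane.radius is not None:
        inplane = plane.inplane_distance(verts)
        reach = (inplane[mesh.triangles] <= plane.radius * 1.05).any(axis=1)
        crossing &= reach
    if not crossing.any():
        raise NoIntersectionError("plane does not intersect the mesh")
    all_neg = ~keep_any  # fully on discard side

    # severed discard components: edge-connected sets of discard triangles
    # that share a vertex with a crossing triangle
    discard_idx = np.flatnonzero(all_neg)
    cross_verts = set(mesh.triangles[crossing].ravel().tolist())
    edge_map: dict[tuple[int, int], list[int]] = {}
    for t in discard_idx:
        a, b, c = mesh.triangles[t]
        for e in ((a, b), (b, c), (c, a)):
            edge_map.setdefault(tuple(sorted(map(int, e))), []).append(int(t))
    parent = {int(t): int(t) for t in discard_idx}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for tris in edge_map.values():
        for t in tris[1:]:
            parent[find(t)] = find(tris[0])
    severed_roots = {find(int(t)) for t in discard_idx
                     if cross_verts & set(map(int, mesh.triangles[t]))}
    severed = np.zeros(mesh.n_triangles, dtype=bool)
    for t in discard_idx:
        if find(int(t)) in severed_roots:
            severed[t] = True

    new_verts = [verts]
    n_base = len(verts)
    cut_cache: dict[tuple[int, int], int] = {}
    next_id = n_base
    extra: list[np.ndarray] = []

    def cut_point(a: int, b: int) -> int:
        nonlocal next_id
        key = (min(a, b), max(a, b))
        if key in cut_cache:
            return cut_cache[key]
        t = d[a] / (d[a] - d[b])
        if t <= 1e-6:      # crossing sits on an existing vertex: reuse it
            cut_cache[key] = a
            return a
        if t >= 1 - 1e-6:
            cut_cache[key] = b
            return b
        p = verts[a] + t * (verts[b] - verts[a])
        extra.append(p)
        cut_cache[key] = next_id
        next_id += 1
        return cut_cache[key]

    out_tris: list[tuple[int, int, int]] = []
    rim_edges: list[tuple[int, int]] = []
    keep_whole = ~severed & ~crossing
    out_tris.extend(map(tuple, mesh.triangles[keep_whole].tolist()))
    for t in np.flatnonzero(crossing):
        tri = [int(v) for v in mesh.triangles[t]]
        keep_v = [sign[v] >= 0 for v in tri]
        n_keep = sum(keep_v)
        if n_keep == 0:
            continue
        if n_keep == 3:
            out_tris.append(tuple(tri))
            continue
        # cyclic rotation (winding-preserving) so the lone vertex is first
        if n_keep == 1:
            k = keep_v.index(True)
            a, b, c = tri[k:] + tri[:k]  # a kept, b & c discarded
            i1, i2 = cut_point(a, b), cut_point(c, a)
            out_tris.append((a, i1, i2))
            if i1 != i2:
                rim_edges.append((i1, i2))
        else:
            k = keep_v.index(False)
            a, b, c = tri[k:] + tri[:k]  # a discarded, b & c kept
            i1, i2 = cut_point(a, b), cut_point(c, a)
            out_tris.append((i1, b, c))
            out_tris.append((i1, c, i2))
            if i1 != i2:
                rim_edges.append((i2, i1))

    all_verts = np.vstack([verts] + extra) if extra else verts.copy()
    tris = np.array(out_tris, dtype=np.int64)
    # drop unused vertices
    used = np.unique(tris)
    remap = -np.ones(len(all_verts), dtype=np.int64)
    remap[used] = np.arange(len(used))
    new_mesh_verts = all_verts[used]
    new_tris = remap[tris]
    # filter any degenerate slivers produced by near-plane vertices
    p = new_mesh_verts[new_tris]
    areas = 0.5 * np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]),
                                 axis=1)
    new_tris = new_tris[areas > 1e-9]
    out_mesh = SurfaceMesh(new_mesh_verts, new_tris)

    rim = None
    metrics: dict = {}
    if rim_edges:
        rim_edges2 = [(int(remap[a]), int(remap[b])) for a, b in rim_edges
                      if remap[a] >= 0 and remap[b] >= 0 and remap[a] != remap[b]]
        if rim_edges2:
            rim = _order_loop(rim_edges2)
            rim_pts = out_mesh.vertices[rim]
            area = _polygon_area(rim_pts, plane.normal)
            metrics["opening_area_mm2"] = area
            metrics["equivalent_diameter_mm"] = float(2.0 * np.sqrt(area / np.pi))
    return ClipResult(mesh=out_mesh, rim=rim, metrics=metrics)


def clip(obj: Volume | SurfaceMesh, plane: ClipPlane, keep_side: int = 1,
         cl: Centerline | None = None,
         opening_index: int | None = None) -> ClipResult:
    """Truncate a segmentation or mesh at a (finite-disk) plane.

    ``keep_side=+1`` keeps the half-space where ``(x - origin) . normal > 0``.
    With a finite disk, only discard-side material connected through the
    disk is severed, so clipping one vein cannot cut the far wall. Mesh
    clips re-triangulate crossing triangles at the plane and return the rim
    vertex loop (consumable by scar corridor analysis) plus opening metrics;
    passing the centerline and opening index adds the vessel length.
    """
    if keep_side not in (1, -1):
        raise PreconditionError("keep_side must be +1 or -1")
    if isinstance(obj, Volume):
        res = _clip_volume(obj, plane, keep_side)
    else:
        res = _clip_mesh(obj, plane, keep_side)
    if cl is not None and opening_index is not None:
        res.metrics["vessel_length_mm"] = float(cl.arc_length[opening_index])
    return res
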