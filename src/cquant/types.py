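"""Core domain types: volumes, surface meshes and landmark sets.

All geometry lives in world millimetres. Voxel indices are 0-based and the
affine maps index -> mm following the NIfTI convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, PreconditionError


@dataclass
class Volume:
    """A 3-D scalar or label image with a voxel-index -> world-mm affine.

    Parameters
    ----------
    data
        3-D array of intensities (arbitrary units) or integer labels.
    affine
        4x4 homogeneous map taking 0-based voxel indices to world mm.
    frame_time
        Optional acquisition time of this frame in seconds.
    """

    data: np.ndarray
    affine: np.ndarray
    frame_time: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise FormatError(f"volume data must be 3-D, got shape {self.data.shape}")
        if any(s < 2 for s in self.data.shape):
            raise FormatError(f"volume needs >= 2 voxels per axis, got {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise FormatError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise FormatError("affine is not invertible")
        if np.any(self.spacing <= 0):
            raise FormatError("voxel spacings must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacings in mm (column norms of the 3x3 affine block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map (..., 3) voxel indices (may be fractional) to world mm."""
        idx = np.asarray(idx, dtype=float)
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_index(self, pts: np.ndarray) -> np.ndarray:
        """Map (..., 3) world-mm points to fractional voxel indices."""
        pts = np.asarray(pts, dtype=float)
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates of every voxel centre, shape (*shape, 3)."""
        idx = np.stack(
            np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij"), axis=-1
        )
        return self.index_to_world(idx)


def _triangle_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    p = vertices[triangles]
    return 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
    )


@dataclass
class SurfaceMesh:
    """Triangle surface mesh in world mm with named data attachments.

    ``vertex_data`` values have length N (per vertex), ``triangle_data``
    values length M (per triangle). Degenerate (zero-area) triangles are
    rejected on construction.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    vertex_data: dict[str, np.ndarray] = field(default_factory=dict)
    triangle_data: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        n = len(self.vertices)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= n
        ):
            raise FormatError("triangle indices out of range")
        areas = _triangle_areas(self.vertices, self.triangles)
        if np.any(areas <= 1e-12):
            bad = int(np.argmin(areas))
            raise FormatError(f"degenerate triangle at index {bad} (area ~ 0)")
        for name, arr in self.vertex_data.items():
            arr = np.asarray(arr)
            if len(arr) != n:
                raise FormatError(f"vertex_data[{name!r}] length {len(arr)} != {n}")
            self.vertex_data[name] = arr
        m = len(self.triangles)
        for name, arr in self.triangle_data.items():
            arr = np.asarray(arr)
            if len(arr) != m:
                raise FormatError(f"triangle_data[{name!r}] length {len(arr)} != {m}")
            self.triangle_data[name] = arr

    # -- geometry ---------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        return _triangle_areas(self.vertices, self.triangles)

    def total_area(self) -> float:
        return float(self.triangle_areas().sum())

    def triangle_normals(self) -> np.ndarray:
        """Unit normals following the triangle winding order."""
        p = self.vertices[self.triangles]
        n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def triangle_centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)

    def signed_volume(self) -> float:
        """Enclosed volume by the divergence theorem (signed by winding)."""
        p = self.vertices[self.triangles]
        return float(np.einsum("ij,ij->i", p[:, 0], np.cross(p[:, 1], p[:, 2])).sum() / 6.0)

    def oriented_outward(self) -> "SurfaceMesh":
        """Return a copy with consistently outward winding (signed volume > 0)."""
        if self.signed_volume() >= 0:
            return self
        tris = self.triangles[:, [0, 2, 1]]
        return SurfaceMesh(self.vertices.copy(), tris,
                           dict(self.vertex_data), dict(self.triangle_data))

    def edges(self) -> np.ndarray:
        """All directed edges as an (3M, 2) array."""
        t = self.triangles
        return np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])

    def is_closed(self) -> bool:
        """True iff every undirected edge is shared by exactly two triangles."""
        e = np.sort(self.edges(), axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def euler_characteristic(self) -> int:
        e = np.sort(self.edges(), axis=1)
        n_edges = len(np.unique(e, axis=0))
        return self.n_vertices - n_edges + self.n_triangles


@dataclass
class LandmarkSet:
    """Ordered, labelled world-mm landmarks."""

    labels: list[str]
    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 1:
            raise PreconditionError("a landmark set needs at least one point")
        if len(self.labels) != len(self.points):
            raise PreconditionError("labels and points must have equal length")
        if len(set(self.labels)) != len(self.labels):
            raise PreconditionError("landmark labels must be unique")

    def __len__(self) -> int:
        return len(self.points)
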