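"""Cubic B-spline free-form deformation (FFD): transform, registration,
mesh tracking.

The deformation ``h(x) = x + u(x)`` displaces world points by a tensor
product of cubic B-splines over a lattice of control-point displacements.
Registration minimises the sum of squared intensity differences (SSD)
between a fixed image and the warped moving image by gradient descent, in a
coarse-to-fine multi-level scheme in which the control lattice spacing
halves at every level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import DomainError, OutOfSupportError
from .types import SurfaceMesh, Volume

__all__ = ["BSplineFFD", "ffd_evaluate", "ffd_register", "track_mesh"]


def _bspline_weights(f: np.ndarray) -> np.ndarray:
    """Cubic B-spline basis values at fractional offsets ``f`` in [0, 1).

    Returns shape (len(f), 4): weights for control points i-1, i, i+1, i+2.
    The four weights sum to 1 (partition of unity).
    """
    f2 = f * f
    f3 = f2 * f
    return np.stack([
        (1 - f) ** 3 / 6.0,
        (3 * f3 - 6 * f2 + 4) / 6.0,
        (-3 * f3 + 3 * f2 + 3 * f + 1) / 6.0,
        f3 / 6.0,
    ], axis=-1)


@dataclass
class BSplineFFD:
    """Free-form deformation parametrised by control-point displacements.

    Parameters
    ----------
    origin
        World-mm position of lattice node (0, 0, 0).
    spacing
        Lattice node spacing per axis (mm).
    control_disp
        (Nx, Ny, Nz, 3) control-point displacement vectors (mm).
    level
        Refinement level this lattice belongs to (coarse = 0).
    """

    origin: np.ndarray
    spacing: np.ndarray
    control_disp: np.ndarray
    level: int = 0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.spacing = np.asarray(self.spacing, float).reshape(3)
        self.control_disp = np.asarray(self.control_disp, float)
        if np.any(self.spacing <= 0):
            raise ValueError("lattice spacing must be positive")
        if self.control_disp.ndim != 4 or self.control_disp.shape[3] != 3:
            raise ValueError("control_disp must have shape (Nx, Ny, Nz, 3)")
        if any(n < 4 for n in self.control_disp.shape[:3]):
            raise ValueError("lattice needs >= 4 control points per axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.control_disp.shape[:3]

    def support_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """World bbox inside which the spline is fully supported."""
        n = np.array(self.shape)
        lo = self.origin + self.spacing
        hi = self.origin + (n - 3) * self.spacing
        return lo, hi

    def displacement(self, points: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Displacement u(p) at world points, shape (N, 3).

        With ``clamp=False`` points outside the valid support raise
        :class:`OutOfSupportError`; with ``clamp=True`` lattice indices are
        clamped (used internally for level initialisation).
        """
        pts = np.asarray(points, float).reshape(-1, 3)
        t = (pts - self.origin) / self.spacing
        i = np.floor(t).astype(np.int64)
        n = np.array(self.shape)
        if clamp:
            i = np.clip(i, 1, n - 3)
        else:
            bad = np.any((i < 1) | (i > n - 3), axis=1)
            if bad.any():
                idx = np.flatnonzero(bad)
                raise OutOfSupportError(
                    f"{idx.size} point(s) outside B-spline support; first "
                    f"offenders: {idx[:5].tolist()}", indices=idx)
        f = t - i
        w = [_bspline_weights(f[:, ax]) for ax in range(3)]
        disp = np.zeros_like(pts)
        c = self.control_disp
        for a in range(4):
            wa = w[0][:, a]
            ia = i[:, 0] + a - 1
            for b in range(4):
                wab = wa * w[1][:, b]
                ib = i[:, 1] + b - 1
                for d in range(4):
                    wabd = wab * w[2][:, d]
                    disp += wabd[:, None] * c[ia, ib, i[:, 2] + d - 1]
        return disp

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return ffd_evaluate(self, points)


def ffd_evaluate(ffd: BSplineFFD, points: np.ndarray) -> np.ndarray:
    """Apply the deformation: returns points + B-spline displacement."""
    pts = np.asarray(points, float).reshape(-1, 3)
    return pts + ffd.displacement(pts)


def track_mesh(mesh: SurfaceMesh, ffds: list[BSplineFFD]) -> list[SurfaceMesh]:
    """Warp a mesh through a sequence of frame deformations.

    Frame ``t`` vertices are ``ffd_evaluate(ffds[t], vertices)``;
    connectivity and attachments are carried over unchanged.
    """
    out = []
    for ffd in ffds:
        verts = ffd_evaluate(ffd, mesh.vertices)
        out.append(SurfaceMesh(verts, mesh.triangles.copy(),
                               dict(mesh.vertex_data), dict(mesh.triangle_data)))
    return out


# ---------------------------------------------------------------------------
# Registration

def make_lattice(lo: np.ndarray, hi: np.ndarray, spacing: float,
                 level: int = 0) -> BSplineFFD:
    """Zero-displacement lattice whose valid support covers [lo, hi]."""
    lo = np.asarray(lo, float)
    hi = np.asarray(hi, float)
    origin = lo - spacing
    n = np.ceil((hi - lo) / spacing - 1e-9).astype(int) + 5
    return BSplineFFD(origin, np.full(3, float(spacing)), np.zeros((*n, 3)), level)


class _SsdObjective:
    """SSD between fixed samples and the moving image warped by an FFD,
    with its analytic gradient w.r.t. the control displacements."""

    def __init__(self, points: np.ndarray, fvals: np.ndarray,
                 moving: Volume, lattice: BSplineFFD):
        self.points = points
        self.fvals = fvals
        self.minv = np.linalg.inv(moving.affine)
        self.mdata = np.ascontiguousarray(moving.data, dtype=np.float32)
        # image gradient in index space, mapped to world via the chain rule
        self.gidx = [g.astype(np.float32) for g in np.gradient(self.mdata)]
        self.lattice = lattice
        # precompute per-point control indices and tensor weights (64 taps)
        t = (points - lattice.origin) / lattice.spacing
        i = np.floor(t).astype(np.int64)
        n = np.array(lattice.shape)
        i = np.clip(i, 1, n - 3)  # sample points sit inside by construction
        f = t - i
        w = [_bspline_weights(f[:, ax]).astype(np.float32) for ax in range(3)]
        ny, nz = lattice.shape[1], lattice.shape[2]
        self.taps: list[tuple[np.ndarray, np.ndarray]] = []
        for a in range(4):
            for b in range(4):
                for d in range(4):
                    wk = w[0][:, a] * w[1][:, b] * w[2][:, d]
                    idx = ((i[:, 0] + a - 1) * ny + (i[:, 1] + b - 1)) * nz \
                        + (i[:, 2] + d - 1)
                    self.taps.append((idx, wk))
        self.n_control = int(np.prod(lattice.shape))

    def _warped_index_coords(self, cflat: np.ndarray) -> np.ndarray:
        disp = np.zeros_like(self.points)
        for idx, wk in self.taps:
            disp += wk[:, None] * cflat[idx]
        p = self.points + disp
        return p @ self.minv[:3, :3].T + self.minv[:3, 3]

    def ssd(self, cflat: np.ndarray) -> float:
        coords = self._warped_index_coords(cflat)
        mv = map_coordinates(self.mdata, coords.T, order=1, mode="nearest")
        r = mv - self.fvals
        if not np.isfinite(r).all():
            raise DomainError("non-finite SSD: image samples are NaN")
        return float(r @ r)

    def ssd_and_grad(self, cflat: np.ndarray) -> tuple[float, np.ndarray]:
        coords = self._warped_index_coords(cflat)
        mv = map_coordinates(self.mdata, coords.T, order=1, mode="nearest")
        r = mv - self.fvals
        if not np.isfinite(r).all():
            raise DomainError("non-finite SSD: image samples are NaN")
        gi = np.stack([map_coordinates(g, coords.T, order=1, mode="nearest")
                       for g in self.gidx], axis=1)
        gworld = gi @ self.minv[:3, :3]          # d(moving)/d(world mm)
        rg = (2.0 * r)[:, None] * gworld
        grad = np.zeros((self.n_control, 3))
        for idx, wk in self.taps:
            wrg = wk[:, None] * rg
            for c in range(3):
                grad[:, c] += np.bincount(idx, weights=wrg[:, c],
                                          minlength=self.n_control)
        return float(r @ r), grad


def _descend(obj: _SsdObjective, cflat: np.ndarray, step: float,
             iters: int, tol: float) -> tuple[np.ndarray, list[float]]:
    """Gradient descent with step halving on non-decrease. Returns the
    optimised controls and the SSD trace over accepted steps."""
    ssd, grad = obj.ssd_and_grad(cflat)
    trace = [ssd]
    lam = step
    for _ in range(iters):
        gmax = np.abs(grad).max()
        if gmax == 0 or lam < 1e-5:
            break
        direction = grad / gmax
        accepted = False
        while lam >= 1e-5:
            trial = cflat - lam * direction
            ssd_trial = obj.ssd(trial)
            if ssd_trial < ssd:
                accepted = True
                break
            lam *= 0.5
        if not accepted:
            break
        cflat = trial
        prev = ssd
        ssd, grad = obj.ssd_and_grad(cflat)
        # the line search guarantees ssd == ssd_trial < prev
        trace.append(ssd)
        if prev - ssd <= tol * max(prev, 1e-30):
            break
    return cflat, trace


def ffd_register(fixed: Volume, moving: Volume, levels: int = 4,
                 lattice_spacing: float = 10.0, step: float = 1.0,
                 iters: int = 100, tol: float = 1e-6,
                 return_trace: bool = False):
    """Multi-level B-spline FFD registration of ``moving`` onto ``fixed``.

    Minimises ``SSD(fixed(x), moving(x + u(x)))`` over control-point
    displacements. The lattice spacing starts at
    ``lattice_spacing * 2**(levels-1)`` and halves per level down to
    ``lattice_spacing``; each finer lattice is initialised from the coarser
    solution and optimised by gradient descent with step halving, so the
    SSD is non-increasing over accepted steps within every level.

    Parameters
    ----------
    levels
        Number of lattice refinement levels (>= 1).
    lattice_spacing
        Finest-level control spacing in mm.
    step
        Initial descent step: maximum control-point move per iteration (mm).
    iters
        Maximum accepted steps per level.
    tol
        Relative SSD decrease below which a level stops.

    Returns
    -------
    BSplineFFD (and the per-level SSD traces when ``return_trace``).
    """
    if levels < 1:
        raise ValueError("levels must be >= 1")
    # world bounding boxes; require overlap
    fidx = np.array(fixed.shape) - 1
    fcorn = fixed.index_to_world(np.array(np.meshgrid([0, fidx[0]], [0, fidx[1]],
                                 [0, fidx[2]], indexing="ij")).reshape(3, -1).T)
    midx = np.array(moving.shape) - 1
    mcorn = moving.index_to_world(np.array(np.meshgrid([0, midx[0]], [0, midx[1]],
                                  [0, midx[2]], indexing="ij")).reshape(3, -1).T)
    flo, fhi = fcorn.min(0), fcorn.max(0)
    mlo, mhi = mcorn.min(0), mcorn.max(0)
    if np.any(fhi < mlo) or np.any(mhi < flo):
        raise DomainError("fixed and moving images share no world-space overlap")

    all_points = fixed.voxel_centers_world().reshape(-1, 3)
    all_fvals = np.asarray(fixed.data, dtype=np.float32).ravel()

    ffd: BSplineFFD | None = None
    traces: list[list[float]] = []
    for lev in range(levels):
        spac = lattice_spacing * 2 ** (levels - 1 - lev)
        lattice = make_lattice(flo, fhi, spac, level=lev)
        cflat = np.zeros((int(np.prod(lattice.shape)), 3))
        if ffd is not None:
            # quasi-interpolation: seed new controls with the coarse
            # displacement sampled at the new control nodes
            nodes = np.stack(np.meshgrid(*(np.arange(s) for s in lattice.shape),
                                         indexing="ij"), axis=-1).reshape(-1, 3)
            node_pts = lattice.origin + nodes * lattice.spacing
            cflat = ffd.displacement(node_pts, clamp=True)
        # coarser levels use a subsampled image pyramid for speed
        stride = min(2 ** (levels - 1 - lev), 4)
        if stride > 1:
            keep = np.zeros(fixed.shape, dtype=bool)
            keep[::stride, ::stride, ::stride] = True
            keep = keep.ravel()
            pts, fv = all_points[keep], all_fvals[keep]
        else:
            pts, fv = all_points, all_fvals
        obj = _SsdObjective(pts, fv, moving, lattice)
        cflat, trace = _descend(obj, cflat, step, iters, tol)
        traces.append(trace)
        ffd = BSplineFFD(lattice.origin, lattice.spacing,
                         cflat.reshape(*lattice.shape, 3), level=lev)
    if return_trace:
        return ffd, traces
    return ffd
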