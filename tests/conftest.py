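"""Shared fixtures: phantoms and derived products reused across test modules.

Heavy objects (chamber phantom, Laplace solves) are session-scoped; every
fixture is deterministic.
"""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pytest

from cquant import clipper, phantoms, segment, thickness
from cquant.types import SurfaceMesh, Volume


@pytest.fixture(scope="session")
def sphere_volume() -> Volume:
    """Digitised sphere, radius 10 mm, 0.5 mm isotropic spacing."""
    sp, n = 0.5, 47
    orig = -sp * (n - 1) / 2
    c = orig + sp * np.arange(n)
    x, y, z = np.meshgrid(c, c, c, indexing="ij")
    mask = (x * x + y * y + z * z) <= 100.0
    aff = np.diag([sp, sp, sp, 1.0])
    aff[:3, 3] = orig
    return Volume(mask.astype(np.uint8), aff)


@pytest.fixture(scope="session")
def sphere_mesh(sphere_volume) -> SurfaceMesh:
    return segment.mesh_from_labels(sphere_volume, 1, smooth_iters=0)


def make_tube_volume(radius: float = 5.0, length: float = 40.0,
                     spacing: float = 1.0) -> Volume:
    """Straight cylinder along +z, axis through the volume centre."""
    half = radius + 3 * spacing
    nxy = 2 * int(np.ceil(half / spacing)) + 1
    nz = int(np.ceil(length / spacing)) + 5
    ox = -spacing * (nxy - 1) / 2
    cxy = ox + spacing * np.arange(nxy)
    cz = spacing * np.arange(nz)
    x, y, z = np.meshgrid(cxy, cxy, cz, indexing="ij")
    mask = (x * x + y * y <= radius * radius) & (z >= 0) & (z <= length)
    aff = np.diag([spacing, spacing, spacing, 1.0])
    aff[:3, 3] = [ox, ox, 0.0]
    return Volume(mask.astype(np.uint8), aff)


def make_cylinder_mesh(radius: float = 10.0, length: float = 30.0,
                       n_theta: int = 48, n_z: int = 31) -> SurfaceMesh:
    """Open parametric cylinder surface along +z (two boundary circles)."""
    theta = 2 * np.pi * np.arange(n_theta) / n_theta
    zs = np.linspace(0.0, length, n_z)
    verts = np.array([[radius * np.cos(t), radius * np.sin(t), z]
                      for z in zs for t in theta])
    tris = []
    for i in range(n_z - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            tris.append((a, b, c))
            tris.append((b, d, c))
    return SurfaceMesh(verts, np.array(tris))


@pytest.fixture(scope="session")
def chamber():
    """Single-vein chamber phantom with its full automatic-clip products."""
    vein = phantoms.VeinSpec([0, 0, 1], 5.0, 25.0)
    blood, truth = phantoms.make_chamber_with_veins(20.0, [vein], 1.0)
    mesh = segment.mesh_from_labels(blood, 1, 0)
    rad = clipper.medial_radius_field(blood)
    centre_idx = np.unravel_index(int(np.argmax(rad.data)), rad.shape)
    centre = rad.index_to_world(np.array(centre_idx, float))
    t = truth[0]
    seed = np.asarray(t["distal"]) - (t["radius"] + 2.0) * np.asarray(t["direction"])
    cl = clipper.centerline(blood, seed, centre)
    idx = clipper.detect_opening(cl)
    plane = clipper.plane_at(cl, idx)
    res = clipper.clip(mesh, plane, keep_side=1, cl=cl, opening_index=idx)
    return SimpleNamespace(blood=blood, truth=truth, mesh=mesh, radial=rad,
                           centre=centre, seed=seed, cl=cl, opening_index=idx,
                           plane=plane, clip=res, clipped=res.mesh, rim=res.rim)


@pytest.fixture(scope="session")
def slab_potential():
    slab = phantoms.make_slab_wall(10.0, 20.0, 0.5)
    pot = thickness.solve_laplace(slab)
    return slab, pot


@pytest.fixture(scope="session")
def shell_potential():
    shell = phantoms.make_spherical_shell(10.0, 15.0, 0.5)
    pot = thickness.solve_laplace(shell)
    return shell, pot
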