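"""File I/O: NIfTI volumes, VTK legacy polydata (ASCII), PLY, landmark JSON.

NIfTI goes through nibabel. The mesh codecs are deliberately small: they
support exactly the dialects the toolkit writes (triangle-only polydata with
scalar POINT_DATA/CELL_DATA; ASCII PLY with float vertex properties) so that
fixtures remain diffable text.
"""

from __future__ import annotations

import json
import os

import nibabel as nib
import numpy as np

from .errors import FormatError, UnsupportedCellError
from .types import LandmarkSet, SurfaceMesh, Volume

__all__ = [
    "read_volume", "write_volume", "read_mesh", "write_mesh",
    "read_landmarks", "write_landmarks",
]


# ---------------------------------------------------------------------------
# NIfTI volumes

def read_volume(path: str | os.PathLike) -> Volume:
    """Read a NIfTI-1/2 file into a :class:`Volume`."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # nibabel raises many concrete types
        raise FormatError(f"{path} is not readable as NIfTI: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return Volume(data=data, affine=np.asarray(img.affine, dtype=float))


def write_volume(v: Volume, path: str | os.PathLike) -> str:
    """Write a :class:`Volume` as NIfTI-1. Returns the path written."""
    path = os.fspath(path)
    img = nib.Nifti1Image(np.asarray(v.data), v.affine)
    nib.save(img, path)
    return path


# ---------------------------------------------------------------------------
# VTK legacy polydata (ASCII)

_VTK_HEADER = "# vtk DataFile Version 4.2"


def _write_vtk(mesh: SurfaceMesh, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{_VTK_HEADER}\ncquant surface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} float\n")
        for p in mesh.vertices:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        m = mesh.n_triangles
        fh.write(f"POLYGONS {m} {4 * m}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        if mesh.vertex_data:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, arr in mesh.vertex_data.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{x:.9g}" for x in np.asarray(arr, float)) + "\n")
        if mesh.triangle_data:
            fh.write(f"CELL_DATA {mesh.n_triangles}\n")
            for name, arr in mesh.triangle_data.items():
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{x:.9g}" for x in np.asarray(arr, float)) + "\n")


def _read_vtk(path: str) -> SurfaceMesh:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    if not lines or not lines[0].startswith("# vtk DataFile"):
        raise FormatError(f"{path}: missing VTK header")
    toks: list[str] = []
    for ln in lines[2:]:
        toks.extend(ln.split())
    i = 0

    def expect(word: str) -> None:
        nonlocal i
        if i >= len(toks) or toks[i].upper() != word:
            raise FormatError(f"{path}: expected {word!r} near token {i}")
        i += 1

    expect("ASCII")
    expect("DATASET")
    expect("POLYDATA")
    expect("POINTS")
    n = int(toks[i]); i += 2  # count, dtype
    verts = np.array(toks[i:i + 3 * n], dtype=float).reshape(n, 3)
    i += 3 * n
    expect("POLYGONS")
    m = int(toks[i]); total = int(toks[i + 1]); i += 2
    tris = []
    consumed = 0
    for _ in range(m):
        k = int(toks[i]); i += 1
        cell = [int(x) for x in toks[i:i + k]]
        i += k
        consumed += k + 1
        if k != 3:
            raise UnsupportedCellError(f"{path}: cell with {k} vertices; only triangles supported")
        tris.append(cell)
    if consumed != total:
        raise FormatError(f"{path}: POLYGONS size mismatch")
    tris_arr = np.array(tris, dtype=np.int64)
    if tris_arr.size and tris_arr.max() >= n:
        raise FormatError(f"{path}: dangling vertex index {tris_arr.max()} >= {n}")
    vertex_data: dict[str, np.ndarray] = {}
    triangle_data: dict[str, np.ndarray] = {}
    target = None
    count = 0
    while i < len(toks):
        word = toks[i].upper()
        if word == "POINT_DATA":
            target, count = vertex_data, int(toks[i + 1]); i += 2
        elif word == "CELL_DATA":
            target, count = triangle_data, int(toks[i + 1]); i += 2
        elif word == "SCALARS":
            name = toks[i + 1]; i += 4  # SCALARS name dtype ncomp
            if toks[i].upper() == "LOOKUP_TABLE":
                i += 2
            if target is None:
                raise FormatError(f"{path}: SCALARS outside POINT_DATA/CELL_DATA")
            target[name] = np.array(toks[i:i + count], dtype=float)
            i += count
        else:
            raise FormatError(f"{path}: unexpected token {toks[i]!r}")
    return SurfaceMesh(verts, tris_arr, vertex_data, triangle_data)


# ---------------------------------------------------------------------------
# PLY (ASCII)

def _write_ply(mesh: SurfaceMesh, path: str) -> None:
    props = list(mesh.vertex_data)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\ncomment cquant surface\n")
        fh.write(f"element vertex {mesh.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        for name in props:
            fh.write(f"property float {name}\n")
        fh.write(f"element face {mesh.n_triangles}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        cols = [mesh.vertices] + [np.asarray(mesh.vertex_data[p], float)[:, None] for p in props]
        for row in np.hstack(cols):
            fh.write(" ".join(f"{x:.9g}" for x in row) + "\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")


def _read_ply(path: str) -> SurfaceMesh:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise FormatError(f"{path}: not a PLY file")
    i = 1
    n_vert = n_face = 0
    vert_props: list[str] = []
    element = None
    while i < len(lines):
        t = lines[i].split()
        i += 1
        if not t or t[0] == "comment":
            continue
        if t[0] == "format":
            if t[1] != "ascii":
                raise FormatError(f"{path}: only ASCII PLY supported")
        elif t[0] == "element":
            element = t[1]
            if element == "vertex":
                n_vert = int(t[2])
            elif element == "face":
                n_face = int(t[2])
        elif t[0] == "property" and element == "vertex" and t[1] != "list":
            vert_props.append(t[-1])
        elif t[0] == "end_header":
            break
    if vert_props[:3] != ["x", "y", "z"]:
        raise FormatError(f"{path}: vertex properties must start with x y z")
    rows = np.array([lines[i + k].split() for k in range(n_vert)], dtype=float)
    i += n_vert
    verts = rows[:, :3]
    vertex_data = {name: rows[:, 3 + j] for j, name in enumerate(vert_props[3:])}
    tris = []
    for k in range(n_face):
        t = [int(x) for x in lines[i + k].split()]
        if t[0] != 3:
            raise UnsupportedCellError(f"{path}: face with {t[0]} vertices; only triangles supported")
        tris.append(t[1:4])
    tris_arr = np.array(tris, dtype=np.int64).reshape(-1, 3)
    if tris_arr.size and tris_arr.max() >= n_vert:
        raise FormatError(f"{path}: dangling vertex index")
    return SurfaceMesh(verts, tris_arr, vertex_data, {})


def read_mesh(path: str | os.PathLike) -> SurfaceMesh:
    """Read a surface mesh from VTK legacy polydata (ASCII) or PLY."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    if path.endswith(".ply"):
        return _read_ply(path)
    return _read_vtk(path)


def write_mesh(mesh: SurfaceMesh, path: str | os.PathLike) -> str:
    """Write a mesh as VTK legacy ASCII polydata (.vtk) or PLY (.ply)."""
    path = os.fspath(path)
    if path.endswith(".ply"):
        _write_ply(mesh, path)
    else:
        _write_vtk(mesh, path)
    return path


# ---------------------------------------------------------------------------
# Landmarks

def read_landmarks(path: str | os.PathLike) -> LandmarkSet:
    """Read landmarks from JSON: [{"label": str, "xyz": [x, y, z]}, ...]."""
    with open(path) as fh:
        items = json.load(fh)
    try:
        labels = [it["label"] for it in items]
        pts = np.array([it["xyz"] for it in items], dtype=float)
    except (KeyError, TypeError) as exc:
        raise FormatError(f"{path}: landmark JSON must be a list of "
                          '{"label", "xyz"} objects') from exc
    return LandmarkSet(labels, pts)


def write_landmarks(lm: LandmarkSet, path: str | os.PathLike) -> str:
    items = [{"label": lab, "xyz": [float(x) for x in p]}
             for lab, p in zip(lm.labels, lm.points)]
    with open(path, "w") as fh:
        json.dump(items, fh, indent=1)
    return os.fspath(path)
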