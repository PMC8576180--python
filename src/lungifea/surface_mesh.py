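"""Triangulated open-surface meshes for membrane models of the lung surface.

The geometry of interest is the visible portion of a lung lobe, captured as a
triangulated open surface (an STL exported from a stereo-DIC reconstruction or
a synthetic stand-in).  Each triangle is a three-node membrane element with a
fixed reference thickness; the open boundary (perimeter) is where measured
displacement boundary conditions are applied.

Units are mm / kPa / mN throughout (1 kPa = 1 mN/mm^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "SurfaceMesh",
    "LocalFrames",
    "read_stl",
    "write_stl",
    "compute_local_frames",
    "perimeter_nodes",
    "enclosed_volume_change",
    "write_vtk",
]

#: conversion used whenever a pressure arrives in cmH2O
CMH2O_TO_KPA = 0.0980665

_MERGE_TOL = 1e-6  # mm; duplicate-vertex merge tolerance on STL read


class MeshFormatError(ValueError):
    """Raised for unreadable files or degenerate facets."""


class DegenerateFrameError(ValueError):
    """Raised when an element normal is (anti)parallel to the AP axis."""


@dataclass
class SurfaceMesh:
    """An open triangulated surface with membrane metadata.

    Parameters
    ----------
    node_coords : (n_nodes, 3) float array, mm
    triangles : (n_elems, 3) int array
        Node triples; winding defines the outward normal.
    thickness : float, mm
        Membrane reference thickness (default 1.0).
    ap_axis : (3,) unit vector
        Anterior–posterior direction of the global frame, used to orient
        per-element local frames (and hence fiber directions).  A bare STL
        carries no anatomical axes, so this is supplied alongside the mesh.
    """

    node_coords: np.ndarray
    triangles: np.ndarray
    thickness: float = 1.0
    ap_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))

    def __post_init__(self) -> None:
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.node_coords.ndim != 2 or self.node_coords.shape[1] != 3:
            raise ValueError("node_coords must be (n_nodes, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (n_elems, 3)")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.node_coords)
        ):
            raise ValueError("triangle refers to an invalid node index")
        if not self.thickness > 0:
            raise ValueError("thickness must be positive")
        ap = np.asarray(self.ap_axis, dtype=float)
        n = np.linalg.norm(ap)
        if not n > 0:
            raise ValueError("ap_axis must be nonzero")
        self.ap_axis = ap / n
        areas = self.areas()
        if np.any(areas <= 0):
            bad = int(np.argmin(areas))
            raise MeshFormatError(f"degenerate (zero-area) element {bad}")
        # open 2-manifold: each edge used by at most two triangles
        edges = self._edges_sorted()
        _, counts = np.unique(edges, axis=0, return_counts=True)
        if np.any(counts > 2):
            raise ValueError("mesh is not 2-manifold (edge shared by >2 triangles)")

    # -- basic measures -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    @property
    def n_elems(self) -> int:
        return len(self.triangles)

    def tri_coords(self) -> np.ndarray:
        """(n_elems, 3, 3) reference coordinates of each triangle's nodes."""
        return self.node_coords[self.triangles]

    def areas(self) -> np.ndarray:
        x = self.tri_coords()
        return 0.5 * np.linalg.norm(
            np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]), axis=1
        )

    def normals(self) -> np.ndarray:
        """Unit normals per element, oriented by triangle winding."""
        x = self.tri_coords()
        n = np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def _edges_sorted(self) -> np.ndarray:
        t = self.triangles
        edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        return np.sort(edges, axis=1)


@dataclass
class LocalFrames:
    """Orthonormal right-handed frame per element.

    ``z_axis`` is the outward element normal, ``y_axis`` the in-plane
    projection of the anterior–posterior axis, ``x_axis = y × z`` closing the
    right-handed triad (so that x, y, z in that order are right-handed).
    """

    x_axis: np.ndarray
    y_axis: np.ndarray
    z_axis: np.ndarray


# ---------------------------------------------------------------------------
# I/O


def read_stl(path, thickness: float = 1.0, ap_axis=(0.0, 1.0, 0.0)) -> SurfaceMesh:
    """Read a binary or ASCII STL into a :class:`SurfaceMesh`.

    Duplicate vertices within 1e-6 mm are merged; triangle winding is kept.
    Zero-area facets raise :class:`MeshFormatError` naming the facet.
    """
    try:
        tm = trimesh.load(str(path), file_type="stl", force="mesh", process=False)
    except Exception as exc:  # pragma: no cover - trimesh error text varies
        raise MeshFormatError(f"cannot read STL {path!r}: {exc}") from exc
    verts = np.asarray(tm.vertices, dtype=float)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if faces.size == 0:
        raise MeshFormatError(f"STL {path!r} contains no facets")
    verts, faces = _merge_close_vertices(verts, faces, tol=_MERGE_TOL)
    a = 0.5 * np.linalg.norm(
        np.cross(verts[faces[:, 1]] - verts[faces[:, 0]],
                 verts[faces[:, 2]] - verts[faces[:, 0]]), axis=1)
    if np.any(a <= 0):
        raise MeshFormatError(f"degenerate (zero-area) facet {int(np.argmin(a))}")
    return SurfaceMesh(verts, faces, thickness=thickness, ap_axis=np.asarray(ap_axis))


def write_stl(mesh: SurfaceMesh, path) -> None:
    """Write the mesh as binary STL (winding preserved)."""
    tm = trimesh.Trimesh(
        vertices=mesh.node_coords, faces=mesh.triangles, process=False
    )
    tm.export(str(path), file_type="stl")


def _merge_close_vertices(verts, faces, tol):
    """Merge vertices closer than ``tol``; preserves first-seen coordinates."""
    # quantize to a grid finer than tol; exact duplicates and near-duplicates
    # within the rounding cell collapse together
    key = np.round(verts / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first)
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    new_verts = verts[first[order]]
    new_faces = rank[inverse][faces]
    return new_verts, new_faces


# ---------------------------------------------------------------------------
# Local frames, perimeter, volume


def compute_local_frames(mesh: SurfaceMesh) -> LocalFrames:
    """Per-element orthonormal frames (z = outward normal, y = in-plane AP).

    Raises :class:`DegenerateFrameError` if any element normal is within
    ~1e-6 rad of the AP axis (the in-plane projection of the AP direction
    vanishes and the frame is undefined).
    """
    z = mesh.normals()
    ap = mesh.ap_axis
    y = ap[None, :] - (z @ ap)[:, None] * z
    ny = np.linalg.norm(y, axis=1)
    bad = ny < 1e-6
    if np.any(bad):
        raise DegenerateFrameError(
            f"ap_axis parallel to normal of element {int(np.argmax(bad))}"
        )
    y = y / ny[:, None]
    x = np.cross(y, z)
    return LocalFrames(x_axis=x, y_axis=y, z_axis=z)


def perimeter_nodes(mesh: SurfaceMesh) -> np.ndarray:
    """Sorted indices of nodes incident to boundary edges.

    A boundary edge belongs to exactly one triangle; a closed surface
    therefore returns an empty array.
    """
    edges = mesh._edges_sorted()
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    boundary = uniq[counts == 1]
    return np.unique(boundary)


def enclosed_volume_change(mesh: SurfaceMesh, u: np.ndarray) -> float:
    """Signed volume swept by the surface as it moves from X to X + u (mm^3).

    Each triangle sweeps an (in general twisted) prism between its reference
    and displaced positions; the prism volumes are computed exactly by closing
    each prism with its side walls and summing signed cone volumes of the
    resulting facets.  Side walls shared by adjacent elements cancel, so the
    sum is the swept volume of the whole patch and is additive over disjoint
    patches.  Positive along the outward normal (winding convention).
    """
    u = np.asarray(u, dtype=float)
    if u.shape != mesh.node_coords.shape:
        raise ValueError("u must be (n_nodes, 3)")
    a = mesh.tri_coords()          # (E, 3, 3)
    ut = u[mesh.triangles]
    # V = int_0^1 int_T  u . n  dA ds  with x_i(s) = a_i + s u_i:
    #   (1/6) (u1+u2+u3) . [e2 x e3 + (e2 x f3 + f2 x e3)/2 + (f2 x f3)/3]
    # where e_k = a_k - a_1, f_k = u_k - u_1.  Exact for linear vertex
    # motion, and identically zero displacement gives exactly zero.
    U = ut.sum(axis=1)
    e2 = a[:, 1] - a[:, 0]
    e3 = a[:, 2] - a[:, 0]
    f2 = ut[:, 1] - ut[:, 0]
    f3 = ut[:, 2] - ut[:, 0]
    flux = (
        np.cross(e2, e3)
        + 0.5 * (np.cross(e2, f3) + np.cross(f2, e3))
        + np.cross(f2, f3) / 3.0
    )
    return float(np.einsum("ij,ij->", U, flux) / 6.0)


# ---------------------------------------------------------------------------
# VTK output (legacy ASCII) for visualisation


def write_vtk(
    mesh: SurfaceMesh,
    path,
    point_data: dict | None = None,
    cell_data: dict | None = None,
) -> None:
    """Write a legacy-ASCII VTK unstructured grid with optional fields.

    ``point_data`` values are (n_nodes,) scalars or (n_nodes, 3) vectors;
    ``cell_data`` likewise per element.  Intended for ParaView inspection of
    stage displacements, stresses and principal-strain vectors.
    """
    lines = [
        "# vtk DataFile Version 3.0",
        "lungifea surface",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} double",
    ]
    lines += [" ".join(f"{v:.9g}" for v in row) for row in mesh.node_coords]
    lines.append(f"CELLS {mesh.n_elems} {4 * mesh.n_elems}")
    lines += ["3 " + " ".join(str(i) for i in tri) for tri in mesh.triangles]
    lines.append(f"CELL_TYPES {mesh.n_elems}")
    lines += ["5"] * mesh.n_elems  # VTK_TRIANGLE

    def emit(block: dict, n: int, header: str):
        lines.append(f"{header} {n}")
        for name, arr in block.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in arr)
            else:
                lines.append(f"VECTORS {name} double")
                lines.extend(" ".join(f"{v:.9g}" for v in row) for row in arr)

    if point_data:
        emit(point_data, mesh.n_nodes, "POINT_DATA")
    if cell_data:
        emit(cell_data, mesh.n_elems, "CELL_DATA")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
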