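"""Surface meshes, nodal scalar fields, smoothing, and quality checks.

Conventions used throughout the package:

* coordinates are in millimetres, with Z the craniocaudal axis of a supine
  CT-derived geometry (superior = larger Z, configurable downstream);
* nodal scalar fields (von Mises wall stress) are in N/cm^2 and are linked
  to a mesh purely by node order — no node-ID remapping happens on load.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import trimesh

from . import vtk_io
from .errors import MeshIOError, MeshValidationError

__all__ = [
    "SurfaceMesh",
    "NodalField",
    "MeshQCReport",
    "load_mesh",
    "save_mesh",
    "load_nodal_field",
    "save_nodal_field",
    "center_at_origin",
    "laplacian_smooth",
    "mesh_qc",
]

_FORMATS = ("stl", "ply", "obj", "vtk")


@dataclass
class SurfaceMesh:
    """Triangulated vessel-wall surface in mm, nodes ordered as loaded.

    Invariants enforced on construction: every triangle index refers to an
    existing node, no triangle repeats a node index, and the mesh has at
    least 4 nodes and 4 triangles (the smallest closed surface).
    """

    nodes: np.ndarray
    triangles: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.nodes = np.ascontiguousarray(np.asarray(self.nodes, dtype=np.float64))
        self.triangles = np.ascontiguousarray(np.asarray(self.triangles, dtype=np.int64))
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshValidationError("nodes must be an (n, 3) array of mm coordinates")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshValidationError("triangles must be an (m, 3) array of node indices")
        if len(self.nodes) < 4:
            raise MeshValidationError(f"node count >= 4 required (got {len(self.nodes)})")
        if len(self.triangles) < 4:
            raise MeshValidationError(f"triangle count >= 4 required (got {len(self.triangles)})")
        if not np.all(np.isfinite(self.nodes)):
            raise MeshValidationError("node coordinates must be finite")
        if self.triangles.min() < 0 or self.triangles.max() >= len(self.nodes):
            raise MeshValidationError("triangle index refers to a non-existent node")
        t = self.triangles
        if np.any((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])):
            raise MeshValidationError("triangle repeats a node index (degenerate index triple)")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def centroid(self) -> np.ndarray:
        """Unweighted mean of node coordinates (mm)."""
        return self.nodes.mean(axis=0)

    def edges(self, unique: bool = False) -> np.ndarray:
        """All triangle edges as sorted index pairs; one row per incidence."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        e = np.sort(e, axis=1)
        if unique:
            e = np.unique(e, axis=0)
        return e

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric node adjacency (1-ring) as a sparse boolean matrix."""
        e = self.edges(unique=True)
        n = self.n_nodes
        data = np.ones(len(e), dtype=np.float64)
        a = sp.coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
        a = a + a.T
        a.data[:] = 1.0
        return a.tocsr()

    def open_edge_nodes(self) -> np.ndarray:
        """Indices of nodes lying on edges used by exactly one triangle."""
        e = self.edges()
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        border = uniq[counts == 1]
        return np.unique(border)

    def translated(self, offset) -> "SurfaceMesh":
        return dataclasses.replace(self, nodes=self.nodes + np.asarray(offset, dtype=float))


@dataclass
class NodalField:
    """One scalar per mesh node, linked to the mesh by node order.

    Stress fields (the default use) must be non-negative; pass
    ``allow_negative=True`` for generic signed fields.
    """

    values: np.ndarray
    name: str = "von_mises_stress"
    allow_negative: bool = False

    def __post_init__(self):
        self.values = np.ascontiguousarray(np.asarray(self.values, dtype=np.float64))
        if self.values.ndim != 1:
            raise MeshValidationError("nodal field must be one scalar per node")
        if not np.all(np.isfinite(self.values)):
            raise MeshValidationError(f"field '{self.name}' contains non-finite values")
        if not self.allow_negative and np.any(self.values < 0):
            raise MeshValidationError(f"stress field '{self.name}' must be non-negative")

    def check_against(self, mesh: SurfaceMesh) -> "NodalField":
        if len(self.values) != mesh.n_nodes:
            raise MeshValidationError(
                f"field '{self.name}' has {len(self.values)} values for a mesh "
                f"with {mesh.n_nodes} nodes"
            )
        return self


@dataclass
class MeshQCReport:
    """Result of the structural quality checks run before isolation."""

    non_manifold_edge_count: int
    degenerate_triangle_count: int
    max_aspect_ratio: float
    aspect_ratio_max: float
    area_tol: float
    passed: bool = field(init=False)

    def __post_init__(self):
        self.passed = (
            self.non_manifold_edge_count == 0
            and self.degenerate_triangle_count == 0
            and self.max_aspect_ratio <= self.aspect_ratio_max
        )

    def to_dict(self) -> dict:
        return {
            "non_manifold_edge_count": int(self.non_manifold_edge_count),
            "degenerate_triangle_count": int(self.degenerate_triangle_count),
            "max_aspect_ratio": float(self.max_aspect_ratio),
            "aspect_ratio_max": float(self.aspect_ratio_max),
            "area_tol": float(self.area_tol),
            "passed": bool(self.passed),
        }


def _infer_format(path, fmt: str) -> str:
    if fmt != "auto":
        if fmt not in _FORMATS:
            raise MeshIOError(f"unsupported mesh format '{fmt}'")
        return fmt
    ext = os.path.splitext(str(path))[1].lower().lstrip(".")
    if ext not in _FORMATS:
        raise MeshIOError(f"cannot infer mesh format from extension '.{ext}'")
    return ext


def _dedup_vertices(verts: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # First-occurrence-order vertex deduplication (STL stores a triangle soup).
    _, first_idx, inverse = np.unique(verts, axis=0, return_index=True, return_inverse=True)
    order = np.argsort(first_idx)
    rank = np.empty(len(order), dtype=np.int64)
    rank[order] = np.arange(len(order))
    return verts[np.sort(first_idx)], rank[inverse][faces]


def load_mesh(path, fmt: str = "auto") -> SurfaceMesh:
    """Load a triangulated surface from STL/PLY/OBJ/legacy-VTK.

    Node order is preserved as stored in the file; for STL the triangle soup
    is deduplicated to shared vertices in first-occurrence order.
    """
    fmt = _infer_format(path, fmt)
    if not os.path.exists(path):
        raise MeshIOError(f"mesh file not found: {path}")
    if fmt == "vtk":
        points, tris, _ = vtk_io.read_polydata(path)
        return SurfaceMesh(points, tris, provenance=f"vtk:{path}")
    try:
        tm = trimesh.load(str(path), file_type=fmt, force="mesh", process=False)
    except MeshValidationError:
        raise
    except Exception as exc:  # trimesh raises assorted parse errors
        raise MeshIOError(f"cannot parse {path} as {fmt}: {exc}") from exc
    verts = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    if len(verts) == 0 or len(faces) == 0:
        raise MeshIOError(f"{path}: no geometry parsed ({fmt})")
    if fmt == "stl":
        verts, faces = _dedup_vertices(verts, faces)
    return SurfaceMesh(verts, faces, provenance=f"{fmt}:{path}")


def save_mesh(mesh: SurfaceMesh, path, fmt: str = "auto") -> None:
    fmt = _infer_format(path, fmt)
    if fmt == "vtk":
        vtk_io.write_polydata(path, mesh.nodes, mesh.triangles)
        return
    tm = trimesh.Trimesh(vertices=mesh.nodes, faces=mesh.triangles, process=False)
    try:
        tm.export(str(path), file_type=fmt)
    except Exception as exc:
        raise MeshIOError(f"cannot write {path} as {fmt}: {exc}") from exc


def load_nodal_field(path, mesh: SurfaceMesh | None = None, name: str | None = None,
                     allow_negative: bool = False) -> NodalField:
    """Load a nodal scalar from a `node_id,value` CSV or a VTK point-data scalar."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".vtk":
        _, _, point_data = vtk_io.read_polydata(path)
        if not point_data:
            raise MeshIOError(f"{path}: no point-data scalars present")
        key = name if name is not None else next(iter(point_data))
        if key not in point_data:
            raise MeshIOError(f"{path}: scalar '{key}' not found (has {list(point_data)})")
        f = NodalField(point_data[key], name=key, allow_negative=allow_negative)
    else:
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            raise MeshIOError(f"cannot read nodal field {path}: {exc}") from exc
        if not {"node_id", "value"}.issubset(df.columns):
            raise MeshIOError(f"{path}: expected header 'node_id,value'")
        df = df.sort_values("node_id")
        ids = df["node_id"].to_numpy()
        if not np.array_equal(ids, np.arange(len(ids))):
            raise MeshValidationError(f"{path}: node_id must be contiguous 0-based indices")
        f = NodalField(df["value"].to_numpy(), name=name or "von_mises_stress",
                       allow_negative=allow_negative)
    if mesh is not None:
        f.check_against(mesh)
    return f


def save_nodal_field(f: NodalField, path) -> None:
    pd.DataFrame({"node_id": np.arange(len(f.values)), "value": f.values}).to_csv(
        path, index=False
    )


def center_at_origin(mesh: SurfaceMesh) -> tuple[SurfaceMesh, np.ndarray]:
    """Translate so the (unweighted) node centroid sits at the origin.

    Returns the centered mesh and the translation that was applied,
    i.e. ``centered.nodes == mesh.nodes + offset``.
    """
    offset = -mesh.centroid
    return mesh.translated(offset), offset


def laplacian_smooth(mesh: SurfaceMesh, iterations: int, relaxation: float = 0.5) -> SurfaceMesh:
    """Surface-preserving (Taubin lambda/mu) Laplacian smoothing.

    Each iteration moves every node toward the mean of its 1-ring neighbours
    by ``relaxation``, then applies the Taubin back-step (mu computed from the
    standard pass-band relation with k_pb = 0.1) to counteract shrinkage; any
    residual centroid drift is removed exactly. Connectivity is unchanged.
    """
    if iterations < 0:
        raise MeshValidationError("iterations must be non-negative")
    if not (0.0 < relaxation <= 1.0):
        raise MeshValidationError("relaxation must lie in (0, 1]")
    if iterations == 0:
        return dataclasses.replace(mesh, nodes=mesh.nodes.copy())

    adj = mesh.adjacency()
    degree = np.asarray(adj.sum(axis=1)).ravel()
    if np.any(degree == 0):
        bad = int(np.flatnonzero(degree == 0)[0])
        raise MeshValidationError(f"node {bad} is isolated (no 1-ring neighbours)")
    inv_deg = sp.diags(1.0 / degree)
    averaging = inv_deg @ adj  # row-stochastic neighbour mean

    lam = relaxation
    mu = -lam / (1.0 - 0.1 * lam)  # Taubin pass-band relation, k_pb = 0.1
    pts = mesh.nodes.copy()
    c0 = pts.mean(axis=0)
    for _ in range(iterations):
        pts = pts + lam * (averaging @ pts - pts)
        pts = pts + mu * (averaging @ pts - pts)
        pts += c0 - pts.mean(axis=0)  # exact centroid preservation
    return dataclasses.replace(mesh, nodes=pts)


def mesh_qc(mesh: SurfaceMesh, aspect_ratio_max: float = 20.0,
            area_tol: float = 1e-8) -> MeshQCReport:
    """Count non-manifold edges, degenerate triangles, and the worst aspect ratio.

    Aspect ratio = longest edge / shortest altitude = e_max^2 / (2 A); computed
    over triangles with area >= ``area_tol`` (degenerate ones are counted
    separately and fail the report on their own).
    """
    if aspect_ratio_max <= 0 or area_tol <= 0:
        raise MeshValidationError("aspect_ratio_max and area_tol must be positive")
    e = mesh.edges()
    _, counts = np.unique(e, axis=0, return_counts=True)
    non_manifold = int(np.sum(counts > 2))

    p = mesh.nodes[mesh.triangles]  # (m, 3, 3)
    v0 = p[:, 1] - p[:, 0]
    v1 = p[:, 2] - p[:, 0]
    v2 = p[:, 2] - p[:, 1]
    areas = 0.5 * np.linalg.norm(np.cross(v0, v1), axis=1)
    degenerate = int(np.sum(areas < area_tol))

    lengths = np.stack(
        [np.linalg.norm(v0, axis=1), np.linalg.norm(v1, axis=1), np.linalg.norm(v2, axis=1)],
        axis=1,
    )
    e_max = lengths.max(axis=1)
    valid = areas >= area_tol
    if np.any(valid):
        max_aspect = float(np.max(e_max[valid] ** 2 / (2.0 * areas[valid])))
    else:
        max_aspect = float("inf")
    return MeshQCReport(
        non_manifold_edge_count=non_manifold,
        degenerate_triangle_count=degenerate,
        max_aspect_ratio=max_aspect,
        aspect_ratio_max=float(aspect_ratio_max),
        area_tol=float(area_tol),
    )
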