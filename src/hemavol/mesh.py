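"""Triangle-mesh container, file I/O, topology diagnostics and volume oracles.

A hematoma segmented from CT arrives as a triangle surface mesh.  Whether that
mesh is *closed* (every edge shared by exactly two faces) and *consistently
oriented* (counter-clockwise winding pointing outward everywhere) decides which
volume estimators can be trusted, so this module provides the mesh container,
the diagnostics, an orientation repair, and two independent volume oracles
(exact signed tetrahedron summation, and Monte-Carlo rejection sampling) that
every estimator in the package is validated against.
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

__all__ = [
    "MeshError",
    "EmptyMeshError",
    "MeshFormatError",
    "OpenMeshError",
    "NonManifoldError",
    "TriangleMesh",
    "FaceGeometry",
    "TopologyReport",
    "VolumeEstimate",
    "read_mesh",
    "write_mesh",
    "face_geometry",
    "topology_report",
    "reorient",
    "signed_tet_volume",
    "signed_tet_volume_oracle",
    "monte_carlo_volume_oracle",
]

# Relative tolerance (times squared bbox diagonal) below which a face area is
# treated as degenerate: real segmentation meshes contain slivers, which are
# skipped by estimators and merely counted in the topology report.
DEGENERATE_AREA_REL = 1e-12


class MeshError(ValueError):
    """Base class for mesh-related errors."""


class EmptyMeshError(MeshError):
    """The mesh (or file) contains no faces."""


class MeshFormatError(MeshError):
    """The file could not be parsed as a supported mesh format."""


class OpenMeshError(MeshError):
    """An operation requiring a closed mesh was given one with boundary."""


class NonManifoldError(MeshError):
    """An operation requiring edge-manifoldness hit a >2-face edge."""


@dataclass(frozen=True)
class TriangleMesh:
    """Indexed triangle surface: ``vertices`` (n, 3) and ``faces`` (m, 3).

    Counter-clockwise winding (seen from outside) encodes the outward normal;
    coordinates are dimensionless model units, read as mm when units are
    declared downstream.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshError(f"vertices must be (n, 3), got {v.shape}")
        if f.size == 0:
            f = f.reshape(0, 3)
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshError(f"faces must be (m, 3), got {f.shape}")
        if len(f) and len(v) < 3:
            raise MeshError("a mesh with faces needs at least 3 vertices")
        if len(f):
            if f.min() < 0 or f.max() >= len(v):
                raise MeshError("face index out of range")
            if (
                (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
            ).any():
                raise MeshError("a face repeats a vertex")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def triangles(self) -> np.ndarray:
        """Per-face vertex coordinates, shape (m, 3, 3)."""
        return self.vertices[self.faces]

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array of [min corner, max corner]."""
        return np.array([self.vertices.min(0), self.vertices.max(0)])

    @property
    def extent(self) -> np.ndarray:
        b = self.bounds
        return b[1] - b[0]

    @property
    def bbox_diagonal(self) -> float:
        return float(np.linalg.norm(self.extent))

    def translated(self, offset) -> "TriangleMesh":
        return TriangleMesh(self.vertices + np.asarray(offset, float), self.faces)

    def with_faces(self, faces) -> "TriangleMesh":
        return TriangleMesh(self.vertices, faces)


@dataclass(frozen=True)
class FaceGeometry:
    """Edge lengths, Heron area, unit normal and centroid of one face."""

    a: float
    b: float
    c: float
    s: float
    area: float
    u: np.ndarray | None  # unit normal; None for degenerate faces
    avg: np.ndarray  # centroid
    degenerate: bool


@dataclass(frozen=True)
class TopologyReport:
    """Edge-multiset diagnostics deciding which estimators are reliable."""

    is_closed: bool
    is_consistently_oriented: bool
    boundary_edge_count: int
    degenerate_face_count: int
    non_manifold_edge_count: int


@dataclass
class VolumeEstimate:
    """A volume measurement: method tag, scalar result, parameters, warnings.

    ``volume`` is in model units cubed; divide by 1000 to convert mm^3 to ml.
    """

    method: str
    volume: float
    params: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def ml(self) -> float:
        return self.volume / 1000.0


# ---------------------------------------------------------------------------
# face geometry


def face_arrays(mesh: TriangleMesh):
    """Vectorised per-face (heron_area, unit_normal, centroid, degenerate_mask).

    Areas follow Heron's formula from the edge lengths; normals come from the
    winding (cross product of the first two edges), never from stored file
    normals. Degenerate (near-collinear) faces get a zero normal and are
    flagged rather than raising.
    """
    tri = mesh.triangles
    p0, p1, p2 = tri[:, 0], tri[:, 1], tri[:, 2]
    a = np.linalg.norm(p1 - p2, axis=1)
    b = np.linalg.norm(p0 - p2, axis=1)
    c = np.linalg.norm(p0 - p1, axis=1)
    s = (a + b + c) / 2.0
    area = np.sqrt(np.clip(s * (s - a) * (s - b) * (s - c), 0.0, None))
    cross = np.cross(p1 - p0, p2 - p0)
    norm = np.linalg.norm(cross, axis=1)
    diag = mesh.bbox_diagonal
    tol = DEGENERATE_AREA_REL * max(diag * diag, 1.0)
    degenerate = area <= tol
    safe = np.where(norm > 0, norm, 1.0)
    normals = cross / safe[:, None]
    normals[degenerate] = 0.0
    centroids = (p0 + p1 + p2) / 3.0
    return area, normals, centroids, degenerate


def face_geometry(mesh: TriangleMesh, index: int) -> FaceGeometry:
    """Geometry of face ``index``: Heron area, unit normal u, centroid avg."""
    if not 0 <= index < mesh.n_faces:
        raise IndexError(f"face index {index} out of range [0, {mesh.n_faces})")
    p0, p1, p2 = mesh.vertices[mesh.faces[index]]
    a = float(np.linalg.norm(p1 - p2))
    b = float(np.linalg.norm(p0 - p2))
    c = float(np.linalg.norm(p0 - p1))
    s = (a + b + c) / 2.0
    area = float(np.sqrt(max(s * (s - a) * (s - b) * (s - c), 0.0)))
    cross = np.cross(p1 - p0, p2 - p0)
    norm = float(np.linalg.norm(cross))
    diag = mesh.bbox_diagonal
    degenerate = area <= DEGENERATE_AREA_REL * max(diag * diag, 1.0)
    u = None if degenerate else cross / norm
    avg = (p0 + p1 + p2) / 3.0
    return FaceGeometry(a, b, c, s, area, u, avg, degenerate)


# ---------------------------------------------------------------------------
# topology


def _directed_edges(faces: np.ndarray) -> np.ndarray:
    return np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])


def topology_report(mesh: TriangleMesh) -> TopologyReport:
    """Classify the mesh via its edge multiset.

    Closed: every undirected edge appears exactly twice.  Consistently
    oriented: no directed edge repeats (two faces sharing an edge traverse it
    in opposite directions).
    """
    if mesh.n_faces == 0:
        return TopologyReport(False, False, 0, 0, 0)
    de = _directed_edges(mesh.faces)
    und = np.sort(de, axis=1)
    _, counts = np.unique(und, axis=0, return_counts=True)
    boundary = int((counts == 1).sum())
    non_manifold = int((counts > 2).sum())
    closed = bool(boundary == 0 and non_manifold == 0)
    _, dcounts = np.unique(de, axis=0, return_counts=True)
    consistent = bool((dcounts == 1).all())
    _, _, _, degen = face_arrays(mesh)
    return TopologyReport(closed, consistent, boundary, int(degen.sum()), non_manifold)


def reorient(mesh: TriangleMesh) -> TriangleMesh:
    """Repair face windings so the mesh is consistently, outward oriented.

    Breadth-first propagation over face adjacency fixes relative orientation;
    the global sign of each connected component is then chosen so its signed
    tetrahedron-sum volume is positive.  Requires a closed, edge-manifold mesh.
    """
    rep = topology_report(mesh)
    if rep.non_manifold_edge_count:
        de = _directed_edges(mesh.faces)
        und = np.sort(de, axis=1)
        edges, counts = np.unique(und, axis=0, return_counts=True)
        bad = edges[counts > 2][0]
        raise NonManifoldError(f"non-manifold edge {tuple(bad)}")
    if not rep.is_closed:
        raise OpenMeshError(
            f"cannot reorient an open mesh ({rep.boundary_edge_count} boundary edges)"
        )
    faces = mesh.faces.copy()
    m = len(faces)
    edge_faces: dict[tuple, list] = defaultdict(list)
    for fi in range(m):
        f = faces[fi]
        for k in range(3):
            i, j = int(f[k]), int(f[(k + 1) % 3])
            edge_faces[(min(i, j), max(i, j))].append(fi)
    flip = np.zeros(m, bool)
    visited = np.zeros(m, bool)
    component = np.full(m, -1)
    for seed in range(m):
        if visited[seed]:
            continue
        visited[seed] = True
        component[seed] = seed
        queue = deque([seed])
        while queue:
            fi = queue.popleft()
            f = faces[fi][::-1] if flip[fi] else faces[fi]
            for k in range(3):
                i, j = int(f[k]), int(f[(k + 1) % 3])
                for gi in edge_faces[(min(i, j), max(i, j))]:
                    if gi == fi:
                        continue
                    g = faces[gi]
                    # neighbour is consistent if it traverses the shared
                    # edge as (j, i) after its own flip is applied
                    fwd = any(
                        (int(g[k2]), int(g[(k2 + 1) % 3])) == (i, j) for k2 in range(3)
                    )
                    need = flip[gi]
                    want = fwd  # traverses (i, j) same way -> must flip
                    if not visited[gi]:
                        visited[gi] = True
                        flip[gi] = want
                        component[gi] = component[fi]
                        queue.append(gi)
    faces[flip] = faces[flip][:, ::-1]
    fixed = TriangleMesh(mesh.vertices, faces)
    # per-component outward sign
    tri = fixed.triangles
    signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0
    out = faces.copy()
    for comp in np.unique(component):
        sel = component == comp
        if signed[sel].sum() < 0:
            out[sel] = out[sel][:, ::-1]
    return TriangleMesh(mesh.vertices, out)


# ---------------------------------------------------------------------------
# volume oracles


def signed_tet_volume(mesh: TriangleMesh) -> float:
    """Signed sum of origin tetrahedra det(P0, P1, P2)/6 over all faces."""
    tri = mesh.triangles
    return float(
        np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
    )


def signed_tet_volume_oracle(mesh: TriangleMesh) -> VolumeEstimate:
    """Exact enclosed volume of a closed mesh by signed tetrahedron summation.

    Independent of translation for closed meshes.  Returns the signed value;
    a negative result (inward orientation) is reported with a warning.
    """
    rep = topology_report(mesh)
    if not rep.is_closed:
        raise OpenMeshError("signed tetrahedron sum is undefined for open meshes")
    v = signed_tet_volume(mesh)
    warnings = []
    if v < 0:
        warnings.append("negative signed volume: mesh is oriented inward")
    return VolumeEstimate("tet_oracle", v, {}, warnings)


def _ray_crossings(tri: np.ndarray, points: np.ndarray, direction: np.ndarray, scale: float):
    """Count ray/triangle crossings per point (Moller-Trumbore, vectorised).

    Returns (counts, suspect) where ``suspect`` flags points whose ray passed
    within tolerance of a triangle edge/vertex or of the surface itself, and
    which therefore need a re-cast in a jittered direction.
    """
    n_pts = len(points)
    counts = np.zeros(n_pts, dtype=np.int64)
    suspect = np.zeros(n_pts, bool)
    if len(tri) == 0:
        return counts, suspect
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    h = np.cross(direction[None, :], e2)
    det = np.einsum("ij,ij->i", e1, h)
    eps_det = 1e-14 * scale * scale
    parallel = np.abs(det) <= eps_det
    inv = np.where(parallel, 1.0, 1.0 / np.where(det == 0, 1.0, det))
    eps_b = 1e-10
    eps_t = 1e-12 * scale
    chunk = max(1, int(4_000_000 / max(len(tri), 1)))
    for lo in range(0, n_pts, chunk):
        pts = points[lo : lo + chunk]
        s = pts[:, None, :] - tri[None, :, 0, :]  # (p, m, 3)
        u = np.einsum("pmj,mj->pm", s, h) * inv[None, :]
        q = np.cross(s, e1[None, :, :])
        v = np.einsum("pmj,j->pm", q, direction) * inv[None, :]
        t = np.einsum("pmj,mj->pm", q, e2) * inv[None, :]
        w = 1.0 - u - v
        hit = (
            (~parallel[None, :])
            & (u >= eps_b)
            & (v >= eps_b)
            & (w >= eps_b)
            & (t > eps_t)
        )
        near = (
            (u >= -eps_b)
            & (v >= -eps_b)
            & (w >= -eps_b)
            & (t > -eps_t)
            & (
                (u < eps_b)
                | (v < eps_b)
                | (w < eps_b)
                | (np.abs(t) <= eps_t)
                | parallel[None, :]
            )
        )
        counts[lo : lo + chunk] = hit.sum(axis=1)
        suspect[lo : lo + chunk] = near.any(axis=1)
    return counts, suspect


def points_inside(mesh: TriangleMesh, points: np.ndarray, seed: int = 0) -> np.ndarray:
    """Ray-parity point-in-mesh test with seeded jittered re-casts on ties."""
    points = np.atleast_2d(np.asarray(points, float))
    tri = mesh.triangles
    scale = max(mesh.bbox_diagonal, 1.0)
    rng = np.random.default_rng(seed)
    inside = np.zeros(len(points), bool)
    pending = np.arange(len(points))
    direction = np.array([1.0, 0.0, 0.0])
    for _ in range(32):
        counts, suspect = _ray_crossings(tri, points[pending], direction, scale)
        ok = ~suspect
        inside[pending[ok]] = counts[ok] % 2 == 1
        pending = pending[suspect]
        if len(pending) == 0:
            break
        d = rng.normal(size=3)
        direction = d / np.linalg.norm(d)
    else:  # pragma: no cover - pathological input
        counts, _ = _ray_crossings(tri, points[pending], direction, scale)
        inside[pending] = counts % 2 == 1
    return inside


def monte_carlo_volume_oracle(
    mesh: TriangleMesh, n_samples: int = 100_000, seed: int = 0
) -> VolumeEstimate:
    """Rejection-sampling volume estimate with its binomial standard error.

    Samples uniformly in the bounding box and classifies each point by ray
    parity; standard error = bbox_volume * sqrt(p(1-p)/n).  Reproducible for a
    fixed seed.
    """
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000")
    rep = topology_report(mesh)
    if not rep.is_closed:
        raise OpenMeshError("Monte-Carlo oracle requires a closed mesh")
    rng = np.random.default_rng(seed)
    lo, hi = mesh.bounds
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    inside = points_inside(mesh, pts, seed=seed + 1)
    p = inside.mean()
    bbox_vol = float(np.prod(hi - lo))
    se = bbox_vol * float(np.sqrt(p * (1 - p) / n_samples))
    return VolumeEstimate(
        "mc_oracle",
        bbox_vol * float(p),
        {"n_samples": n_samples, "seed": seed, "standard_error": se},
    )


# ---------------------------------------------------------------------------
# file I/O


_FORMAT_ALIASES = {
    "stl": "stl",
    "stl_ascii": "stl_ascii",
    "obj": "obj",
    "off": "off",
}


def _merge_vertices(vertices: np.ndarray, faces: np.ndarray):
    """Unify duplicate vertices within 1e-8 x bbox diagonal.

    STL stores three loose vertices per facet; merging is required before any
    topology analysis.  Faces collapsed to a line or point by the merge are
    dropped.
    """
    if len(vertices) == 0:
        return vertices, faces
    diag = float(np.linalg.norm(vertices.max(0) - vertices.min(0)))
    tol = 1e-8 * max(diag, 1.0)
    keys = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(keys, axis=0, return_index=True, return_inverse=True)
    merged = vertices[first]
    new_faces = inverse[faces]
    keep = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 0] != new_faces[:, 2])
    )
    return merged, new_faces[keep]


def read_mesh(path, file_format: str | None = None) -> TriangleMesh:
    """Load an STL (ASCII or binary, auto-detected), OBJ or OFF mesh.

    Duplicate vertices are merged (tolerance 1e-8 x bbox diagonal); any
    file-stored normals are discarded — winding is the authoritative source
    of orientation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ftype = None
    if file_format is not None:
        if file_format not in _FORMAT_ALIASES:
            raise MeshFormatError(f"unsupported format {file_format!r}")
        ftype = "stl" if file_format == "stl_ascii" else file_format
    try:
        tm = _trimesh.load(str(path), file_type=ftype, force="mesh", process=False)
    except Exception as exc:
        raise MeshFormatError(f"cannot parse {path}: {exc}") from exc
    verts = np.asarray(getattr(tm, "vertices", np.zeros((0, 3))), float)
    faces = np.asarray(getattr(tm, "faces", np.zeros((0, 3), int)), np.int64)
    if len(faces) == 0:
        raise EmptyMeshError(f"{path} contains no faces")
    verts, faces = _merge_vertices(verts, faces)
    if len(faces) == 0:
        raise EmptyMeshError(f"{path} contains only degenerate faces")
    return TriangleMesh(verts, faces)


def write_mesh(mesh: TriangleMesh, path, file_format: str | None = None) -> None:
    """Write a mesh as STL (binary), STL ASCII, OBJ or OFF.

    The format is taken from ``file_format`` ('stl', 'stl_ascii', 'obj',
    'off') or inferred from the path suffix (``.stl`` means binary).
    """
    if mesh.n_faces == 0:
        raise EmptyMeshError("refusing to write an empty mesh")
    path = Path(path)
    if file_format is None:
        file_format = path.suffix.lstrip(".").lower()
    if file_format not in _FORMAT_ALIASES:
        raise MeshFormatError(f"unsupported format {file_format!r}")
    tm = _trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    data = tm.export(file_type=file_format)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)
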