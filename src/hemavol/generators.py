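"""Benchmark solids and synthetic hematoma phantoms, plus controlled damage.

The pyramid and cube are the standard models with known volume (l*w*h/3 and
a^3); blobs are star-shaped phantoms emulating the three clinical hematoma
shape classes (regular, irregular, multilobular).  ``open_variant`` and
``corrupt_normals`` produce exactly the defects whose effect on each estimator
the package measures: a hole in the surface, and flipped face windings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import MeshError, TriangleMesh

__all__ = [
    "BlobSpec",
    "make_pyramid",
    "make_cube",
    "make_blob",
    "icosphere",
    "subdivide_midpoint",
    "open_variant",
    "corrupt_normals",
]


def subdivide_midpoint(mesh: TriangleMesh, times: int = 1) -> TriangleMesh:
    """Split every face into four via edge midpoints, ``times`` rounds.

    Midpoints are cached per undirected edge, so shared edges stay shared and
    closed meshes stay closed; winding (orientation) is preserved.  Geometry
    is unchanged for planar faces, which is what makes benchmark volumes
    provably independent of triangulation density.
    """
    verts = [v for v in mesh.vertices]
    faces = mesh.faces
    for _ in range(times):
        midpoint: dict[tuple, int] = {}

        def mid(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in midpoint:
                midpoint[key] = len(verts)
                verts.append((verts[i] + verts[j]) / 2.0)
            return midpoint[key]

        new_faces = []
        for f in faces:
            i0, i1, i2 = int(f[0]), int(f[1]), int(f[2])
            m01, m12, m02 = mid(i0, i1), mid(i1, i2), mid(i0, i2)
            new_faces.extend(
                [(i0, m01, m02), (m01, i1, m12), (m02, m12, i2), (m01, m12, m02)]
            )
        faces = np.array(new_faces, np.int64)
    return TriangleMesh(np.array(verts), faces)


def make_pyramid(
    l: float, w: float, h: float, subdivision: int = 0
) -> TriangleMesh:
    """Closed quadrangular pyramid: base l x w at height 0, apex at height h.

    ``subdivision`` midpoint-subdivision rounds refine the 6 base triangles
    into 6*4^subdivision faces without moving the surface.
    """
    if l <= 0 or w <= 0 or h <= 0:
        raise ValueError("pyramid dimensions must be positive")
    verts = np.array(
        [
            [0.0, 0.0, 0.0],
            [l, 0.0, 0.0],
            [l, w, 0.0],
            [0.0, w, 0.0],
            [l / 2.0, w / 2.0, h],
        ]
    )
    faces = np.array(
        [
            [0, 2, 1],  # base, outward normal -z
            [0, 3, 2],
            [0, 1, 4],  # sides
            [1, 2, 4],
            [2, 3, 4],
            [3, 0, 4],
        ],
        np.int64,
    )
    return subdivide_midpoint(TriangleMesh(verts, faces), subdivision)


def make_cube(a: float, subdivision: int = 1) -> TriangleMesh:
    """Closed axis-aligned cube [0, a]^3, each face an m x m triangle grid.

    ``subdivision`` is the grid count m per face edge, giving 12*m^2 faces.
    """
    if a <= 0:
        raise ValueError("cube edge must be positive")
    m = int(subdivision)
    if m < 1:
        raise ValueError("subdivision must be >= 1")
    index: dict[tuple, int] = {}
    verts: list = []

    def vid(key):
        if key not in index:
            index[key] = len(verts)
            verts.append(np.array(key, float) * (a / m))
        return index[key]

    faces = []
    for axis in range(3):
        u, v = (axis + 1) % 3, (axis + 2) % 3
        for side_hi in (False, True):
            k = m if side_hi else 0
            for i in range(m):
                for j in range(m):
                    corners = []
                    for di, dj in ((0, 0), (1, 0), (1, 1), (0, 1)):
                        key = [0, 0, 0]
                        key[axis] = k
                        key[u] = i + di
                        key[v] = j + dj
                        corners.append(vid(tuple(key)))
                    c0, c1, c2, c3 = corners
                    if side_hi:  # u x v = +axis: CCW in (u, v) points outward
                        faces.extend([(c0, c1, c2), (c0, c2, c3)])
                    else:
                        faces.extend([(c0, c2, c1), (c0, c3, c2)])
    return TriangleMesh(np.array(verts), np.array(faces, np.int64))


# ---------------------------------------------------------------------------
# blob phantoms


@dataclass(frozen=True)
class BlobSpec:
    """Parameters of a star-shaped hematoma phantom.

    ``base_radii`` are the ellipsoid semi-axes (mm when units are declared);
    bumps are spherical Gaussians in seeded random directions whose amplitude
    is relative to the local ellipsoid radius and whose width is an angular
    standard deviation in radians.  Shape classes follow the clinical grading:
    regular (smooth, no bumps), irregular (many small surface perturbations,
    frayed margins), lobular (2-4 large lobes).

    ``center`` places the phantom in scanner-like coordinates: CT
    reconstructions are never centred on the lesion, and the projection
    method's open-mesh error depends on where the mesh sits relative to the
    coordinate origin, so an origin-centred phantom would be an
    unrealistically favourable special case for that failure mode.
    """

    shape_class: str = "regular"
    base_radii: tuple = (12.0, 10.0, 9.0)
    bump_count: int = 0
    bump_amplitude: float = 0.0
    bump_width: float = 0.5
    subdivision_level: int = 3
    seed: int = 0
    center: tuple = (60.0, 60.0, 40.0)

    def __post_init__(self):
        if self.shape_class not in ("regular", "irregular", "lobular"):
            raise ValueError(f"unknown shape class {self.shape_class!r}")
        if any(r <= 0 for r in self.base_radii):
            raise ValueError("base radii must be positive")
        if self.shape_class == "regular" and self.bump_amplitude != 0.0:
            raise ValueError("regular blobs must have zero bump amplitude")
        if self.shape_class == "lobular" and not (
            2 <= self.bump_count <= 4 and self.bump_amplitude >= 0.3
        ):
            raise ValueError("lobular blobs need 2-4 bumps with amplitude >= 0.3")

    @classmethod
    def for_class(
        cls,
        shape_class: str,
        seed: int = 0,
        base_radii: tuple = (12.0, 10.0, 9.0),
        subdivision_level: int = 3,
    ) -> "BlobSpec":
        """Canonical parameters per shape class (amplitudes relative)."""
        presets = {
            "regular": dict(bump_count=0, bump_amplitude=0.0, bump_width=0.5),
            "irregular": dict(bump_count=24, bump_amplitude=0.06, bump_width=0.25),
            "lobular": dict(bump_count=3, bump_amplitude=0.4, bump_width=0.6),
        }
        if shape_class not in presets:
            raise ValueError(f"unknown shape class {shape_class!r}")
        return cls(
            shape_class=shape_class,
            base_radii=tuple(base_radii),
            subdivision_level=subdivision_level,
            seed=seed,
            **presets[shape_class],
        )


_PHI = (1.0 + np.sqrt(5.0)) / 2.0
_ICO_VERTS = np.array(
    [
        [-1, _PHI, 0], [1, _PHI, 0], [-1, -_PHI, 0], [1, -_PHI, 0],
        [0, -1, _PHI], [0, 1, _PHI], [0, -1, -_PHI], [0, 1, -_PHI],
        [_PHI, 0, -1], [_PHI, 0, 1], [-_PHI, 0, -1], [-_PHI, 0, 1],
    ],
    float,
)
_ICO_FACES = np.array(
    [
        [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
        [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
        [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
        [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
    ],
    np.int64,
)


def icosphere(subdivision_level: int = 3) -> TriangleMesh:
    """Unit-sphere triangulation: subdivided icosahedron, 20*4^level faces."""
    mesh = TriangleMesh(_ICO_VERTS / np.linalg.norm(_ICO_VERTS[0]), _ICO_FACES)
    for _ in range(subdivision_level):
        mesh = subdivide_midpoint(mesh, 1)
        v = mesh.vertices / np.linalg.norm(mesh.vertices, axis=1)[:, None]
        mesh = TriangleMesh(v, mesh.faces)
    return mesh


def make_blob(spec: BlobSpec) -> TriangleMesh:
    """Star-shaped phantom: icosphere vertices moved to r(direction).

    r = ellipsoid radius along the vertex direction times (1 + sum of
    Gaussian bumps at seeded random directions).  Star-shapedness guarantees
    a closed, self-intersection-free, consistently oriented mesh; the same
    seed always yields the identical mesh.
    """
    sphere = icosphere(spec.subdivision_level)
    dirs = sphere.vertices  # unit vectors
    a, b, c = spec.base_radii
    # radius of the ellipsoid along each unit direction
    r_ell = 1.0 / np.sqrt(
        (dirs[:, 0] / a) ** 2 + (dirs[:, 1] / b) ** 2 + (dirs[:, 2] / c) ** 2
    )
    factor = np.ones(len(dirs))
    if spec.bump_count > 0 and spec.bump_amplitude != 0:
        rng = np.random.default_rng(spec.seed)
        centers = rng.normal(size=(spec.bump_count, 3))
        centers /= np.linalg.norm(centers, axis=1)[:, None]
        ang = np.arccos(np.clip(dirs @ centers.T, -1.0, 1.0))
        factor = factor + (
            spec.bump_amplitude * np.exp(-((ang / spec.bump_width) ** 2))
        ).sum(axis=1)
    if factor.min() <= 1e-6:
        raise ValueError("bump amplitude drives the radius non-positive")
    verts = dirs * (r_ell * factor)[:, None] + np.asarray(spec.center, float)
    return TriangleMesh(verts, sphere.faces)


# ---------------------------------------------------------------------------
# corruptions


def open_variant(mesh: TriangleMesh, patch="base_cap", axis: int = 2) -> TriangleMesh:
    """Remove a patch of faces, producing a mesh with boundary.

    ``patch`` is ``"base_cap"`` (all faces lying in the minimal plane along
    ``axis``), ``"top_cap"`` (maximal plane), or ``("disk", direction,
    angular_radius)`` removing faces whose centroid direction from the mesh
    centroid is within the given angle of ``direction``.
    """
    lo, hi = mesh.bounds
    tri = mesh.triangles
    tol = 1e-9 * max(mesh.bbox_diagonal, 1.0)
    if patch == "base_cap":
        sel = np.all(np.abs(tri[:, :, axis] - lo[axis]) <= tol, axis=1)
    elif patch == "top_cap":
        sel = np.all(np.abs(tri[:, :, axis] - hi[axis]) <= tol, axis=1)
    elif isinstance(patch, (tuple, list)) and patch[0] == "disk":
        _, direction, ang_radius = patch
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        center = mesh.vertices.mean(axis=0)
        cdirs = tri.mean(axis=1) - center
        cdirs /= np.linalg.norm(cdirs, axis=1)[:, None]
        sel = np.arccos(np.clip(cdirs @ d, -1.0, 1.0)) <= ang_radius
    else:
        raise ValueError(f"unknown patch {patch!r}")
    if not sel.any():
        raise MeshError(f"patch {patch!r} selects no faces")
    return mesh.with_faces(mesh.faces[~sel])


def corrupt_normals(mesh: TriangleMesh, fraction: float, seed: int = 0) -> TriangleMesh:
    """Reverse the winding of a seeded random fraction of faces.

    Emulates the inaccurate surface normals that surface reconstruction can
    produce; the vertex set is unchanged.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    m = mesh.n_faces
    k = max(1, int(round(fraction * m)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(m, size=min(k, m), replace=False)
    faces = mesh.faces.copy()
    faces[idx] = faces[idx][:, ::-1]
    return mesh.with_faces(faces)
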