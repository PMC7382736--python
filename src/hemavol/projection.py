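"""Projection (divergence-theorem) volume, as 3D-Slicer/VTK computes it.

Each triangle contributes, per axis, Heron area times the normal component
times the centroid coordinate — the signed volume of the prism between the
face and the coordinate plane.  For a closed, consistently oriented mesh the
three axis sums Vx, Vy, Vz are all equal to the enclosed volume, so any
weights summing to one give the exact result.  For an open or mis-oriented
mesh the sums disagree, depend on where the mesh sits relative to the origin,
and the estimate silently degrades — the failure mode this package exists to
quantify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import (
    EmptyMeshError,
    TriangleMesh,
    VolumeEstimate,
    face_arrays,
    topology_report,
)

__all__ = ["ProjectionResult", "projected_volumes", "projection_volume"]


@dataclass(frozen=True)
class ProjectionResult:
    Vx: float
    Vy: float
    Vz: float
    kx: float
    ky: float
    kz: float
    V: float


def projected_volumes(mesh: TriangleMesh) -> tuple[float, float, float]:
    """Per-axis signed projected-volume sums (Vx, Vy, Vz).

    V_axis = sum over faces of area * u_axis * avg_axis, degenerate faces
    skipped; the sign is carried by the unit normal u, i.e. by the winding.
    """
    if mesh.n_faces == 0:
        raise EmptyMeshError("projection of an empty mesh")
    area, normals, centroids, degen = face_arrays(mesh)
    keep = ~degen
    terms = area[keep, None] * normals[keep] * centroids[keep]
    vx, vy, vz = terms.sum(axis=0)
    return float(vx), float(vy), float(vz)


def projection_result(
    mesh: TriangleMesh, weight_mode: str = "equal"
) -> ProjectionResult:
    """Combine the axis sums with weights kx, ky, kz (summing to 1).

    ``equal``: kx = ky = kz = 1/3 — exact for closed meshes by the divergence
    theorem.  ``normal_weighted``: k_axis proportional to |sum of
    area * u_axis| (the net open-boundary signature); falls back to equal
    weights when all three vanish, which is precisely the closed case.
    """
    vx, vy, vz = projected_volumes(mesh)
    if weight_mode == "equal":
        k = np.array([1.0, 1.0, 1.0]) / 3.0
    elif weight_mode == "normal_weighted":
        area, normals, _, degen = face_arrays(mesh)
        net = np.abs((area[:, None] * normals)[~degen].sum(axis=0))
        k = net / net.sum() if net.sum() > 1e-12 * max(area.sum(), 1.0) else (
            np.array([1.0, 1.0, 1.0]) / 3.0
        )
    else:
        raise ValueError(f"unknown weight mode {weight_mode!r}")
    v = float(k[0] * vx + k[1] * vy + k[2] * vz)
    return ProjectionResult(vx, vy, vz, float(k[0]), float(k[1]), float(k[2]), v)


def projection_volume(
    mesh: TriangleMesh, weight_mode: str = "equal"
) -> VolumeEstimate:
    """Projection-method volume estimate with reliability warnings.

    An open or inconsistently oriented mesh yields a warning rather than an
    error: the method must remain runnable on invalid input so its failure
    can be measured.
    """
    res = projection_result(mesh, weight_mode)
    rep = topology_report(mesh)
    warnings = []
    if not rep.is_closed:
        warnings.append(
            f"mesh is not closed ({rep.boundary_edge_count} boundary edges): "
            "projection volume is unreliable and translation-dependent"
        )
    if not rep.is_consistently_oriented:
        warnings.append(
            "mesh has inconsistent face orientation: projection volume is unreliable"
        )
    if rep.degenerate_face_count:
        warnings.append(f"skipped {rep.degenerate_face_count} degenerate faces")
    return VolumeEstimate(
        "projection",
        res.V,
        {
            "weight_mode": weight_mode,
            "weights": (res.kx, res.ky, res.kz),
            "projected": (res.Vx, res.Vy, res.Vz),
        },
        warnings,
    )
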