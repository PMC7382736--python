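"""Cohort comparison harness and the bedside ABC/2 (Tada) comparator.

Runs every requested estimator over a cohort of synthetic hematoma phantoms
— optionally damaged by a hole or by flipped normals — and summarises signed
and absolute errors against a reference method evaluated on the intact
(closed) mesh, grouped by shape class and, when units are declared, by the
clinical ml size groups (<10, 10-20, >20 ml).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .generators import BlobSpec, corrupt_normals, make_blob, open_variant
from .mesh import (
    TriangleMesh,
    VolumeEstimate,
    monte_carlo_volume_oracle,
    signed_tet_volume_oracle,
)
from .projection import projection_volume
from .slicing import _axis_index, cross_section, slice_volume
from .voxel import voxel_volume

__all__ = [
    "CohortEntry",
    "METHOD_TAGS",
    "measure",
    "tada_volume",
    "tada_from_mesh",
    "run_cohort",
]

METHOD_TAGS = ("projection", "slice1", "slice2", "voxel", "tada", "tet_oracle", "mc_oracle")


def tada_volume(A: float, B: float, C: float) -> VolumeEstimate:
    """Bedside formula V = A*B*C/2 (long diameter, broad diameter, layer
    count x slice thickness).  Derived from the ellipsoid volume; known to
    degrade on irregular and lobular shapes."""
    if A <= 0 or B <= 0 or C <= 0:
        raise ValueError("Tada diameters must be positive")
    return VolumeEstimate("tada", A * B * C / 2.0, {"A": A, "B": B, "C": C})


def tada_from_mesh(mesh: TriangleMesh, axis=2, n_planes: int = 64) -> VolumeEstimate:
    """Measure A, B, C from the mesh the way a clinician reads a CT stack.

    A = longest diameter on the maximal-area slice, B = width perpendicular
    to A on the same slice, C = extent along the slicing axis.
    """
    ax = _axis_index(axis)
    lo, hi = mesh.bounds[:, ax]
    coords = np.linspace(lo, hi, n_planes + 1)
    best_pts, best_area = None, -1.0
    for c in coords:
        cs = cross_section(mesh, ax, c)
        if cs.area > best_area and cs.polygons:
            best_area = cs.area
            best_pts = np.concatenate([p for p in cs.polygons if len(p)])
    if best_pts is None:
        raise ValueError("mesh has no cross-section along the axis")
    # A: max pairwise distance on the maximal slice (coarse O(n^2) is fine)
    d = best_pts[:, None, :] - best_pts[None, :, :]
    dist = np.linalg.norm(d, axis=2)
    i, j = np.unravel_index(np.argmax(dist), dist.shape)
    A = float(dist[i, j])
    axis_a = (best_pts[j] - best_pts[i]) / max(A, 1e-12)
    perp = np.array([-axis_a[1], axis_a[0]])
    proj = best_pts @ perp
    B = float(proj.max() - proj.min())
    C = float(hi - lo)
    est = tada_volume(A, B, C)
    est.params["slice_area"] = best_area
    return est


def measure(
    mesh: TriangleMesh,
    method: str,
    segments: int = 7,
    axis=2,
    weight_mode: str = "equal",
    refinement: str = "slice_aligned",
    sub_slices: int = 4,
    mc_samples: int = 100_000,
    seed: int = 0,
) -> VolumeEstimate:
    """Dispatch a volume measurement by method tag."""
    if method == "projection":
        return projection_volume(mesh, weight_mode)
    if method == "slice1":
        return slice_volume(mesh, axis, segments, "method1")
    if method == "slice2":
        return slice_volume(mesh, axis, segments, "method2")
    if method == "voxel":
        return voxel_volume(mesh, segments, axis, refinement, sub_slices)
    if method == "tada":
        return tada_from_mesh(mesh, axis)
    if method == "tet_oracle":
        return signed_tet_volume_oracle(mesh)
    if method == "mc_oracle":
        return monte_carlo_volume_oracle(mesh, mc_samples, seed)
    raise ValueError(f"unknown method {method!r}; valid tags: {', '.join(METHOD_TAGS)}")


@dataclass(frozen=True)
class CohortEntry:
    """One cohort member: a phantom spec plus the damage applied to it."""

    mesh_id: str
    blob: BlobSpec
    open_patch: object = None  # None, "base_cap", "top_cap", ("disk", dir, ang)
    flip_fraction: float = 0.0
    flip_seed: int = 0

    def build(self) -> tuple[TriangleMesh, TriangleMesh]:
        """(closed mesh, measured mesh after the stated corruption)."""
        closed = make_blob(self.blob)
        measured = closed
        if self.open_patch is not None:
            measured = open_variant(measured, self.open_patch)
        if self.flip_fraction > 0:
            measured = corrupt_normals(measured, self.flip_fraction, self.flip_seed)
        return closed, measured


def _size_group(volume_ml: float) -> str:
    if volume_ml < 10:
        return "<10 ml"
    if volume_ml <= 20:
        return "10-20 ml"
    return ">20 ml"


def run_cohort(
    entries,
    methods,
    segments: int = 7,
    reference: str = "projection",
    axis=2,
    units: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Measure every cohort entry with every method and summarise errors.

    The reference method runs on the intact closed mesh (the standard-value
    convention); each listed method runs on the corrupted variant, and
    error = estimate - reference on the same phantom.  Returns (rows,
    summary) DataFrames; the summary holds mean signed and mean absolute
    error per shape class (and per ml size group when ``units='mm'``).
    """
    entries = list(entries)
    methods = list(methods)
    if not entries:
        raise ValueError("cohort is empty")
    if not methods:
        raise ValueError("no methods given")
    for m in list(methods) + [reference]:
        if m not in METHOD_TAGS:
            raise ValueError(
                f"unknown method {m!r}; valid tags: {', '.join(METHOD_TAGS)}"
            )
    rows = []
    for entry in entries:
        closed, measured = entry.build()
        ref = measure(closed, reference, segments=segments, axis=axis)
        group = _size_group(ref.volume / 1000.0) if units == "mm" else ""
        for method in methods:
            est = measure(measured, method, segments=segments, axis=axis)
            rows.append(
                {
                    "id": entry.mesh_id,
                    "shape_class": entry.blob.shape_class,
                    "size_group": group,
                    "method": method,
                    "volume": est.volume,
                    "reference": ref.volume,
                    "error": est.volume - ref.volume,
                }
            )
    df = pd.DataFrame(rows)
    keys = ["shape_class", "method"] if units != "mm" else [
        "shape_class",
        "size_group",
        "method",
    ]
    summary = (
        df.assign(abs_error=df["error"].abs())
        .groupby(keys, as_index=False)
        .agg(
            mean_error=("error", "mean"),
            mean_abs_error=("abs_error", "mean"),
            n=("error", "size"),
        )
    )
    return df, summary
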