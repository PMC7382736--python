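import numpy as np
import pytest
import trimesh

from hemavol import (
    EmptyMeshError,
    MeshError,
    MeshFormatError,
    OpenMeshError,
    TriangleMesh,
    corrupt_normals,
    face_geometry,
    monte_carlo_volume_oracle,
    read_mesh,
    reorient,
    signed_tet_volume,
    signed_tet_volume_oracle,
    topology_report,
    write_mesh,
)


def unit_tetrahedron():
    v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    f = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])
    return TriangleMesh(v, f)


class TestTriangleMesh:
    def test_invalid_face_index_rejected(self):
        with pytest.raises(MeshError):
            TriangleMesh(np.zeros((3, 3)), [[0, 1, 5]])

    def test_repeated_vertex_in_face_rejected(self):
        with pytest.raises(MeshError):
            TriangleMesh(np.eye(3), [[0, 1, 1]])


class TestFaceGeometry:
    @pytest.mark.parametrize(
        "tri, expected_area",
        [
            ([[0, 0, 0], [3, 0, 0], [0, 4, 0]], 6.0),  # 3-4-5 right triangle
            ([[0, 0, 0], [2, 0, 0], [1, np.sqrt(3), 0]], np.sqrt(3)),  # equilateral, side 2
        ],
    )
    def test_heron_area(self, tri, expected_area):
        mesh = TriangleMesh(np.array(tri, float), [[0, 1, 2]])
        geom = face_geometry(mesh, 0)
        assert geom.area == pytest.approx(expected_area, rel=1e-12)
        assert geom.s == pytest.approx((geom.a + geom.b + geom.c) / 2)
        assert np.linalg.norm(geom.u) == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(geom.avg, np.mean(tri, axis=0))

    def test_collinear_face_flagged_degenerate(self):
        mesh = TriangleMesh([[0, 0, 0], [1, 0, 0], [2, 0, 0]], [[0, 1, 2]])
        geom = face_geometry(mesh, 0)
        assert geom.area == 0.0
        assert geom.degenerate
        assert geom.u is None


class TestTopology:
    def test_closed_cube(self, cube):
        rep = topology_report(cube)
        assert rep.is_closed
        assert rep.is_consistently_oriented
        assert rep.boundary_edge_count == 0
        assert rep.non_manifold_edge_count == 0

    def test_removed_face_opens_three_boundary_edges(self, cube):
        broken = cube.with_faces(cube.faces[1:])
        rep = topology_report(broken)
        assert not rep.is_closed
        assert rep.boundary_edge_count == 3

    def test_flipped_face_detected_as_inconsistent(self, cube):
        faces = cube.faces.copy()
        faces[0] = faces[0][::-1]
        rep = topology_report(cube.with_faces(faces))
        assert rep.is_closed  # closure is orientation-blind
        assert not rep.is_consistently_oriented


class TestReorient:
    def test_restores_signed_volume_after_flips(self, cube):
        corrupted = corrupt_normals(cube, 0.25, seed=4)
        assert signed_tet_volume(corrupted) != pytest.approx(1000.0)
        fixed = reorient(corrupted)
        assert signed_tet_volume(fixed) == pytest.approx(1000.0, rel=1e-12)

    def test_idempotent_on_consistent_mesh(self, cube):
        fixed = reorient(cube)
        np.testing.assert_array_equal(fixed.faces, cube.faces)

    def test_open_mesh_rejected(self, cube):
        with pytest.raises(OpenMeshError):
            reorient(cube.with_faces(cube.faces[1:]))


class TestTetOracle:
    def test_unit_cube_and_tetrahedron(self):
        tet = unit_tetrahedron()
        assert signed_tet_volume_oracle(tet).volume == pytest.approx(1 / 6, rel=1e-12)

    def test_benchmark_volumes(self, pyramid, cube):
        assert signed_tet_volume_oracle(pyramid).volume == pytest.approx(6000.0, rel=1e-12)
        assert signed_tet_volume_oracle(cube).volume == pytest.approx(1000.0, rel=1e-12)

    def test_open_mesh_rejected(self, cube):
        with pytest.raises(OpenMeshError):
            signed_tet_volume_oracle(cube.with_faces(cube.faces[2:]))

    def test_agrees_with_trimesh_volume(self, blob_lobular):
        ref = trimesh.Trimesh(
            blob_lobular.vertices, blob_lobular.faces, process=False
        ).volume
        assert signed_tet_volume(blob_lobular) == pytest.approx(ref, rel=1e-9)


class TestMonteCarloOracle:
    def test_axis_aligned_cube_is_exact(self, cube):
        est = monte_carlo_volume_oracle(cube, 10_000, seed=1)
        assert est.volume == pytest.approx(1000.0)
        assert est.params["standard_error"] == 0.0

    def test_pyramid_within_three_sigma(self, pyramid):
        est = monte_carlo_volume_oracle(pyramid, 200_000, seed=5)
        se = est.params["standard_error"]
        assert abs(est.volume - 6000.0) <= 3 * se

    def test_deterministic_for_fixed_seed(self, pyramid):
        a = monte_carlo_volume_oracle(pyramid, 20_000, seed=9)
        b = monte_carlo_volume_oracle(pyramid, 20_000, seed=9)
        assert a.volume == b.volume

    def test_open_mesh_rejected(self, cube):
        with pytest.raises(OpenMeshError):
            monte_carlo_volume_oracle(cube.with_faces(cube.faces[2:]), 10_000)


class TestIO:
    @pytest.mark.parametrize("fmt", ["stl", "stl_ascii", "obj", "off"])
    def test_roundtrip_preserves_geometry(self, tmp_path, cube, fmt):
        path = tmp_path / f"cube.{ 'stl' if fmt.startswith('stl') else fmt }"
        write_mesh(cube, path, file_format=fmt)
        back = read_mesh(path)
        assert back.n_faces == cube.n_faces
        a = np.array(sorted(map(tuple, np.round(cube.vertices, 6))))
        b = np.array(sorted(map(tuple, np.round(back.vertices, 6))))
        np.testing.assert_allclose(a, b, atol=1e-6)
        assert signed_tet_volume(back) == pytest.approx(1000.0, rel=1e-6)

    def test_ascii_stl_merges_duplicate_vertices(self, tmp_path):
        tet = unit_tetrahedron()
        path = tmp_path / "tet.stl"
        write_mesh(tet, path, file_format="stl_ascii")
        assert path.read_text().count("facet normal") == 4
        back = read_mesh(path)
        assert back.n_vertices == 4
        assert back.n_faces == 4

    def test_off_cube_reads_closed(self, tmp_path, cube):
        path = tmp_path / "cube.off"
        write_mesh(cube, path)
        assert topology_report(read_mesh(path)).is_closed

    def test_obj_record_counts(self, tmp_path):
        simple = TriangleMesh(
            np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float),
            [[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]],
        )
        path = tmp_path / "tet.obj"
        write_mesh(simple, path)
        lines = path.read_text().splitlines()
        assert sum(1 for ln in lines if ln.startswith("v ")) == 4
        assert sum(1 for ln in lines if ln.startswith("f ")) == 4

    def test_unparseable_file_raises_format_error(self, tmp_path):
        bad = tmp_path / "bad.off"
        bad.write_text("not a mesh at all\n\x00\x01")
        with pytest.raises((MeshFormatError, EmptyMeshError)):
            read_mesh(bad)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_mesh(tmp_path / "nope.stl")

    def test_empty_mesh_write_rejected(self):
        empty = TriangleMesh(np.zeros((3, 3)), np.zeros((0, 3), int))
        with pytest.raises(EmptyMeshError):
            write_mesh(empty, "unused.stl")
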