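import numpy as np
import pytest

from hemavol import (
    BlobSpec,
    OctreeCell,
    build_octree,
    classify_leaf,
    corrupt_normals,
    iter_leaves,
    make_blob,
    open_variant,
    signed_tet_volume,
    slice_volume,
    voxel_volume,
    voxelize,
)


@pytest.fixture(scope="module")
def small_blob():
    return make_blob(BlobSpec.for_class("regular", seed=3, subdivision_level=2))


class TestOctree:
    def test_depth_one_gives_eight_cells(self, cube):
        root = build_octree(cube, 1)
        assert root.state == "subdivided"
        assert len(root.children) == 8

    def test_aligned_cube_boundary_cells_hug_the_faces(self, cube):
        root = build_octree(cube, 3)
        leaf = 10.0 / 2**3
        for cell in iter_leaves(root):
            if cell.state == "boundary":
                lo, hi = cell.min_corner, cell.min_corner + cell.side
                touches = any(
                    abs(lo[k]) < 1e-9 or abs(hi[k] - 10.0) < 1e-9 for k in range(3)
                )
                assert touches
                assert cell.side == pytest.approx(leaf)

    def test_brute_force_leaf_classification(self, cube):
        # compare octree in/out states against the analytic cube test
        root = build_octree(cube, 3)
        leaves = [c for c in iter_leaves(root) if c.state == "unclassified"]
        for cell in leaves:
            state = classify_leaf(cell, cube)
            c = cell.center
            analytic = bool(np.all((c > 0) & (c < 10)))
            assert (state == "inside") == analytic

    def test_boundary_cell_count_grows_like_surface(self, small_blob):
        counts = {
            s: voxelize(small_blob, segments=s).n_boundary for s in (4, 5, 6)
        }
        for s in (4, 5):
            assert 3.0 < counts[s + 1] / counts[s] < 5.5


class TestClassifyLeaf:
    def test_center_and_far_cells(self, cube):
        inside_cell = OctreeCell(np.array([4.0, 4.0, 4.0]), 2.0, 0)
        outside_cell = OctreeCell(np.array([40.0, 40.0, 40.0]), 2.0, 0)
        assert classify_leaf(inside_cell, cube) == "inside"
        assert classify_leaf(outside_cell, cube) == "outside"

    def test_matches_analytic_pyramid_membership(self, pyramid):
        rng = np.random.default_rng(12)
        pts = rng.uniform([0, 0, -2], [30, 30, 22], size=(2000, 3))

        def analytic(p):
            x, y, z = p
            if not 0 <= z <= 20:
                return False
            half = 15.0 * (1 - z / 20.0)
            return abs(x - 15) <= half and abs(y - 15) <= half

        margin = 0.05
        checked = 0
        for p in pts:
            half = 15.0 * (1 - np.clip(p[2], 0, 20) / 20.0)
            d = max(abs(p[0] - 15) - half, abs(p[1] - 15) - half, -p[2], p[2] - 20)
            if abs(d) < margin:  # skip points hugging the surface
                continue
            cell = OctreeCell(p - 1e-6, 2e-6, 0)
            assert (classify_leaf(cell, pyramid) == "inside") == analytic(p)
            checked += 1
        assert checked > 1500


class TestVoxelVolume:
    def test_aligned_cube_exact_both_refinements(self, cube):
        aligned = voxelize(cube, segments=5)
        assert aligned.volume == pytest.approx(1000.0, rel=1e-12)
        assert aligned.leaf_size == pytest.approx(10.0 / 16)
        sub = voxelize(cube, segments=5, refinement="sub_slices", sub_slices=4)
        assert sub.volume == pytest.approx(1000.0, rel=1e-9)

    def test_slice_aligned_equals_trapezoid_slice(
        self, pyramid, cube, small_blob
    ):
        for mesh, s in ((pyramid, 6), (cube, 5), (small_blob, 5)):
            v_vox = voxelize(mesh, segments=s).volume
            v_sl2 = slice_volume(mesh, "z", s, "method2").volume
            assert v_vox == pytest.approx(v_sl2, rel=1e-9)

    def test_decomposition_bookkeeping(self, small_blob):
        res = voxelize(small_blob, segments=5)
        assert res.volume == pytest.approx(
            res.inside_volume + res.boundary_volume, rel=1e-12
        )
        assert res.inside_volume <= res.volume
        assert res.volume <= res.inside_volume + res.n_boundary * res.leaf_size**3

    def test_monotone_sandwich(self, small_blob):
        oracle = signed_tet_volume(small_blob)
        prev_inside = 0.0
        for s in (4, 5, 6):
            res = voxelize(small_blob, segments=s)
            assert res.inside_volume >= prev_inside - 1e-9
            assert res.inside_volume <= oracle
            assert res.inside_volume + res.n_boundary * res.leaf_size**3 >= oracle
            prev_inside = res.inside_volume

    def test_sub_slices_error_halves_per_depth(self, small_blob):
        oracle = signed_tet_volume(small_blob)
        errs = {
            s: abs(
                voxelize(
                    small_blob, segments=s, refinement="sub_slices", sub_slices=4
                ).volume
                - oracle
            )
            for s in (4, 5, 6)
        }
        assert errs[5] <= errs[4] / 2
        assert errs[6] <= errs[5] / 2

    def test_no_inside_leaf_warns(self):
        tiny = make_blob(
            BlobSpec.for_class("regular", seed=0, subdivision_level=1)
        )
        est = voxel_volume(tiny, segments=2)
        assert est.volume > 0
        if est.params["inside_volume"] == 0:
            assert est.warnings

    def test_segments_domain(self, cube):
        with pytest.raises(ValueError):
            voxelize(cube, segments=1)
        with pytest.raises(ValueError):
            voxelize(cube, segments=5, refinement="nope")


class TestRobustness:
    def test_cap_removal_leaves_estimate_unchanged(self, pyramid):
        opened = open_variant(pyramid, "base_cap")
        for refinement in ("slice_aligned", "sub_slices"):
            v0 = voxelize(pyramid, segments=5, refinement=refinement).volume
            v1 = voxelize(opened, segments=5, refinement=refinement).volume
            assert abs(v1 - v0) / 6000.0 < 1e-6

    def test_flipped_normals_leave_estimate_unchanged(self, small_blob):
        corrupted = corrupt_normals(small_blob, 0.5, seed=2)
        v0 = voxelize(small_blob, segments=5).volume
        v1 = voxelize(corrupted, segments=5).volume
        assert v1 == pytest.approx(v0, rel=1e-12)
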