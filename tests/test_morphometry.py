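"""Morphometry: components, exact volumes, surface areas, MCI, extent."""

import math
from collections import deque

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitomorph import (
    MCI_SPHERE,
    Capsule,
    MeasureConfig,
    SegmentedObject,
    SemanticClass,
    Sphere,
    VoxelSpacing,
    connected_components,
    measure_all,
    mci,
    object_extent,
    object_surface_area,
    object_volume,
    voxelize_shape,
)

from conftest import make_volume


def flood_fill_components(mask, connectivity):
    """Brute-force BFS partition of a boolean mask — the oracle."""
    offsets = [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
        and (abs(dz) + abs(dy) + abs(dx) == 1 if connectivity == 6 else True)
    ]
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.add(v)
            for d in offsets:
                w = tuple(v[i] + d[i] for i in range(3))
                if all(0 <= w[i] < mask.shape[i] for i in range(3)) and mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(frozenset(comp))
    return set(comps)


def components_as_sets(objects):
    return {frozenset(map(tuple, o.voxel_indices())) for o in objects}


def sphere_object(radius_nm, spacing, center_jitter=0.37):
    sp = VoxelSpacing(*spacing)
    gshape = tuple(int(np.ceil(2 * (radius_nm + 4 * s) / s)) for s in sp.zyx)
    center = tuple((g / 2 + center_jitter) * s for g, s in zip(gshape, sp.zyx))
    shape = Sphere(center, radius_nm)
    mask, _ = voxelize_shape(shape, sp, gshape)
    return SegmentedObject(1, SemanticClass.MITOCHONDRION, mask, (0, 0, 0), sp), shape


class TestConnectedComponents:
    def test_two_separated_cubes(self):
        grid = np.zeros((10, 10, 10), dtype=np.uint16)
        grid[1:4, 1:4, 1:4] = 1
        grid[1:4, 1:4, 6:9] = 1  # 2-voxel gap
        objs = connected_components(make_volume(grid), SemanticClass.MITOCHONDRION, 26)
        assert [o.n_voxels for o in objs] == [27, 27]

    def test_corner_touch_connectivity(self):
        grid = np.zeros((4, 4, 4), dtype=np.uint16)
        grid[1, 1, 1] = 1
        grid[2, 2, 2] = 1  # share only a corner
        vol = make_volume(grid)
        assert len(connected_components(vol, SemanticClass.MITOCHONDRION, 26)) == 1
        assert len(connected_components(vol, SemanticClass.MITOCHONDRION, 6)) == 2

    def test_u_tube_merges_in_3d(self):
        # Two vertical arms joined at the bottom: middle slices show two
        # separate profiles, yet the object is one mitochondrion in 3D.
        grid = np.zeros((8, 8, 8), dtype=np.uint16)
        grid[1:7, 2:4, 1:3] = 1  # arm 1
        grid[1:7, 2:4, 5:7] = 1  # arm 2
        grid[1:3, 2:4, 1:7] = 1  # bridge at low z
        vol = make_volume(grid)
        for conn in (6, 26):
            objs = connected_components(vol, SemanticClass.MITOCHONDRION, conn)
            assert len(objs) == 1
            assert components_as_sets(objs) == flood_fill_components(grid > 0, conn)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_agrees_with_flood_fill_on_random_masks(self, connectivity):
        rng = np.random.default_rng(42)
        for _ in range(30):
            mask = rng.random((12, 12, 12)) < 0.3
            vol = make_volume(mask.astype(np.uint16))
            objs = connected_components(vol, SemanticClass.MITOCHONDRION, connectivity)
            assert components_as_sets(objs) == flood_fill_components(mask, connectivity)

    def test_deterministic_ordering_and_boundary_flag(self):
        grid = np.zeros((6, 6, 6), dtype=np.uint16)
        grid[0, 0, 0] = 1  # touches the volume face -> id 1 (lexicographic min)
        grid[3:5, 3:5, 3:5] = 1
        objs = connected_components(make_volume(grid), SemanticClass.MITOCHONDRION, 6)
        assert [o.object_id for o in objs] == [1, 2]
        assert objs[0].touches_boundary and not objs[1].touches_boundary

    def test_absent_class_errors_empty_class_does_not(self):
        grid = np.zeros((3, 3, 3), dtype=np.uint16)
        grid[1, 1, 1] = 1
        vol = make_volume(grid, pairs={1: SemanticClass.PRESYNAPTIC_TERMINAL,
                                       2: SemanticClass.MITOCHONDRION})
        # class in table but with zero voxels -> empty list
        assert connected_components(vol, SemanticClass.MITOCHONDRION) == []
        with pytest.raises(ValueError, match="not present"):
            connected_components(vol, SemanticClass.ENDOPLASMIC_RETICULUM)


class TestVolume:
    def test_exact_voxel_arithmetic(self):
        grid = np.zeros((5, 5, 5), dtype=np.uint16)
        grid[1:4, 1:4, 1:4] = 1
        obj = connected_components(make_volume(grid, spacing=(4, 4, 4)))[0]
        assert object_volume(obj) == pytest.approx(27 * 64 * 1e-9, rel=1e-12)

    def test_single_voxel_extreme_anisotropy(self):
        grid = np.zeros((3, 3, 3), dtype=np.uint16)
        grid[1, 1, 1] = 1
        obj = connected_components(make_volume(grid, spacing=(8.5, 8.5, 100.0)))[0]
        assert object_volume(obj) == pytest.approx(7.225e-6, rel=1e-12)

    def test_sphere_volume_within_2_percent(self):
        obj, shape = sphere_object(200.0, (8, 8, 8))
        assert object_volume(obj) * 1e9 == pytest.approx(shape.analytic_volume_nm3, rel=0.02)
        assert object_volume(obj) == pytest.approx(4 / 3 * math.pi * 0.2**3, rel=0.02)


class TestSurfaceArea:
    def test_single_voxel_face_counting(self):
        grid = np.zeros((3, 3, 3), dtype=np.uint16)
        grid[1, 1, 1] = 1
        obj = connected_components(make_volume(grid, spacing=(4, 4, 4)))[0]
        assert object_surface_area(obj, "voxel_faces") == pytest.approx(9.6e-5, rel=1e-12)
        # the mesh estimator must handle the degenerate case without error
        assert object_surface_area(obj, "mesh") > 0

    def test_sphere_mesh_within_3_percent_and_faces_overestimate(self):
        obj, shape = sphere_object(200.0, (8, 8, 8))
        a_mesh = object_surface_area(obj, "mesh") * 1e6
        a_faces = object_surface_area(obj, "voxel_faces") * 1e6
        assert a_mesh == pytest.approx(shape.analytic_surface_nm2, rel=0.03)
        assert a_faces > a_mesh  # face counting over-estimates curved surfaces

    def test_sphere_errors_shrink_with_radius(self):
        # volume and area errors, averaged over sub-voxel centre offsets to
        # wash out quantisation luck, decrease monotonically over a doubling
        # radius sequence (the mesh-area error later plateaus at its ~0.5%
        # estimator floor, so the sequence stops at 96 nm)
        sp = VoxelSpacing(4, 4, 4)
        verrs, aerrs = [], []
        for r in (24.0, 48.0, 96.0):
            g = int(np.ceil((2 * r + 60) / 4))
            ve, ae = [], []
            for off in (0.11, 0.29, 0.43, 0.57, 0.73):
                center = tuple((g / 2 + off) * 4 for _ in range(3))
                shape = Sphere(center, r)
                mask, _ = voxelize_shape(shape, sp, (g, g, g))
                obj = SegmentedObject(1, SemanticClass.MITOCHONDRION, mask, (0, 0, 0), sp)
                ve.append(abs(object_volume(obj) * 1e9 / shape.analytic_volume_nm3 - 1))
                ae.append(
                    abs(object_surface_area(obj, "mesh") * 1e6 / shape.analytic_surface_nm2 - 1)
                )
            verrs.append(np.mean(ve))
            aerrs.append(np.mean(ae))
        assert verrs[0] > verrs[1] > verrs[2]
        assert aerrs[0] > aerrs[1] > aerrs[2]

    def test_anisotropy_consistency(self):
        # the same 600 nm sphere sampled isotropically and on thick sections
        v = {}
        for spc in [(8, 8, 8), (6, 6, 30)]:
            obj, shape = sphere_object(600.0, spc)
            v[spc] = object_volume(obj) * 1e9
            assert v[spc] == pytest.approx(shape.analytic_volume_nm3, rel=0.05)
        assert v[(8, 8, 8)] == pytest.approx(v[(6, 6, 30)], rel=0.05)


class TestMCI:
    @pytest.mark.parametrize("r", [1.0, 10.0, 250.0])
    def test_sphere_closed_form(self, r):
        sa, v = 4 * math.pi * r**2, 4 / 3 * math.pi * r**3
        assert mci(sa, v, "vincent") == pytest.approx(MCI_SPHERE, rel=1e-12)
        assert mci(sa, v, "normalized") == pytest.approx(1.0, rel=1e-12)

    @given(
        sa=st.floats(1e-6, 1e6),
        v=st.floats(1e-6, 1e6),
        s=st.floats(1e-3, 1e3),
    )
    def test_scale_invariance(self, sa, v, s):
        assert mci(s**2 * sa, s**3 * v) == pytest.approx(mci(sa, v), rel=1e-9)

    def test_scale_invariance_factor_ten(self):
        assert mci(100 * 3.7, 1000 * 0.41) == pytest.approx(mci(3.7, 0.41), rel=1e-12)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            mci(0.0, 1.0)
        with pytest.raises(ValueError):
            mci(1.0, -2.0)

    def test_isoperimetric_bound_on_phantoms(self):
        sp = VoxelSpacing(8, 8, 8)
        shapes = [
            Sphere((800, 800, 800), 300),
            Capsule((800, 800, 400), (800, 800, 1400), 200),
        ]
        for shape in shapes:
            mask, _ = voxelize_shape(shape, sp, (200, 200, 250))
            obj = SegmentedObject(1, SemanticClass.MITOCHONDRION, mask, (0, 0, 0), sp)
            m = mci(object_surface_area(obj, "mesh"), object_volume(obj))
            assert m >= MCI_SPHERE - 0.02


class TestExtent:
    def test_straight_run(self):
        grid = np.zeros((3, 3, 102), dtype=np.uint16)
        grid[1, 1, 1:101] = 1
        obj = connected_components(make_volume(grid, spacing=(4, 4, 4)))[0]
        assert object_extent(obj) == pytest.approx(0.396, rel=1e-9)

    def test_single_voxel_is_zero(self):
        grid = np.zeros((3, 3, 3), dtype=np.uint16)
        grid[1, 1, 1] = 1
        obj = connected_components(make_volume(grid))[0]
        assert object_extent(obj) == 0.0

    def test_capsule_any_orientation(self):
        # tip-to-tip 2 µm capsule at 10 random orientations: extent within
        # 3% of the analytic length minus one voxel pitch
        rng = np.random.default_rng(5)
        sp = VoxelSpacing(8, 8, 8)
        tip_to_tip, r = 2000.0, 150.0
        for _ in range(10):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            half = (tip_to_tip / 2 - r) * u
            c = np.array([1400.0, 1400.0, 1400.0])
            cap = Capsule(tuple(c - half), tuple(c + half), r)
            mask, _ = voxelize_shape(cap, sp, (350, 350, 350))
            obj = SegmentedObject(1, SemanticClass.MITOCHONDRION, mask, (0, 0, 0), sp)
            expected = (tip_to_tip - sp.mean_pitch_nm) / 1000.0
            assert object_extent(obj) == pytest.approx(expected, rel=0.03)

    def test_capsule_mci_rotation_robust(self):
        rng = np.random.default_rng(11)
        sp = VoxelSpacing(8, 8, 8)
        values = []
        for _ in range(10):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            half = 700.0 * u
            c = np.array([1200.0, 1200.0, 1200.0])
            cap = Capsule(tuple(c - half), tuple(c + half), 180.0)
            mask, _ = voxelize_shape(cap, sp, (300, 300, 300))
            obj = SegmentedObject(1, SemanticClass.MITOCHONDRION, mask, (0, 0, 0), sp)
            values.append(mci(object_surface_area(obj, "mesh"), object_volume(obj)))
        assert (max(values) - min(values)) / np.mean(values) < 0.10


class TestMeasureAll:
    def test_three_disjoint_objects_stable_ids(self):
        grid = np.zeros((20, 20, 20), dtype=np.uint16)
        grid[2:6, 2:6, 2:6] = 1
        grid[10:14, 10:14, 10:14] = 1
        grid[2:6, 12:18, 2:8] = 1
        vol = make_volume(grid)
        first = measure_all(vol)
        second = measure_all(vol)
        assert len(first) == 3
        assert [r.object_id for r in first] == [r.object_id for r in second]
        assert [r.n_voxels for r in first] == [r.n_voxels for r in second]

    def test_empty_mitochondrion_class(self):
        grid = np.zeros((4, 4, 4), dtype=np.uint16)
        grid[1, 1, 1] = 2
        vol = make_volume(grid, pairs={1: SemanticClass.MITOCHONDRION,
                                       2: SemanticClass.PRESYNAPTIC_TERMINAL})
        assert measure_all(vol) == []

    def test_min_voxel_filter_and_boundary_exclusion(self):
        grid = np.zeros((8, 8, 8), dtype=np.uint16)
        grid[0, 0, 0] = 1  # single voxel on the boundary
        grid[3:6, 3:6, 3:6] = 1
        vol = make_volume(grid)
        assert len(measure_all(vol)) == 2
        assert len(measure_all(vol, MeasureConfig(min_voxels=2))) == 1
        assert len(measure_all(vol, MeasureConfig(exclude_boundary=True))) == 1
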