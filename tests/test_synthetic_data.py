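"""Phantom generator: exact voxelisation, cohorts, jitter, presets."""

import dataclasses
import json
import math

import numpy as np
import pytest

from mitomorph import (
    Capsule,
    CohortParams,
    Fig3Params,
    GroupSpec,
    LogNormalComponent,
    SemanticClass,
    Sphere,
    VoxelSpacing,
    add_boundary_jitter,
    connected_components,
    generate_cohort,
    generate_fig3_scene,
    load_preset,
    voxelize_shape,
)
from mitomorph.synthetic_data import PRESET_NAMES, _sample_volumes_um3


def tiny_params(seed=0, n_pre=4, n_post=3, spacing=(16, 16, 16)):
    """A miniature cohort (coarse voxels, small objects) for fast tests."""
    return CohortParams(
        name="tiny",
        spacing=VoxelSpacing(*spacing),
        groups={
            "presynaptic": GroupSpec(
                n=n_pre,
                components=(LogNormalComponent.from_mean_sd(0.05, 0.02),),
                aspect_range=(1.0, 1.5),
                target_mean_um3=0.05,
                target_sem_um3=0.02 / math.sqrt(n_pre),
            ),
            "postsynaptic": GroupSpec(
                n=n_post,
                components=(LogNormalComponent.from_mean_sd(0.2, 0.1),),
                aspect_range=(2.5, 5.0),
                target_mean_um3=0.2,
                target_sem_um3=0.1 / math.sqrt(n_post),
            ),
        },
        seed=seed,
    )


class TestVoxelize:
    def test_sphere_volume_within_1_percent_and_center_rule_exact(self):
        sp = VoxelSpacing(4, 4, 4)
        shape = Sphere((150.0, 150.0, 150.0), 100.0)
        mask, n = voxelize_shape(shape, sp, (75, 75, 75))
        assert n * sp.voxel_volume_nm3 == pytest.approx(shape.analytic_volume_nm3, rel=0.01)
        # centre-inclusion rule is exactly recomputable
        idx = np.argwhere(mask)
        centers = (idx + 0.5) * 4.0
        d = np.linalg.norm(centers - 150.0, axis=1)
        assert (d <= 100.0).all()

    def test_capsule_slice_extent(self):
        sp = VoxelSpacing(6, 6, 30)
        L, r = 900.0, 120.0
        cap = Capsule((300, 300, 400), (300, 300, 400 + L), r)
        mask, _ = voxelize_shape(cap, sp, (20, 100, 300))
        z_slices = np.unique(np.argwhere(mask)[:, 0]).size
        assert z_slices == pytest.approx((2 * r) / 30.0, abs=2)
        x_cols = np.unique(np.argwhere(mask)[:, 2]).size
        assert x_cols == pytest.approx((L + 2 * r) / 6.0, abs=2)

    def test_degenerate_sphere_single_voxel(self):
        sp = VoxelSpacing(8, 8, 8)
        # centred exactly on a voxel centre, radius below half a voxel pitch
        shape = Sphere((20.0, 20.0, 20.0), 3.0)
        mask, n = voxelize_shape(shape, sp, (5, 5, 5))
        assert n == 1
        assert mask[2, 2, 2]

    def test_shape_exceeding_grid_errors(self):
        with pytest.raises(ValueError, match="exceed"):
            voxelize_shape(Sphere((10, 10, 10), 500.0), VoxelSpacing(8, 8, 8), (6, 6, 6))

    def test_sphere_error_shrinks_with_resolution_ratio(self):
        sp = VoxelSpacing(8, 8, 8)
        errs = []
        for ratio in (5, 10, 20, 40):
            r = ratio * 8.0
            c = (r + 40.0 + 2.9, r + 40.0 + 2.9, r + 40.0 + 2.9)
            g = int(np.ceil((2 * r + 90) / 8))
            shape = Sphere(c, r)
            mask, n = voxelize_shape(shape, sp, (g, g, g))
            errs.append(abs(n * sp.voxel_volume_nm3 / shape.analytic_volume_nm3 - 1))
        assert errs[0] > errs[1] > errs[2] > errs[3]


class TestLogNormal:
    def test_mean_sd_round_trip(self):
        c = LogNormalComponent.from_mean_sd(0.195, 0.135)
        assert c.mean_um3 == pytest.approx(0.195, rel=1e-12)
        assert c.sd_um3 == pytest.approx(0.135, rel=1e-12)
        assert c.gsd > 1

    def test_sampled_mixture_hits_mean_and_subpopulations(self):
        preset = load_preset("cortex")
        group = preset.groups["postsynaptic"]
        assert group.mixture_mean_um3 == pytest.approx(group.target_mean_um3, rel=1e-9)
        big = dataclasses.replace(group, n=4000)
        rng = np.random.default_rng(0)
        draws = _sample_volumes_um3(big, rng, v_min_um3=1e-4)
        assert draws.mean() == pytest.approx(group.target_mean_um3, rel=0.1)
        # well-separated subpopulations: mass near 0.18 and mass beyond 1.2
        assert (draws < 0.4).mean() > 0.3
        assert (draws > 1.2).mean() > 0.15


class TestGenerateCohort:
    def test_counts_match_manifest_and_labels(self):
        vol, man = generate_cohort(tiny_params())
        mitos = man.mitochondria()
        assert len(mitos) == 7
        objs = connected_components(vol, SemanticClass.MITOCHONDRION)
        assert len(objs) == 7
        man.check_complete(vol)  # every nonzero label has one manifest entry

    def test_same_seed_is_byte_identical(self):
        v1, m1 = generate_cohort(tiny_params(seed=5))
        v2, m2 = generate_cohort(tiny_params(seed=5))
        np.testing.assert_array_equal(v1.grid, v2.grid)
        assert json.dumps(m1.to_json_obj(), sort_keys=True) == json.dumps(
            m2.to_json_obj(), sort_keys=True
        )
        v3, _ = generate_cohort(tiny_params(seed=6))
        assert v3.grid.shape != v1.grid.shape or not np.array_equal(v3.grid, v1.grid)

    def test_realized_voxel_volume_matches_analytic(self):
        vol, man = generate_cohort(tiny_params())
        voxvol = vol.spacing.voxel_volume_nm3 / 1e9
        for m in man.mitochondria():
            assert m.realized_voxels * voxvol == pytest.approx(m.analytic_volume_um3, rel=0.05)

    def test_manifest_completeness_detects_tampering(self):
        vol, man = generate_cohort(tiny_params())
        vol.grid[vol.grid == 1] = 0
        with pytest.raises(AssertionError, match="incomplete"):
            man.check_complete(vol)


class TestBoundaryJitter:
    def test_amplitude_zero_is_identity(self):
        vol, _ = generate_cohort(tiny_params())
        out = add_boundary_jitter(vol, 0, seed=1)
        np.testing.assert_array_equal(out.grid, vol.grid)
        assert out.grid is not vol.grid

    def test_volume_perturbation_bounded(self):
        sp = VoxelSpacing(8, 8, 8)
        shape = Sphere((300.0, 300.0, 300.0), 200.0)
        from mitomorph import LabelTable, LabelVolume

        mask, n = voxelize_shape(shape, sp, (75, 75, 75))
        base = LabelVolume(
            mask.astype(np.uint16), sp, LabelTable.from_pairs({1: SemanticClass.MITOCHONDRION})
        )
        for seed in range(10):
            out = add_boundary_jitter(base, 1, seed=seed)
            n_after = int((out.grid == 1).sum())
            assert abs(n_after - n) / n < 0.15

    def test_object_count_preserved(self):
        vol, man = generate_cohort(tiny_params(seed=2))
        before = len(connected_components(vol, SemanticClass.MITOCHONDRION))
        out = add_boundary_jitter(vol, 1, seed=3)
        after = len(connected_components(out, SemanticClass.MITOCHONDRION))
        assert before == after


class TestFig3Scene:
    def test_manifest_lists_spanned_boutons(self):
        _, man = generate_fig3_scene(boutons=4, extent_fraction=1.0)
        assert len(man.mitochondria()[0].spanned_bouton_ids) == 4
        _, man = generate_fig3_scene(boutons=5, extent_fraction=0.4)
        assert len(man.mitochondria()[0].spanned_bouton_ids) == 2

    def test_rejects_zero_boutons(self):
        with pytest.raises(ValueError):
            generate_fig3_scene(boutons=0)


class TestPresets:
    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_all_presets_load(self, name):
        preset = load_preset(name)
        assert isinstance(preset, (CohortParams, Fig3Params))

    def test_region_presets_carry_printed_group_statistics(self):
        expected = {
            "NA": ((0.05, 0.004, 67), (0.195, 0.018, 56), (4, 4, 4)),
            "CA1": ((0.043, 0.002, 200), (0.158, 0.017, 50), (8, 8, 8)),
            "cortex": ((0.056, 0.002, 324), (0.89, 0.124, 55), (6, 6, 30)),
            "DCN": ((0.375, 0.03, 85), (1.357, 0.182, 32), (8.5, 8.5, 100)),
        }
        for name, (pre, post, spc) in expected.items():
            p = load_preset(name)
            assert (p.spacing.dx, p.spacing.dy, p.spacing.dz) == spc
            for key, (mean, sem, n) in (("presynaptic", pre), ("postsynaptic", post)):
                g = p.groups[key]
                assert (g.target_mean_um3, g.target_sem_um3, g.n) == (mean, sem, n)
                assert g.mixture_mean_um3 == pytest.approx(mean, rel=1e-9)

    def test_seed_override(self):
        assert load_preset("NA", seed=17).seed == 17
        assert load_preset("fig3", seed=17).seed == 17
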