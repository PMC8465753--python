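"""Feature computation: refinement, scalar features, profiles, assembly."""

import numpy as np
import pytest

from glioprofile.features import (
    assemble_feature_record,
    compute_laterality,
    compute_multifocality,
    compute_resectability,
    compute_volume,
    cortical_profile,
    feature_names,
    find_foci,
    refine_tumor_mask,
    subcortical_profile,
)
from glioprofile.volumes import BinaryMask, EmptyMaskError, VolumeGeometry

from .conftest import cube_mask
from .oracles import brute_directed_p95


def _sphere(geometry, centre_mm, radius_mm):
    wx, wy, wz = geometry.world_coordinates()
    d2 = (wx - centre_mm[0]) ** 2 + (wy - centre_mm[1]) ** 2 + (wz - centre_mm[2]) ** 2
    return BinaryMask(geometry, d2 <= radius_mm ** 2)


class TestRefinement:
    def test_component_below_point_one_ml_removed(self, geometry):
        # 50 voxels at 1 mm^3 = 0.05 mL -> discarded
        data = np.zeros(geometry.shape, bool)
        data[2:4, 2:7, 2:7] = True  # 2*5*5 = 50 voxels
        refined = refine_tumor_mask(BinaryMask(geometry, data),
                                    closing_radius=1, closing_iterations=1)
        assert refined.is_empty

    def test_component_of_exactly_100_voxels_kept(self, geometry):
        # threshold is strict "smaller than": 0.1 mL survives
        data = np.zeros(geometry.shape, bool)
        data[2:6, 2:7, 2:7] = True  # 4*5*5 = 100 voxels = 0.1 mL
        refined = refine_tumor_mask(BinaryMask(geometry, data),
                                    closing_radius=1, closing_iterations=1)
        assert refined.voxel_count >= 100

    def test_large_sphere_kept_single_voxel_removed(self, geometry):
        mask = _sphere(geometry, (5.0, 0.0, 0.0), 10.0)
        data = mask.data.copy()
        data[1, 1, 1] = True  # isolated voxel far from the sphere
        refined = refine_tumor_mask(BinaryMask(geometry, data))
        assert not refined.data[1, 1, 1]
        assert refined.data[mask.data].all()  # sphere survives (closing extensive)

    def test_no_surviving_component_below_floor(self, geometry):
        rng = np.random.default_rng(2)
        data = rng.random(geometry.shape) < 0.02
        refined = refine_tumor_mask(BinaryMask(geometry, data))
        if not refined.is_empty:
            from glioprofile.volumes import connected_components
            comps = connected_components(refined)
            voxel_ml = geometry.voxel_volume_mm3 / 1000.0
            assert (comps.sizes * voxel_ml >= 0.1).all()


class TestVolume:
    def test_thousand_voxels_is_one_ml(self):
        geo = VolumeGeometry.isotropic((12, 12, 12))
        mask = cube_mask(geo, (0, 0, 0), 10)
        assert compute_volume(mask) == pytest.approx(1.0)

    def test_empty_mask_is_zero(self, small_geometry):
        mask = BinaryMask(small_geometry, np.zeros(small_geometry.shape, bool))
        assert compute_volume(mask) == 0.0

    def test_anisotropic_spacing(self):
        geo = VolumeGeometry((12, 12, 12), np.diag([0.98, 0.99, 1.0, 1.0]))
        data = np.zeros(geo.shape, bool)
        data.ravel()[:523] = True
        assert compute_volume(BinaryMask(geo, data)) == pytest.approx(
            523 * 0.98 * 0.99 * 1.0 / 1000.0)


class TestLaterality:
    def test_entirely_left(self, geometry, bundle):
        mask = _sphere(geometry, (-12.0, 0.0, 0.0), 5.0)
        left, right, crossing = compute_laterality(mask, bundle.hemisphere)
        assert (left, right, crossing) == (100.0, 0.0, False)

    def test_single_contralateral_voxel_sets_crossing(self, geometry, bundle):
        mask = _sphere(geometry, (-12.0, 0.0, 0.0), 5.0)
        data = mask.data.copy()
        right_idx = np.argwhere(bundle.hemisphere.right)[0]
        data[tuple(right_idx)] = True
        _, _, crossing = compute_laterality(BinaryMask(geometry, data),
                                            bundle.hemisphere)
        assert crossing

    def test_percentages_by_voxel_counting(self, geometry, bundle):
        data = np.zeros(geometry.shape, bool)
        left_idx = np.argwhere(bundle.hemisphere.left)[:60]
        right_idx = np.argwhere(bundle.hemisphere.right)[:40]
        for idx in np.concatenate([left_idx, right_idx]):
            data[tuple(idx)] = True
        left, right, crossing = compute_laterality(BinaryMask(geometry, data),
                                                   bundle.hemisphere)
        assert left == pytest.approx(60.0)
        assert right == pytest.approx(40.0)
        assert crossing
        assert left + right == pytest.approx(100.0, abs=1e-6)

    def test_empty_mask_rejected(self, geometry, bundle):
        empty = BinaryMask(geometry, np.zeros(geometry.shape, bool))
        with pytest.raises(EmptyMaskError):
            compute_laterality(empty, bundle.hemisphere)


class TestMultifocality:
    def test_single_component_sentinel(self, geometry):
        mask = _sphere(geometry, (5.0, 0.0, 0.0), 6.0)
        assert compute_multifocality(mask) == (False, 1, -1.0)

    def test_two_distant_foci(self, geometry):
        # surfaces 10 mm apart: gap between [-18,-8] and [2,12] spheres of r=5
        a = _sphere(geometry, (-13.0, 0.0, 0.0), 5.0)
        b = _sphere(geometry, (7.0, 0.0, 0.0), 5.0)
        mask = BinaryMask(geometry, a.data | b.data)
        multifocal, count, dist = compute_multifocality(mask)
        assert multifocal and count == 2
        assert dist == pytest.approx(10.0, abs=1.0)  # voxelization granularity

    def test_close_satellite_not_counted(self, geometry):
        # 3 mm gap < 5 mm rule -> treated as unifocal
        a = _sphere(geometry, (-10.0, 0.0, 0.0), 6.0)
        b = _sphere(geometry, (1.0, 0.0, 0.0), 2.0)  # gap = 11 - 8 = 3 mm
        mask = BinaryMask(geometry, a.data | b.data)
        assert compute_multifocality(mask) == (False, 1, -1.0)

    def test_biggest_focus_selected_by_volume(self, geometry):
        a = _sphere(geometry, (-12.0, 0.0, 0.0), 7.0)
        b = _sphere(geometry, (10.0, 5.0, 5.0), 3.0)
        mask = BinaryMask(geometry, a.data | b.data)
        foci = find_foci(mask)
        sizes = foci.components.sizes
        assert sizes[foci.index_of_biggest - 1] == sizes.max()
        assert foci.index_of_biggest not in foci.satellite_labels
        # equivalent-sphere diameter recovers the generating radius roughly
        d_big = foci.diameters_mm[foci.index_of_biggest - 1]
        assert d_big == pytest.approx(14.0, rel=0.1)


class TestResectability:
    def _heatmap(self, geometry, left_val, right_val, bundle):
        from glioprofile.atlas import ResectionHeatmap
        return ResectionHeatmap(geometry,
                                np.full(geometry.shape, left_val),
                                np.full(geometry.shape, right_val))

    def test_zero_heatmap_gives_zero_index(self, geometry, bundle):
        mask = _sphere(geometry, (-10.0, 0.0, 0.0), 5.0)
        hm = self._heatmap(geometry, 0.0, 0.0, bundle)
        residual, index = compute_resectability(mask, hm, 100.0, 0.0)
        assert index == 0.0
        assert residual == pytest.approx(mask.volume_ml())

    def test_unit_heatmap_gives_index_one(self, geometry, bundle):
        mask = _sphere(geometry, (-10.0, 0.0, 0.0), 5.0)
        hm = self._heatmap(geometry, 1.0, 1.0, bundle)
        residual, index = compute_resectability(mask, hm, 100.0, 0.0)
        assert index == pytest.approx(1.0)
        assert residual == pytest.approx(0.0, abs=1e-12)

    def test_direct_summation_small_tumor(self, geometry, bundle):
        from glioprofile.atlas import ResectionHeatmap
        left = np.zeros(geometry.shape)
        data = np.zeros(geometry.shape, bool)
        for i, p in enumerate((0.2, 0.5, 0.8)):
            data[10 + i, 10, 10] = True
            left[10 + i, 10, 10] = p
        hm = ResectionHeatmap(geometry, left, np.zeros(geometry.shape))
        residual, index = compute_resectability(BinaryMask(geometry, data),
                                                hm, 100.0, 0.0)
        assert index == pytest.approx(0.5)
        assert residual == pytest.approx(0.003 - 0.0015)

    def test_residual_plus_resectable_conserves_volume(self, geometry, bundle):
        mask = _sphere(geometry, (-8.0, 2.0, -3.0), 7.0)
        left, right, _ = compute_laterality(mask, bundle.hemisphere)
        residual, index = compute_resectability(mask, bundle.heatmap, left, right)
        vol = mask.volume_ml()
        assert residual + index * vol == pytest.approx(vol, rel=1e-9)


class TestProfiles:
    def test_tumor_inside_one_structure(self, geometry, bundle):
        atlas = bundle.cortical["Schaefer7"]
        label = 3
        idx = np.argwhere(atlas.labels == label)
        data = np.zeros(geometry.shape, bool)
        for i in idx[:30]:
            data[tuple(i)] = True
        profile = cortical_profile(BinaryMask(geometry, data), bundle.cortical)
        key = f"cortical.Schaefer7.{atlas.names[label]}"
        assert profile[key] == pytest.approx(100.0)
        others = [v for k, v in profile.items()
                  if k.startswith("cortical.Schaefer7.") and k != key]
        assert all(v == 0.0 for v in others)

    def test_profile_has_87_entries_summing_at_most_100_per_atlas(self, geometry, bundle):
        mask = _sphere(geometry, (-8.0, 0.0, 0.0), 8.0)
        profile = cortical_profile(mask, bundle.cortical)
        assert len(profile) == 87
        for atlas_id in bundle.cortical:
            total = sum(v for k, v in profile.items()
                        if k.startswith(f"cortical.{atlas_id}."))
            assert total <= 100.0 + 1e-9

    def test_half_in_each_of_two_structures(self, geometry, bundle):
        atlas = bundle.cortical["Harvard-Oxford"]
        ia = np.argwhere(atlas.labels == 1)[:20]
        ib = np.argwhere(atlas.labels == 2)[:20]
        data = np.zeros(geometry.shape, bool)
        for i in np.concatenate([ia, ib]):
            data[tuple(i)] = True
        profile = cortical_profile(BinaryMask(geometry, data), bundle.cortical)
        assert profile[f"cortical.Harvard-Oxford.{atlas.names[1]}"] == pytest.approx(50.0)
        assert profile[f"cortical.Harvard-Oxford.{atlas.names[2]}"] == pytest.approx(50.0)

    def test_subcortical_overlap_implies_zero_distance(self, geometry, bundle):
        name = bundle.subcortical.names[0]
        smask = bundle.subcortical.structure_mask(name)
        idx = np.argwhere(smask.data)[0]
        data = np.zeros(geometry.shape, bool)
        data[tuple(idx)] = True
        data[tuple(np.clip(idx + 1, 0, np.array(geometry.shape) - 1))] = True
        overlaps, distances = subcortical_profile(BinaryMask(geometry, data),
                                                  bundle.subcortical)
        assert overlaps[name] > 0
        assert distances[name] == 0.0
        assert len(overlaps) == len(distances) == 68

    def test_empty_structure_gets_sentinel(self, geometry, bundle):
        from glioprofile.atlas import ProbabilisticAtlas
        structures = dict(bundle.subcortical.structures)
        name = bundle.subcortical.names[5]
        structures[name] = np.full(geometry.shape, 0.3)  # empty after 0.5 threshold
        atlas = ProbabilisticAtlas(geometry, structures)
        mask = _sphere(geometry, (10.0, 10.0, 10.0), 3.0)
        _, distances = subcortical_profile(mask, atlas)
        assert distances[name] == -1.0

    def test_nonoverlap_distance_matches_bruteforce(self):
        geo = VolumeGeometry.isotropic((12, 12, 12))
        tumor = cube_mask(geo, (0, 0, 0), 3)
        structure = cube_mask(geo, (7, 7, 7), 3)
        from glioprofile.volumes import directed_distance_percentile
        got = directed_distance_percentile(tumor, structure, 95.0)
        assert got == pytest.approx(
            brute_directed_p95(tumor.data, structure.data, geo.spacing))


class TestAssembly:
    def test_record_has_233_named_values(self, geometry, bundle):
        mask = _sphere(geometry, (-8.0, 0.0, 0.0), 7.0)
        record = assemble_feature_record(mask, mask, bundle, refine=False)
        values = record.to_dict()
        assert len(values) == 233
        assert record.feature_count == 233
        assert list(values) == feature_names(bundle)

    def test_identical_masks_give_equal_volumes(self, geometry, bundle):
        mask = _sphere(geometry, (-8.0, 0.0, 0.0), 7.0)
        record = assemble_feature_record(mask, mask, bundle, refine=False)
        assert record.volume_patient_ml == record.volume_mni_ml

    def test_empty_refined_mask_gives_no_tumor_variant(self, geometry, bundle):
        data = np.zeros(geometry.shape, bool)
        data[3, 3, 3] = True  # single voxel: below the 0.1 mL floor
        record = assemble_feature_record(BinaryMask(geometry, data),
                                         BinaryMask(geometry, data), bundle)
        assert not record.has_tumor
        assert record.volume_mni_ml is None

    def test_geometry_mismatch_rejected(self, geometry, bundle):
        other = VolumeGeometry.isotropic((12, 12, 12))
        mask = cube_mask(other, (2, 2, 2), 4)
        with pytest.raises(ValueError):
            assemble_feature_record(mask, mask, bundle)
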