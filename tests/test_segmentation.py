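"""Reference-ROI threshold segmentation: the pipeline's core computation."""

import numpy as np
import pytest

from nmvol.errors import DegenerateReferenceError, EmptyRegionError
from nmvol.image import BinaryMask, ProbabilisticAtlas, VoxelImage
from nmvol.phantom import generate_subject, make_atlases
from nmvol.registration import motion_correct_and_average
from nmvol.segmentation import (
    LC_PARAMS,
    SNC_PARAMS,
    ReferenceStats,
    SegmentationParams,
    build_search_region,
    reference_stats,
    segment_structure,
    segment_subject,
)

from conftest import quiet_spec

AFFINE = np.diag([0.39, 0.39, 3.0, 1.0])


def brute_force_segment(image, search, mu, sigma, k):
    """Naive triple-loop oracle for the threshold rule."""
    out = np.zeros(image.shape, dtype=bool)
    thr = mu + k * sigma
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            for l in range(image.shape[2]):
                if search[i, j, l] and image[i, j, l] > thr:
                    out[i, j, l] = True
    return out


class TestReferenceStats:
    def test_hand_computed_mean_and_sd(self):
        data = np.zeros((3, 1, 1))
        data[:, 0, 0] = [8.0, 10.0, 12.0]
        img = VoxelImage(data, AFFINE)
        mask = BinaryMask(np.ones((3, 1, 1), dtype=bool), AFFINE)
        stats = reference_stats(img, mask)
        assert stats.mu_ref == pytest.approx(10.0)
        assert stats.sigma_ref == pytest.approx(2.0)  # n−1 denominator
        assert stats.n_ref == 3

    def test_constant_region_is_degenerate(self):
        img = VoxelImage(np.full((3, 3, 3), 4.2), AFFINE)
        mask = BinaryMask(np.ones((3, 3, 3), dtype=bool), AFFINE)
        with pytest.raises(DegenerateReferenceError):
            reference_stats(img, mask)

    def test_too_few_voxels_rejected(self):
        img = VoxelImage(np.ones((3, 3, 3)), AFFINE)
        mask = BinaryMask(np.zeros((3, 3, 3), dtype=bool), AFFINE)
        with pytest.raises(DegenerateReferenceError):
            reference_stats(img, mask)

    def test_phantom_reference_mean_within_clt_bound(self, default_subject):
        spec, measurements, truth = default_subject
        stats = reference_stats(measurements[0], truth.ref_mask)
        bound = 3.0 * spec.ref_region_sd / np.sqrt(stats.n_ref)
        assert abs(stats.mu_ref - spec.ref_region_mean) < bound


class TestSearchRegion:
    def test_all_zero_atlas_rejected(self):
        atlas = ProbabilisticAtlas(np.zeros((4, 4, 4)), AFFINE)
        with pytest.raises(EmptyRegionError):
            build_search_region(atlas, SNC_PARAMS)

    def test_single_voxel_dilates_to_six_connected_cross(self):
        prob = np.zeros((5, 5, 5))
        prob[2, 2, 2] = 1.0
        atlas = ProbabilisticAtlas(prob, AFFINE)
        mask = build_search_region(
            atlas, SegmentationParams(k=2.8, dilation_iterations=1)
        )
        assert mask.voxel_count == 7
        expected = {(2, 2, 2), (1, 2, 2), (3, 2, 2), (2, 1, 2), (2, 3, 2),
                    (2, 2, 1), (2, 2, 3)}
        assert set(map(tuple, np.argwhere(mask.data))) == expected

    def test_zero_dilations_equal_raw_threshold(self):
        rng = np.random.default_rng(0)
        atlas = ProbabilisticAtlas(rng.random((6, 6, 4)), AFFINE)
        mask = build_search_region(
            atlas, SegmentationParams(k=2.8, dilation_iterations=0)
        )
        np.testing.assert_array_equal(mask.data, atlas.data > 0.05)


class TestSegmentStructure:
    def test_hand_case_threshold_and_count(self):
        intensities = [10.0, 12.0, 15.0, 20.0, 25.0]
        data = np.zeros((5, 1, 1))
        data[:, 0, 0] = intensities
        img = VoxelImage(data, AFFINE)
        search = BinaryMask(np.ones((5, 1, 1), dtype=bool), AFFINE)
        ref = ReferenceStats(mu_ref=10.0, sigma_ref=2.0, n_ref=100)
        result = segment_structure(img, search, ref, SegmentationParams(k=2.8))
        assert result.threshold_value == pytest.approx(15.6)
        assert result.voxel_count == 2

    def test_flat_image_yields_empty_valid_result(self):
        img = VoxelImage(np.full((4, 4, 4), 10.0), AFFINE)
        search = BinaryMask(np.ones((4, 4, 4), dtype=bool), AFFINE)
        ref = ReferenceStats(mu_ref=10.0, sigma_ref=1.0, n_ref=50)
        result = segment_structure(img, search, ref, SNC_PARAMS)
        assert result.voxel_count == 0 and result.volume_mm3 == 0.0

    def test_threshold_is_strict_inequality(self):
        img = VoxelImage(np.full((2, 2, 2), 12.8), AFFINE)
        search = BinaryMask(np.ones((2, 2, 2), dtype=bool), AFFINE)
        ref = ReferenceStats(mu_ref=10.0, sigma_ref=1.0, n_ref=50)
        result = segment_structure(img, search, ref, SegmentationParams(k=2.8))
        assert result.voxel_count == 0  # 12.8 == threshold, excluded

    def test_agrees_with_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            img_data = rng.normal(10, 4, size=(16, 16, 8))
            search_data = rng.random((16, 16, 8)) > 0.5
            img = VoxelImage(img_data, AFFINE)
            search = BinaryMask(search_data, AFFINE)
            ref = ReferenceStats(
                mu_ref=float(rng.normal(10, 1)),
                sigma_ref=float(rng.uniform(0.5, 4)),
                n_ref=100,
            )
            k = float(rng.uniform(0.5, 4))
            result = segment_structure(img, search, ref, SegmentationParams(k=k))
            oracle = brute_force_segment(
                img_data, search_data, ref.mu_ref, ref.sigma_ref, k
            )
            np.testing.assert_array_equal(result.mask.data, oracle)

    def test_volume_non_increasing_in_k(self):
        rng = np.random.default_rng(1)
        img = VoxelImage(rng.normal(10, 4, size=(12, 12, 6)), AFFINE)
        search = BinaryMask(np.ones((12, 12, 6), dtype=bool), AFFINE)
        ref = ReferenceStats(mu_ref=10.0, sigma_ref=2.0, n_ref=100)
        volumes = [
            segment_structure(img, search, ref, SegmentationParams(k=k)).volume_mm3
            for k in (0.5, 1.0, 2.0, 2.8, 3.9)
        ]
        assert all(a >= b for a, b in zip(volumes, volumes[1:]))
        assert volumes[0] > volumes[-1]

    def test_scale_equivariance(self):
        rng = np.random.default_rng(2)
        data = rng.normal(10, 4, size=(10, 10, 5))
        search = BinaryMask(np.ones((10, 10, 5), dtype=bool), AFFINE)
        ref = ReferenceStats(mu_ref=10.0, sigma_ref=2.0, n_ref=100)
        base = segment_structure(VoxelImage(data, AFFINE), search, ref, SNC_PARAMS)
        c = 37.5
        scaled_ref = ReferenceStats(10.0 * c, 2.0 * c, 100)
        scaled = segment_structure(
            VoxelImage(data * c, AFFINE), search, ref=scaled_ref, params=SNC_PARAMS
        )
        np.testing.assert_array_equal(base.mask.data, scaled.mask.data)


class TestSegmentSubject:
    def test_noise_free_phantom_recovers_truth_exactly(self):
        spec = quiet_spec()
        measurements, truth = generate_subject(spec)
        averaged = motion_correct_and_average(measurements, skip_moco=True)
        snc_atlas, lc_atlas, _ = make_atlases(spec)
        snc, lc = segment_subject(
            averaged, snc_atlas, lc_atlas, truth.ref_mask
        )
        assert snc.voxel_count == truth.snc_mask.voxel_count
        assert lc.voxel_count == truth.lc_mask.voxel_count
        assert snc.volume_mm3 == pytest.approx(truth.true_volumes["snc"])

    def test_full_default_pipeline_recovers_volumes(self, default_subject):
        # with motion + estimated realignment, interpolation smooths the
        # reference noise and lowers thresholds slightly; recovery is held
        # to a wider bound than the motion-free case
        spec, measurements, truth = default_subject
        averaged = motion_correct_and_average(measurements)
        snc_atlas, lc_atlas, _ = make_atlases(spec)
        snc, lc = segment_subject(averaged, snc_atlas, lc_atlas, truth.ref_mask)
        assert snc.volume_mm3 == pytest.approx(truth.true_volumes["snc"], rel=0.25)
        assert lc.volume_mm3 == pytest.approx(truth.true_volumes["lc"], rel=0.25)

    def test_lc_threshold_strictly_above_snc_threshold(self, quiet_subject):
        _, measurements, truth = quiet_subject
        averaged = motion_correct_and_average(measurements, skip_moco=True)
        spec = quiet_spec()
        snc_atlas, lc_atlas, _ = make_atlases(spec)
        snc, lc = segment_subject(averaged, snc_atlas, lc_atlas, truth.ref_mask)
        assert lc.threshold_value > snc.threshold_value
        assert lc.params.k == 3.9 and snc.params.k == 2.8

    def test_low_contrast_lc_yields_zero_volume_while_snc_survives(self):
        # LC contrast below 3.9·σ_ref leaves the LC empty; SNc at full
        # contrast still segments
        spec = quiet_spec(lc_contrast=0.5)
        measurements, truth = generate_subject(spec)
        averaged = motion_correct_and_average(measurements, skip_moco=True)
        snc_atlas, lc_atlas, _ = make_atlases(spec)
        snc, lc = segment_subject(averaged, snc_atlas, lc_atlas, truth.ref_mask)
        assert lc.volume_mm3 == 0.0
        assert snc.volume_mm3 > 0.0

    def test_result_volume_consistent_with_voxel_count(self, quiet_subject):
        _, measurements, truth = quiet_subject
        averaged = motion_correct_and_average(measurements, skip_moco=True)
        spec = quiet_spec()
        snc_atlas, lc_atlas, _ = make_atlases(spec)
        snc, _ = segment_subject(averaged, snc_atlas, lc_atlas, truth.ref_mask)
        assert snc.volume_mm3 == pytest.approx(
            snc.voxel_count * np.prod(averaged.voxel_dims)
        )
        assert snc.count_components() >= 2  # bilateral structure
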