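import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoquant import (
    AnalysisConfig,
    SimCellParams,
    VoxelGrid,
    classify_size,
    label_objects,
    measure_objects,
    median_filter_3d,
    segment_mito,
    simulate_cell,
    threshold_constant,
    tophat_filter_3d,
)
from mitoquant.segmentation import BinaryMask, ellipsoid_footprint, suggest_threshold
from oracles import flood_fill_labels, median_oracle, tophat_oracle

GEOM = (0.35, 0.325, 0.325)
ISO = (1.0, 1.0, 1.0)


def grid(data, geom=ISO, **kw):
    return VoxelGrid(np.asarray(data, dtype=float), *geom, **kw)


class TestMedianFilter:
    def test_isolated_impulse_removed(self):
        a = np.zeros((3, 3, 3))
        a[1, 1, 1] = 100
        out = median_filter_3d(grid(a), 1)
        assert not out.data.any()

    def test_constant_stack_unchanged(self):
        out = median_filter_3d(grid(np.full((4, 5, 6), 7.0)), 2)
        np.testing.assert_array_equal(out.data, 7.0)

    def test_radius_zero_is_identity(self, rng):
        a = rng.integers(0, 100, (4, 4, 4)).astype(float)
        np.testing.assert_array_equal(median_filter_3d(grid(a), 0).data, a)

    def test_matches_neighborhood_oracle(self, rng):
        a = rng.integers(0, 256, (5, 5, 5)).astype(float)
        out = median_filter_3d(grid(a), 1)
        np.testing.assert_array_equal(out.data, median_oracle(a, 1))

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            median_filter_3d(grid(np.zeros((2, 2, 2))), -1)


class TestTophatFilter:
    def test_flat_image_maps_to_zero(self):
        out = tophat_filter_3d(grid(np.full((6, 6, 6), 50.0)), radius_um=2.0)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_thin_line_survives_intact(self):
        a = np.zeros((7, 9, 9))
        a[3, 4, :] = 100.0
        out = tophat_filter_3d(grid(a), radius_um=2.0)
        np.testing.assert_array_equal(out.data, a)

    def test_plateau_removed_line_kept(self, rng):
        # flat plateau (40) much wider than the element + thin line (100):
        # only the line's excess over the plateau survives
        a = np.full((7, 15, 15), 40.0)
        a[3, 7, :] = 100.0
        out = tophat_filter_3d(grid(a), radius_um=2.0)
        fp = ellipsoid_footprint((2.0, 2.0, 2.0))
        np.testing.assert_array_equal(out.data, tophat_oracle(a, fp))
        assert out.data[3, 7, 7] == 60.0
        assert out.data[0, 0, 0] == 0.0

    def test_matches_erosion_dilation_oracle(self, rng):
        a = rng.integers(0, 200, (6, 8, 7)).astype(float)
        out = tophat_filter_3d(grid(a), radius_um=1.5)
        np.testing.assert_array_equal(out.data, tophat_oracle(a, ellipsoid_footprint((1.5,) * 3)))

    def test_anisotropic_element(self, rng):
        a = rng.integers(0, 200, (4, 10, 10)).astype(float)
        g = VoxelGrid(a, 0.5, 0.25, 0.25)
        out = tophat_filter_3d(g, radius_um=0.5)
        fp = ellipsoid_footprint((1.0, 2.0, 2.0))
        np.testing.assert_array_equal(out.data, tophat_oracle(a, fp))

    def test_element_larger_than_stack_rejected(self):
        with pytest.raises(ValueError, match="larger than"):
            tophat_filter_3d(grid(np.zeros((2, 20, 20))), radius_um=5.0)


class TestThreshold:
    def test_boundary_inclusive(self):
        g = grid([[[0.0, 5.0, 10.0]]])
        mask = threshold_constant(g, 5.0)
        np.testing.assert_array_equal(mask.data, [[[False, True, True]]])

    def test_zero_threshold_all_true(self, rng):
        g = grid(rng.integers(0, 9, (3, 3, 3)).astype(float))
        assert threshold_constant(g, 0.0).data.all()

    def test_above_max_all_false(self, rng):
        g = grid(rng.integers(0, 9, (3, 3, 3)).astype(float))
        assert not threshold_constant(g, 10.0).data.any()

    def test_suggest_threshold_mean_plus_k_sd(self):
        g = grid(np.arange(8.0).reshape(2, 2, 2))
        bg = np.ones((2, 2, 2), dtype=bool)
        vals = np.arange(8.0)
        assert suggest_threshold(g, bg, k=3.0) == pytest.approx(vals.mean() + 3 * vals.std())


class TestLabelObjects:
    def test_two_separated_clusters(self):
        m = np.zeros((3, 3, 7), dtype=bool)
        m[1, 1, 0:2] = True
        m[1, 1, 5:7] = True
        labels = label_objects(BinaryMask(m, *ISO))
        assert labels.n_labels == 2

    def test_corner_touch_connectivity(self):
        m = np.zeros((2, 2, 2), dtype=bool)
        m[0, 0, 0] = m[1, 1, 1] = True
        assert label_objects(BinaryMask(m, *ISO), connectivity=26).n_labels == 1
        assert label_objects(BinaryMask(m, *ISO), connectivity=6).n_labels == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle(self, rng, connectivity):
        m = rng.random((10, 10, 10)) < 0.2
        labels = label_objects(BinaryMask(m, *ISO), connectivity)
        expected = flood_fill_labels(m, connectivity)
        np.testing.assert_array_equal(labels.data, expected)  # includes label order
        assert labels.n_labels == expected.max()

    def test_labels_follow_raster_order_of_first_voxel(self):
        m = np.zeros((1, 4, 8), dtype=bool)
        m[0, 0, 6] = True  # first in raster order
        m[0, 2, 0:2] = True
        labels = label_objects(BinaryMask(m, *ISO))
        assert labels.data[0, 0, 6] == 1
        assert labels.data[0, 2, 0] == 2


class TestClassifySize:
    @pytest.mark.parametrize(
        "volume,expected",
        [(1.9, "small"), (2.0, "medium"), (10.0, "medium"), (10.5, "network"), (0.0, "small")],
    )
    def test_boundaries(self, volume, expected):
        assert classify_size(volume) == expected

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1e6, allow_nan=False))
    def test_partitions_volumes_exhaustively(self, v):
        assert classify_size(v) in {"small", "medium", "network"}

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            classify_size(-0.1)


class TestMeasureObjects:
    def test_volume_arithmetic_and_class(self):
        lab = np.zeros((10, 10, 10), dtype=np.int32)
        lab.ravel()[:100] = 1
        labels = label_objects(BinaryMask(lab > 0, 0.35, 0.325, 0.325))
        inten = VoxelGrid(np.full((10, 10, 10), 10.0), 0.35, 0.325, 0.325)
        (rec,) = measure_objects(labels, inten)
        assert rec.voxel_count == 100
        assert rec.volume_um3 == pytest.approx(3.696875)
        assert rec.size_class == "medium"
        assert rec.mean_intensity == 10.0
        assert rec.total_intensity == pytest.approx(10.0 * 100)

    def test_shape_mismatch_rejected(self):
        labels = label_objects(BinaryMask(np.ones((2, 2, 2), dtype=bool), *ISO))
        with pytest.raises(ValueError):
            measure_objects(labels, grid(np.zeros((3, 3, 3))))

    def test_ground_truth_sums_exact(self, simulated_cell):
        channels, truth = simulated_cell
        # measuring the truth label map against any intensity stack must
        # reproduce the planted voxel counts exactly
        recs = measure_objects(truth.label_volume, channels.mito)
        counts = {r.object_id: r.voxel_count for r in recs}
        for row in truth.per_object.itertuples():
            assert counts[row.object_id] == row.voxel_count


class TestSegmentMito:
    def test_all_zero_stack_gives_no_objects(self, sim_config):
        g = VoxelGrid(np.zeros((8, 10, 10)), *GEOM)
        labels, records = segment_mito(g, sim_config)
        assert labels.n_labels == 0 and records == []

    def test_recovers_planted_object_count(self, simulated_cell, sim_config):
        channels, truth = simulated_cell
        labels, records = segment_mito(channels.mito, sim_config)
        assert truth.n_objects == 30
        assert labels.n_labels == 30

    def test_deterministic(self, simulated_cell, sim_config):
        channels, _ = simulated_cell
        l1, _ = segment_mito(channels.mito, sim_config)
        l2, _ = segment_mito(channels.mito, sim_config)
        np.testing.assert_array_equal(l1.data, l2.data)

    def test_voxel_conservation_and_renumbering_invariance(self, simulated_cell, sim_config):
        channels, _ = simulated_cell
        labels, records = segment_mito(channels.mito, sim_config)
        assert sum(r.voxel_count for r in records) == np.count_nonzero(labels.data)
        # permute labels: totals must be invariant
        perm = np.concatenate([[0], np.random.default_rng(1).permutation(labels.n_labels) + 1])
        relabeled = type(labels)(perm[labels.data], labels.n_labels, labels.dz, labels.dy, labels.dx)
        recs2 = measure_objects(relabeled, channels.mito)
        assert sorted(r.voxel_count for r in recs2) == sorted(r.voxel_count for r in records)
        assert sum(r.total_intensity for r in recs2) == pytest.approx(
            sum(r.total_intensity for r in records)
        )

    def test_intensity_measured_on_input_not_filtered(self, sim_config):
        # a stack with uniform foreground: filtered values drop, but measured
        # mean intensity must equal the raw foreground value
        a = np.zeros((9, 15, 15))
        a[4, 7, 2:13] = 400.0
        g = VoxelGrid(a, *GEOM)
        cfg = AnalysisConfig(threshold_value=50.0, median_radius=0, tophat_radius_um=1.0)
        _, records = segment_mito(g, cfg)
        assert len(records) == 1
        assert records[0].mean_intensity == pytest.approx(400.0)
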