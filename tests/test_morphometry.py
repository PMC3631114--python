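import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bonepore as bp
from bonepore.morphometry import (
    HistogramSpec,
    circularity,
    elongation_from_coords,
    measure_object,
    measure_slice,
    shape_roughness,
    summarize_groups,
)
from bonepore.segmentation import CalibratedImage, threshold_segment
from conftest import match_objects


def segment_clean(img):
    """Direct threshold of a noiseless synthetic image (binary by construction)."""
    return threshold_segment(img, 100)


class TestCircularity:
    def test_analytic_circle_is_zero(self):
        r = 50.0
        assert circularity(math.pi * r**2, 2 * math.pi * r) == 0.0

    def test_analytic_square(self):
        s = 7.0
        assert circularity(s**2, 4 * s) == pytest.approx(1 - math.pi / 4, abs=1e-12)

    @given(st.floats(1.0, 1e4), st.floats(1.0, 1e4))
    def test_range(self, a, p):
        assert 0.0 <= circularity(a, p) < 1.0


class TestShapeRoughness:
    def test_equal_radii_give_one(self):
        assert shape_roughness(np.full(100, 3.7)) == pytest.approx(1.0, abs=1e-15)

    def test_known_three_point_value(self):
        # med=2, min=1, max=4 -> cbrt(2*1/16)
        assert shape_roughness([1.0, 2.0, 4.0]) == pytest.approx((2 / 16) ** (1 / 3))

    @settings(deadline=None)
    @given(st.lists(st.floats(0.1, 100.0), min_size=1, max_size=50))
    def test_in_unit_interval_and_one_iff_constant(self, radii):
        sr = shape_roughness(radii)
        assert 0.0 < sr <= 1.0
        if min(radii) == max(radii):
            assert sr == pytest.approx(1.0, abs=1e-12)
        elif max(radii) / min(radii) > 1.001:
            assert sr < 1.0


class TestMeasureObject:
    def test_digitized_disk_anchors(self, disk_image):
        img, truth = disk_image
        o = measure_slice(segment_clean(img)).objects[0]
        assert o.circularity <= 0.05
        assert o.shape_roughness > 0.97
        assert abs(o.elongation - 1.0) < 0.02
        assert abs(o.area_um2 - truth[0].true_area_um2) / truth[0].true_area_um2 < 0.02

    def test_area_is_count_times_calibration(self, disk_image):
        img, _ = disk_image
        mask = segment_clean(img)
        o = measure_object(mask, 1)
        assert o.area_um2 == o.pixel_count * img.pixel_area_um2

    def test_single_pixel_conventions(self):
        arr = np.full((9, 9), 200, dtype=np.uint8)
        arr[4, 4] = 10
        o = measure_object(threshold_segment(CalibratedImage(arr, 2.971), 50), 1)
        assert o.area_um2 == pytest.approx(2.971)
        assert (o.elongation, o.circularity, o.shape_roughness) == (1.0, 0.0, 1.0)
        assert o.degenerate

    def test_collinear_pixels_flagged(self):
        coords = np.column_stack([np.arange(6), np.arange(6)])
        e, degenerate = elongation_from_coords(coords)
        assert degenerate and e == 6.0

    def test_rasterized_ellipse_elongation(self):
        spec = bp.SyntheticImageSpec(
            width_px=256, height_px=256, n_objects=1,
            axis_length_range_px=(80, 80), axis_ratio_range=(2, 2), seed=1,
        )
        img, _ = bp.generate_pore_image(spec)
        o = measure_slice(segment_clean(img)).objects[0]
        assert o.elongation == pytest.approx(2.00, abs=0.05)

    def test_sr_matches_brute_force_contour_scan(self):
        # exhaustive scan over every traced contour vertex, written
        # independently of the morphometry internals
        spec = bp.SyntheticImageSpec(
            width_px=400, height_px=400, n_objects=6,
            axis_length_range_px=(15, 30), axis_ratio_range=(1, 2.5),
            roughness_amplitude=0.2, seed=11,
        )
        img, _ = bp.generate_pore_image(spec)
        mask = segment_clean(img)
        for lab in range(1, mask.n_objects + 1):
            o = measure_object(mask, lab)
            dists = sorted(
                float(d) for d in o.boundary_radii_um
            )
            n = len(dists)
            med = dists[n // 2] if n % 2 else 0.5 * (dists[n // 2 - 1] + dists[n // 2])
            expected = (med * dists[0] / dists[-1] ** 2) ** (1.0 / 3.0)
            assert o.shape_roughness == pytest.approx(expected, abs=1e-9)

    def test_unknown_label_raises(self, disk_image):
        img, _ = disk_image
        with pytest.raises(KeyError):
            measure_object(segment_clean(img), 99)


class TestScaleAndRotationInvariance:
    def test_shape_descriptors_calibration_invariant(self, disk_image):
        img, _ = disk_image
        mask = segment_clean(img)
        o1 = measure_object(mask, 1, pixel_area_um2=2.971)
        o2 = measure_object(mask, 1, pixel_area_um2=11.5)
        for f in ("elongation", "circularity", "shape_roughness"):
            assert getattr(o1, f) == pytest.approx(getattr(o2, f), abs=1e-9)
        assert o2.area_um2 == pytest.approx(o1.area_um2 * 11.5 / 2.971)

    def test_rotation_robustness_of_descriptors(self):
        from bonepore.synth import _radial_profile

        vals = []
        for phi in np.linspace(0.0, np.pi, 7):
            R = 45
            rows, cols = np.mgrid[-R : R + 1, -R : R + 1]
            rb = _radial_profile(
                np.arctan2(cols, rows), 40.0, 20.0, phi, 0.0, np.zeros(6), np.zeros(6)
            )
            arr = np.full((2 * R + 21, 2 * R + 21), 200, dtype=np.uint8)
            arr[10 : 10 + 2 * R + 1, 10 : 10 + 2 * R + 1][np.hypot(rows, cols) <= rb] = 30
            o = measure_slice(threshold_segment(CalibratedImage(arr), 100)).objects[0]
            vals.append((o.elongation, o.circularity, o.shape_roughness))
        v = np.array(vals)
        assert np.all((v.max(axis=0) - v.min(axis=0)) / v.mean(axis=0) < 0.03)


class TestRoughnessMonotonicity:
    def test_sr_decreases_and_c_increases_with_roughness(self):
        mean_sr, mean_c = [], []
        for amp in (0.0, 0.1, 0.2, 0.3):
            srs, cs = [], []
            for seed in range(4):
                spec = bp.SyntheticImageSpec(
                    width_px=400, height_px=400, n_objects=6,
                    axis_length_range_px=(20, 30), axis_ratio_range=(1, 1.5),
                    roughness_amplitude=amp, seed=seed,
                )
                img, _ = bp.generate_pore_image(spec)
                for o in measure_slice(segment_clean(img)).objects:
                    srs.append(o.shape_roughness)
                    cs.append(o.circularity)
            mean_sr.append(np.mean(srs))
            mean_c.append(np.mean(cs))
        assert all(a > b for a, b in zip(mean_sr, mean_sr[1:]))
        assert all(a < b for a, b in zip(mean_c, mean_c[1:]))


class TestMeasureSlice:
    def test_empty_mask(self):
        mask = threshold_segment(CalibratedImage(np.full((32, 32), 128, np.uint8)), 50)
        m = measure_slice(mask)
        assert m.objects == [] and m.total_pore_fraction == 0.0

    @pytest.mark.parametrize("cal", [1.0, 2.971])
    def test_pore_fraction_is_calibration_free(self, cal):
        arr = np.full((100, 100), 200, dtype=np.uint8)
        arr[40:50, 40:50] = 10
        m = measure_slice(threshold_segment(CalibratedImage(arr, cal), 50))
        assert m.total_pore_fraction == pytest.approx(0.01)

    def test_pore_fraction_matches_truth(self):
        spec = bp.SyntheticImageSpec(
            width_px=400, height_px=400, n_objects=10,
            axis_length_range_px=(12, 24), axis_ratio_range=(1, 1.5), seed=2,
        )
        img, truth = bp.generate_pore_image(spec)
        m = measure_slice(segment_clean(img))
        true_frac = sum(t.true_area_um2 for t in truth) / (400 * 400 * spec.pixel_area_um2)
        assert m.total_pore_fraction == pytest.approx(true_frac, rel=0.02)

    def test_histograms_rel_freq_sum_to_one_with_stated_bins(self, disk_image):
        img, _ = disk_image
        m = measure_slice(segment_clean(img))
        spec = HistogramSpec()
        assert spec.bin_width["area_um2"] == 60.0
        assert spec.bin_width["elongation"] == 0.1
        assert spec.bin_width["circularity"] == 0.02
        assert spec.bin_width["shape_roughness"] == 0.02
        for desc, (edges, counts, rel) in m.histograms.items():
            assert rel.sum() == pytest.approx(1.0, abs=1e-12)
            w = spec.bin_width[desc]
            assert np.allclose(np.diff(edges), w)
            assert edges[0] == spec.origin[desc]


class TestSummarizeGroups:
    def _slice_with_areas(self, areas):
        objs = [
            bp.PoreObject(
                label=i + 1, pixel_count=1, area_um2=a, perimeter_um=1.0,
                centroid=(0.0, 0.0), elongation=1.0, circularity=0.0,
                shape_roughness=1.0, boundary_radii_um=np.array([1.0]),
            )
            for i, a in enumerate(areas)
        ]
        return bp.SliceMorphometry(objs, 1e4, sum(areas) / 1e4, {})

    def test_two_point_statistics(self):
        df = summarize_groups([(self._slice_with_areas([100.0, 300.0]), "AM", "F")])
        assert df.loc[0, "area_um2_mean"] == 200.0
        assert df.loc[0, "area_um2_sd"] == pytest.approx(141.42, abs=0.01)
        assert df.loc[0, "n_objects"] == 2

    def test_identical_groups_identical_rows(self):
        s = self._slice_with_areas([50.0, 150.0, 250.0])
        df = summarize_groups([(s, "AM", "F"), (s, "PL", "F")])
        cols = [c for c in df.columns if c not in ("histology", "treatment")]
        assert df.loc[0, cols].equals(df.loc[1, cols])

    def test_pooled_mean_equals_concatenated_mean(self):
        s1 = self._slice_with_areas([10.0, 30.0])
        s2 = self._slice_with_areas([20.0, 40.0, 60.0])
        df = summarize_groups([(s1, "AM", "C"), (s2, "AM", "C")])
        assert df.loc[0, "area_um2_mean"] == pytest.approx(
            np.mean([10.0, 30.0, 20.0, 40.0, 60.0])
        )

    def test_missing_group_warns(self):
        with pytest.warns(UserWarning, match="no slices"):
            summarize_groups(
                [
                    (self._slice_with_areas([1.0]), "AM", "F"),
                    (self._slice_with_areas([1.0]), "PL", "C"),
                ]
            )


class TestGroundTruthRecovery:
    def test_protocol_recovers_truth_under_noise(self, recovery_image_spec):
        """Full pipeline on two noisy, unevenly lit fields: every pore is
        found and its area/elongation match the analytic ground truth."""
        for seed in (0, 1):
            img, truth = bp.generate_pore_image(recovery_image_spec(seed))
            m = measure_slice(bp.run_protocol(img))
            pairs = match_objects(truth, m.objects)
            assert len(pairs) == len(truth)
            for t, o in pairs:
                assert abs(o.area_um2 - t.true_area_um2) / t.true_area_um2 < 0.02
                assert abs(o.elongation - t.true_elongation) / t.true_elongation < 0.05
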