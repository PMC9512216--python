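import numpy as np
import pytest

from plumetrack import (
    ExtentSeries,
    ViewCalibration,
    align_to_task_end,
    calibrate_view,
    extract_extents,
    merge_views,
    segment_cloud,
)
from plumetrack.geometry import load_extents_csv, save_extents_csv
from plumetrack.segmentation import CloudMask


def cloud_from_mask(mask: np.ndarray, view_id: str = "C1_side") -> CloudMask:
    stack = mask[None] if mask.ndim == 2 else mask
    return CloudMask(
        masks=stack.astype(bool),
        threshold_used=np.full(len(stack), 128.0),
        min_component_area_px=0,
        fps=25.0,
        view_id=view_id,
        task_end_frame=0,
    )


class TestCalibrateView:
    def test_single_horizontal_bar(self):
        # horizontal bar 100 px long, 1.0 m known length -> 0.01 m/px
        cal = calibrate_view(
            [((5, 10), (5, 110), 1.0), ((0, 5), (100, 5), 2.0)], "C1_side", (50, 50)
        )
        assert cal.metres_per_pixel_h == pytest.approx(0.01)
        assert cal.metres_per_pixel_v == pytest.approx(0.02)

    def test_two_horizontal_bars_averaged(self):
        bars = [
            ((5, 0), (5, 100), 1.0),   # 0.010 m/px
            ((8, 0), (8, 100), 1.2),   # 0.012 m/px
            ((0, 5), (100, 5), 1.0),   # vertical
        ]
        cal = calibrate_view(bars, "C1_side", (50, 50))
        assert cal.metres_per_pixel_h == pytest.approx(0.011)

    def test_oblique_bar_ignored(self):
        bars = [
            ((0, 0), (50, 50), 1.0),  # 45 degrees: unusable
            ((5, 0), (5, 100), 1.0),
            ((0, 5), (100, 5), 1.0),
        ]
        cal = calibrate_view(bars, "C1_side", (50, 50))
        assert cal.metres_per_pixel_h == pytest.approx(0.01)

    def test_missing_axis_errors(self):
        with pytest.raises(ValueError, match="no usable scale bar"):
            calibrate_view([((5, 10), (5, 110), 1.0)], "C1_side", (50, 50))

    def test_zero_length_bar_errors(self):
        with pytest.raises(ValueError, match="coincident"):
            calibrate_view([((5, 10), (5, 10), 1.0)], "C1_side", (50, 50))

    def test_roundtrip_from_scenario_bars(self, small_scenario):
        for view, origin in (
            ("C1_side", small_scenario.side_origin_px),
            ("C3_top", small_scenario.top_origin_px),
        ):
            cal = calibrate_view(small_scenario.scale_bars(view), view, origin)
            assert cal.metres_per_pixel_h == pytest.approx(
                small_scenario.metres_per_pixel
            )
            assert cal.metres_per_pixel_v == pytest.approx(
                small_scenario.metres_per_pixel
            )


class TestExtractExtents:
    def test_empty_masks_zero_series(self):
        cal = ViewCalibration("C1_side", 0.01, 0.01, (50, 50))
        series = extract_extents(cloud_from_mask(np.zeros((100, 100), bool)), cal)
        assert np.all(series.x_front == 0)
        assert np.all(series.z_up == 0)

    def test_x_front_arithmetic(self):
        # blob spanning cols [origin+10, origin+110] at m/px 0.01 -> 1.10 m
        mask = np.zeros((200, 200), bool)
        mask[50, 60:161] = True
        cal = ViewCalibration("C1_side", 0.01, 0.01, (50, 50))
        series = extract_extents(cloud_from_mask(mask), cal)
        assert series.x_front[0] == pytest.approx(1.10)

    def test_y_diameter_arithmetic(self):
        # top-view blob spanning rows 40..139 -> inclusive span 100 px -> 1.00 m
        mask = np.zeros((200, 200), bool)
        mask[40:140, 80] = True
        cal = ViewCalibration("C3_top", 0.01, 0.01, (100, 50))
        series = extract_extents(cloud_from_mask(mask, "C3_top"), cal)
        assert series.y_diameter[0] == pytest.approx(1.00)

    def test_pixels_behind_mouth_clamped(self):
        mask = np.zeros((100, 100), bool)
        mask[50, 10:40] = True  # entirely behind the origin column
        cal = ViewCalibration("C1_side", 0.01, 0.01, (50, 60))
        series = extract_extents(cloud_from_mask(mask), cal)
        assert series.x_front[0] == 0.0

    def test_z_directions(self):
        mask = np.zeros((100, 100), bool)
        mask[30:81, 60] = True  # rows 30..80 around origin row 50
        cal = ViewCalibration("C1_side", 0.01, 0.02, (50, 50))
        series = extract_extents(cloud_from_mask(mask), cal)
        assert series.z_up[0] == pytest.approx(20 * 0.02)
        assert series.z_down[0] == pytest.approx(30 * 0.02)

    def test_view_mismatch_errors(self):
        cal = ViewCalibration("C3_top", 0.01, 0.01, (50, 50))
        with pytest.raises(ValueError, match="view"):
            extract_extents(cloud_from_mask(np.zeros((100, 100), bool)), cal)

    def test_scaling_covariance(self):
        mask = np.zeros((100, 100), bool)
        mask[40:61, 50:81] = True
        c1 = ViewCalibration("C1_side", 0.01, 0.01, (50, 50))
        c2 = ViewCalibration("C1_side", 0.02, 0.02, (50, 50))
        s1 = extract_extents(cloud_from_mask(mask), c1)
        s2 = extract_extents(cloud_from_mask(mask), c2)
        assert s2.x_front[0] == pytest.approx(2 * s1.x_front[0])
        assert s2.z_up[0] == pytest.approx(2 * s1.z_up[0])

    def test_origin_translation(self):
        mask = np.zeros((100, 100), bool)
        mask[50, 50:91] = True
        base = extract_extents(
            cloud_from_mask(mask), ViewCalibration("C1_side", 0.01, 0.01, (50, 40))
        )
        shifted = extract_extents(
            cloud_from_mask(mask), ViewCalibration("C1_side", 0.01, 0.01, (50, 45))
        )
        assert base.x_front[0] - shifted.x_front[0] == pytest.approx(5 * 0.01)


class TestAlign:
    def make_series(self, n=451, fps=25.0):
        return ExtentSeries(
            time_s=np.arange(n) / fps, fps=fps, x_front=np.zeros(n)
        )

    def test_paper_style_timing(self):
        s = align_to_task_end(self.make_series(), 200)
        assert s.time_s[0] == pytest.approx(-8.0)
        assert s.time_s[200] == pytest.approx(0.0)
        assert s.time_s[450] == pytest.approx(10.0)

    def test_task_end_zero(self):
        s = align_to_task_end(self.make_series(10), 0)
        assert np.all(s.time_s >= 0)

    def test_idempotent(self):
        s1 = align_to_task_end(self.make_series(), 100)
        s2 = align_to_task_end(s1, 100)
        assert np.array_equal(s1.time_s, s2.time_s)
        assert np.array_equal(s1.x_front, s2.x_front)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            align_to_task_end(self.make_series(10), 10)


class TestMergeViews:
    def make(self, n, fps=25.0, **fields):
        return ExtentSeries(time_s=np.arange(n) / fps, fps=fps, **fields)

    def test_identical_axes_concatenates_fields(self):
        side = self.make(10, x_front=np.ones(10), z_up=np.ones(10), z_down=np.zeros(10))
        top = self.make(10, y_diameter=np.full(10, 2.0))
        merged = merge_views(side, top)
        assert np.all(merged.x_front == 1.0)
        assert np.all(merged.y_diameter == 2.0)
        assert len(merged) == 10

    def test_shorter_top_view_trims(self):
        side = self.make(10, x_front=np.arange(10.0))
        top = self.make(5, y_diameter=np.ones(5))
        merged = merge_views(side, top)
        assert len(merged) == 5
        assert merged.x_front[-1] == 4.0

    def test_missing_top_view_leaves_y_absent(self):
        side = self.make(10, x_front=np.ones(10))
        merged = merge_views(side, None)
        assert merged.y_diameter is None
        assert merged.x_front is not None

    def test_fps_mismatch_errors(self):
        side = self.make(10, fps=25.0, x_front=np.ones(10))
        top = self.make(10, fps=30.0, y_diameter=np.ones(10))
        with pytest.raises(ValueError, match="fps"):
            merge_views(side, top)


class TestSeriesValidation:
    def test_negative_extents_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ExtentSeries(time_s=np.arange(3) / 25.0, fps=25.0, x_front=[-1, 0, 0])

    def test_nonuniform_time_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            ExtentSeries(time_s=[0.0, 0.04, 0.1], fps=25.0)

    def test_value_at_out_of_range(self):
        s = ExtentSeries(time_s=np.arange(5) / 25.0, fps=25.0, x_front=np.ones(5))
        with pytest.raises(ValueError, match="outside"):
            s.value_at("x_front", 3.0)


def test_extents_csv_roundtrip(tmp_path):
    series = [
        ExtentSeries(
            time_s=np.arange(6) / 25.0 - 0.08,
            fps=25.0,
            x_front=np.linspace(0, 1, 6),
            z_up=np.linspace(0, 0.5, 6),
            subject_id="S1",
            task_id="T2",
        ),
        ExtentSeries(
            time_s=np.arange(6) / 25.0,
            fps=25.0,
            y_diameter=np.linspace(0, 2, 6),
            subject_id="S2",
            task_id="T2",
        ),
    ]
    path = tmp_path / "extents.csv"
    save_extents_csv(series, path)
    loaded = {(s.subject_id, s.task_id): s for s in load_extents_csv(path)}
    s1 = loaded[("S1", "T2")]
    assert np.allclose(s1.x_front, series[0].x_front)
    assert s1.y_diameter is None
    s2 = loaded[("S2", "T2")]
    assert np.allclose(s2.y_diameter, series[1].y_diameter)
    assert s2.x_front is None
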