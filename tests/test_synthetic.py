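import numpy as np
import pytest

import epidtrack as et
from epidtrack.errors import ParameterError
from epidtrack.synthetic import save_series


class TestRenderSeries:
    def test_same_seed_bit_identical(self, geometry_512):
        cfg = et.default_scene(n_frames=3, noise_sd=0.03, seed=99)
        a, _ = et.render_series(cfg, geometry_512)
        b, _ = et.render_series(cfg, geometry_512)
        for ia, ib in zip(a, b):
            assert np.array_equal(ia.pixels, ib.pixels)

    def test_groundtruth_com_is_marker_mean(self, geometry_512):
        cfg = et.default_scene(n_frames=4, tracking_offset=(0.3, 0.2))
        _, truth = et.render_series(cfg, geometry_512)
        np.testing.assert_allclose(truth.com_px, truth.marker_px.mean(axis=1))

    def test_21_frames_cover_one_and_a_half_periods(self, geometry_512):
        cfg = et.default_scene(n_frames=21)
        imgs, truth = et.render_series(cfg, geometry_512)
        assert len(imgs) == 21
        assert truth.times_s[-1] == pytest.approx(10.0)  # one 6 BPM period
        assert cfg.motion.period_s == 10.0
        # motion returns to its start value after exactly one period
        assert truth.motion_mm[20, 1] == pytest.approx(truth.motion_mm[0, 1], abs=1e-9)

    def test_marker_leaving_aperture_is_config_error(self, geometry_512):
        cfg = et.default_scene(n_frames=2, tracking_offset=(0.0, 9.0))
        with pytest.raises(ParameterError):
            et.render_series(cfg, geometry_512)

    def test_occlusion_mode_allows_clipping(self, geometry_512):
        cfg = et.default_scene(
            n_frames=2, tracking_offset=(0.0, 9.0), occlusion_margin_mm=2.0
        )
        imgs, _ = et.render_series(cfg, geometry_512)  # must not raise
        assert len(imgs) == 2

    def test_pixel_range_and_polarity(self, geometry_512):
        cfg = et.default_scene(n_frames=1, noise_sd=0.05)
        (img,), truth = et.render_series(cfg, geometry_512)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0
        center = tuple(np.round(truth.aperture_center_px[0]).astype(int))
        corner = img.pixels[5, 5]
        assert img.pixels[center] < corner  # open field brighter (lower) than blocked

    def test_perfect_tracking_zero_error(self, geometry_512):
        cfg = et.default_scene(n_frames=5)  # tracking_offset None -> perfect
        imgs, _ = et.render_series(cfg, geometry_512)
        md = et.SeriesMetadata(geometry=geometry_512)
        series = et.analyze_series(imgs, md)
        assert all(o.included for o in series.offsets)
        assert np.nanmax(series.et_2d_mm) <= 0.5 * geometry_512.pixel_mm_at_iso


def _stretch(p):
    return (p - p.min()) / (p.max() - p.min())


class TestSeriesRoundtrip:
    def test_raw_save_and_read_back(self, tmp_path, geometry_512):
        cfg = et.default_scene(n_frames=2, seed=5)
        imgs, _ = et.render_series(cfg, geometry_512)
        save_series(imgs, tmp_path, fmt="raw")
        md = et.SeriesMetadata(geometry=geometry_512)
        back = et.read_image_series(tmp_path, md)
        assert len(back) == 2
        for orig, rb in zip(imgs, back):
            # read-back equals the min-max-normalized scene within quantization
            assert np.abs(_stretch(orig.pixels) - rb.pixels).max() <= 1.0 / 65535 + 1e-9

    def test_tiff_save_and_read_back(self, tmp_path, geometry_512):
        cfg = et.default_scene(n_frames=1, seed=6)
        imgs, _ = et.render_series(cfg, geometry_512)
        save_series(imgs, tmp_path, fmt="tiff")
        md = et.SeriesMetadata(geometry=geometry_512)
        back = et.read_image_series(tmp_path, md)
        assert np.abs(_stretch(imgs[0].pixels) - back[0].pixels).max() <= 1.0 / 65535 + 1e-9

    def test_pipeline_invariant_to_storage_roundtrip(self, tmp_path, geometry_512):
        """Offsets measured on read-back frames match those on the originals:
        the analysis is invariant to the writer's affine contrast stretch."""
        cfg = et.default_scene(n_frames=3, seed=7, tracking_offset=(0.4, -0.3))
        imgs, _ = et.render_series(cfg, geometry_512)
        save_series(imgs, tmp_path, fmt="raw")
        md = et.SeriesMetadata(geometry=geometry_512)
        back = et.read_image_series(tmp_path, md)
        a = et.analyze_series(imgs, md)
        b = et.analyze_series(back, md)
        for oa, ob in zip(a.offsets, b.offsets):
            assert ob.included
            assert ob.pan_mm == pytest.approx(oa.pan_mm, abs=5e-3)
            assert ob.tilt_mm == pytest.approx(oa.tilt_mm, abs=5e-3)


class TestMakePopulation:
    def test_requires_two_patients(self):
        with pytest.raises(ParameterError):
            et.make_population([(0.0, 0.3)])

    def test_field_layout_and_determinism(self):
        models = [(0.1, 0.3), (-0.2, 0.4)]
        fields = et.make_population(models, n_fields=2, n_frames=3, seed=1)
        assert len(fields) == 4
        assert {f.patient_id for f in fields} == {"P01", "P02"}
        again = et.make_population(models, n_fields=2, n_frames=3, seed=1)
        np.testing.assert_array_equal(
            fields[0].config.tracking_offset, again[0].config.tracking_offset
        )
        # distinct fields draw distinct offsets
        assert not np.array_equal(
            fields[0].config.tracking_offset, fields[1].config.tracking_offset
        )

    def test_single_frame_fields_fail_downstream(self):
        fields = et.make_population([(0.0, 0.2), (0.0, 0.2)], n_fields=1, n_frames=1, seed=2)
        imgs, _ = fields[0].render()
        series = et.analyze_series(imgs, fields[0].metadata)
        from epidtrack.errors import InsufficientDataError

        with pytest.raises(InsufficientDataError):
            et.field_stats(series)
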