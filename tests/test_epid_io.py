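import numpy as np
import pytest

import epidtrack as et
from epidtrack.epid_io import normalize_counts, write_raw_frame
from epidtrack.errors import (
    DegenerateImageError,
    FormatError,
    InconsistencyError,
    NoFramesError,
)


def _random_image(rng, n=64):
    """Random frame spanning the full [0, 1] grayscale (so the reader's
    per-frame min-max normalization is the identity)."""
    px = rng.random((n, n))
    px[0, 0], px[0, 1] = 0.0, 1.0
    return et.EpidImage(px)


class TestRawFrames:
    def test_write_read_roundtrip_within_quantization(self, tmp_path):
        rng = np.random.default_rng(0)
        img = _random_image(rng)
        path = tmp_path / "frame.raw"
        write_raw_frame(img, path)
        back = et.read_raw_frame(path, matrix_size=64)
        assert np.abs(back.pixels - img.pixels).max() <= 1.0 / 65535 + 1e-12

    def test_roundtrip_8bit_with_header(self, tmp_path):
        rng = np.random.default_rng(1)
        dialect = et.RawDialect(bytes_per_pixel=1, header_bytes=128)
        img = _random_image(rng)
        path = tmp_path / "frame.raw"
        write_raw_frame(img, path, dialect)
        back = et.read_raw_frame(path, dialect, matrix_size=64)
        assert np.abs(back.pixels - img.pixels).max() <= 1.0 / 255 + 1e-12

    def test_constant_frame_is_degenerate(self, tmp_path):
        path = tmp_path / "flat.raw"
        path.write_bytes(np.full(64 * 64, 777, dtype="<u2").tobytes())
        with pytest.raises(DegenerateImageError):
            et.read_raw_frame(path, matrix_size=64)

    def test_size_mismatch_names_byte_counts(self, tmp_path):
        path = tmp_path / "short.raw"
        path.write_bytes(b"\x00" * 100)
        with pytest.raises(FormatError, match="8192.*100"):
            et.read_raw_frame(path, matrix_size=64)

    def test_minmax_midpoint_before_inversion(self):
        counts = np.array([[100, 600], [1100, 100]])
        norm = normalize_counts(counts, invert=False)
        assert norm[0, 1] == pytest.approx(0.5)
        # polarity flip: high counts (open beam) -> 0 (white)
        assert normalize_counts(counts, invert=True)[1, 0] == 0.0

    @pytest.mark.parametrize("scale", [0.5, 3.0, 1000.0])
    def test_normalization_is_scale_invariant(self, scale):
        rng = np.random.default_rng(2)
        counts = rng.integers(50, 4000, size=(32, 32)).astype(float)
        np.testing.assert_allclose(
            normalize_counts(counts), normalize_counts(counts * scale), atol=1e-12
        )


class TestSeries:
    def _write_series(self, tmp_path, n, size=64, seed=0):
        rng = np.random.default_rng(seed)
        paths = []
        for i in range(n):
            img = et.EpidImage(rng.random((size, size)))
            p = tmp_path / f"frame_{i:03d}.raw"
            write_raw_frame(img, p)
            paths.append(p)
        return paths

    def test_timestamps_at_2hz(self, tmp_path):
        self._write_series(tmp_path, 21)
        md = et.SeriesMetadata(geometry=et.GeometryConfig(matrix_size=64))
        series = et.read_image_series(tmp_path, md)
        assert len(series) == 21
        times = [img.time_s for img in series]
        np.testing.assert_allclose(times, np.arange(21) * 0.5)
        assert [img.index for img in series] == list(range(1, 22))
        # consecutive frame spacing is exactly 1/frame_rate
        assert np.all(np.diff(times) == 0.5)

    def test_single_frame(self, tmp_path):
        self._write_series(tmp_path, 1)
        md = et.SeriesMetadata(geometry=et.GeometryConfig(matrix_size=64))
        series = et.read_image_series(tmp_path, md)
        assert len(series) == 1 and series[0].time_s == 0.0

    def test_manifest_order_is_authoritative(self, tmp_path):
        self._write_series(tmp_path, 3)
        manifest = tmp_path / "order.txt"
        manifest.write_text("frame_002.raw\nframe_000.raw\nframe_001.raw\n")
        md = et.SeriesMetadata(geometry=et.GeometryConfig(matrix_size=64))
        series = et.read_image_series(manifest, md)
        direct = et.read_image_series(tmp_path, md)
        np.testing.assert_allclose(series[0].pixels, direct[2].pixels)
        assert series[0].index == 1  # indices follow manifest order, not filenames

    def test_empty_directory(self, tmp_path):
        md = et.SeriesMetadata(geometry=et.GeometryConfig(matrix_size=64))
        with pytest.raises(NoFramesError):
            et.read_image_series(tmp_path, md)

    def test_mixed_dimensions_rejected(self, tmp_path):
        import tifffile

        rng = np.random.default_rng(3)
        tifffile.imwrite(tmp_path / "a.tif", rng.integers(0, 999, (64, 64)).astype("uint16"))
        tifffile.imwrite(tmp_path / "b.tif", rng.integers(0, 999, (32, 32)).astype("uint16"))
        md = et.SeriesMetadata(geometry=et.GeometryConfig(matrix_size=64))
        with pytest.raises(InconsistencyError):
            et.read_image_series(tmp_path, md)

    def test_corrupt_frame_flagged_not_fatal(self, tmp_path):
        self._write_series(tmp_path, 3)
        (tmp_path / "frame_001.raw").write_bytes(
            np.full(64 * 64, 5, dtype="<u2").tobytes()
        )  # constant -> degenerate
        md = et.SeriesMetadata(geometry=et.GeometryConfig(matrix_size=64))
        series = et.read_image_series(tmp_path, md, on_error="flag")
        assert [img.valid for img in series] == [True, False, True]


class TestOffsetsCsv:
    def _series(self):
        offsets = [
            et.FrameOffset(index=1, pan_mm=0.1, tilt_mm=-0.2, n_markers=3, time_s=0.0),
            et.FrameOffset(index=2, included=False, exclusion_reason="no_field", time_s=0.5),
            et.FrameOffset(index=3, pan_mm=0.43256, tilt_mm=0.11111, n_markers=3, time_s=1.0),
        ]
        return et.tracking_error_series(offsets)

    def test_roundtrip_three_decimals(self, tmp_path):
        from epidtrack.epid_io import read_offsets_csv

        series = self._series()
        path = tmp_path / "offsets.csv"
        et.write_offsets_csv(series, path)
        df = read_offsets_csv(path)
        assert len(df) == 3
        assert df.loc[2, "pan_mm"] == pytest.approx(0.43256, abs=5e-4)
        assert df.loc[2, "et_pan_mm"] == pytest.approx(abs(0.43256 - 0.1), abs=5e-4)

    def test_excluded_rows_have_empty_et_cells(self, tmp_path):
        series = self._series()
        path = tmp_path / "offsets.csv"
        et.write_offsets_csv(series, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 4  # header + 3 rows
        excluded_row = lines[2].split(",")
        header = lines[0].split(",")
        for col in ("et_pan_mm", "et_tilt_mm", "et_2d_mm", "pan_mm"):
            assert excluded_row[header.index(col)] == ""
        assert excluded_row[header.index("included")] == "False"
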