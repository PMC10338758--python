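import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import epidtrack as et
from epidtrack.errors import EmptySeriesError, InsufficientDataError
from epidtrack.tracking_analysis import (
    FrameOffset,
    field_stats,
    frame_offset,
    patient_stats,
    tracking_error_series,
)

GEO = et.GeometryConfig()


def _offsets(pairs, start_index=1):
    return [
        FrameOffset(index=i, pan_mm=p, tilt_mm=t, time_s=(i - 1) * 0.5)
        for i, (p, t) in enumerate(pairs, start=start_index)
    ]


class TestFrameOffset:
    def test_ten_pixels_is_1p8_mm(self):
        off = frame_offset((100.0, 100.0), (100.0, 110.0), GEO)
        assert off.pan_mm == pytest.approx(1.8)
        assert off.tilt_mm == pytest.approx(0.0)

    def test_coincident_points(self):
        off = frame_offset((55.5, 66.6), (55.5, 66.6), GEO)
        assert (off.pan_mm, off.tilt_mm) == (0.0, 0.0)

    def test_signed_axes(self):
        center = (200.0, 300.0)
        off = frame_offset(center, (center[0] - 5, center[1] + 5), GEO)
        assert off.pan_mm == pytest.approx(0.9)
        assert off.tilt_mm == pytest.approx(-0.9)


class TestTrackingErrorSeries:
    def test_constant_offsets_zero_error(self):
        series = tracking_error_series(_offsets([(0.4, -0.2)] * 5))
        assert np.allclose(series.et_pan_mm, 0) and np.allclose(series.et_2d_mm, 0)

    def test_three_four_five(self):
        series = tracking_error_series(_offsets([(0.0, 0.0), (0.3, -0.4)]))
        assert series.et_pan_mm[1] == pytest.approx(0.3)
        assert series.et_tilt_mm[1] == pytest.approx(0.4)
        assert series.et_2d_mm[1] == pytest.approx(0.5)

    def test_baseline_is_first_included(self):
        offs = [FrameOffset(index=1, included=False, exclusion_reason="no_markers")]
        offs += _offsets([(0.5, 0.5), (0.7, 0.5)], start_index=2)
        series = tracking_error_series(offs)
        assert series.baseline_index == 2
        assert np.isnan(series.et_pan_mm[0])
        assert series.et_pan_mm[1] == 0.0  # baseline zero
        assert series.et_pan_mm[2] == pytest.approx(0.2)

    def test_no_included_frames(self):
        with pytest.raises(EmptySeriesError):
            tracking_error_series(
                [FrameOffset(index=1, included=False, exclusion_reason="x")]
            )

    @settings(derandomize=True, max_examples=50)
    @given(
        pairs=st.lists(
            st.tuples(
                st.floats(-5, 5, allow_nan=False), st.floats(-5, 5, allow_nan=False)
            ),
            min_size=2,
            max_size=12,
        ),
        shift=st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
    )
    def test_invariance_to_constant_shift_and_triangle_bounds(self, pairs, shift):
        """Baseline subtraction removes any common offset; per-frame
        max(et_pan, et_tilt) <= et_2d <= et_pan + et_tilt always holds."""
        base = tracking_error_series(_offsets(pairs))
        shifted = tracking_error_series(
            _offsets([(p + shift[0], t + shift[1]) for p, t in pairs])
        )
        np.testing.assert_allclose(base.et_pan_mm, shifted.et_pan_mm, atol=1e-9)
        np.testing.assert_allclose(base.et_2d_mm, shifted.et_2d_mm, atol=1e-9)
        ep, tl, d2 = base.et_pan_mm, base.et_tilt_mm, base.et_2d_mm
        assert np.all(d2 >= np.maximum(ep, tl) - 1e-12)
        assert np.all(d2 <= ep + tl + 1e-12)


class TestFieldStats:
    def test_closed_form_examples(self):
        # E_T values {0, 1, 2, 3, 4} in pan via offsets 0..4 with zero tilt
        series = tracking_error_series(_offsets([(v, 0.0) for v in range(5)]))
        st_ = field_stats(series)
        assert st_.pan.mean_mm == pytest.approx(2.0)
        assert st_.pan.max_mm == pytest.approx(4.0)
        assert st_.d2.mean_mm == pytest.approx(2.0)
        assert st_.pan.p90_mm == pytest.approx(np.percentile([0, 1, 2, 3, 4], 90))
        assert st_.detection_rate == 1.0

    def test_baseline_zero_counted(self):
        c = 1.4
        series = tracking_error_series(_offsets([(0, 0), (c, 0), (c, 0), (c, 0)]))
        assert field_stats(series).pan.mean_mm == pytest.approx(3 * c / 4)

    def test_insufficient_frames(self):
        with pytest.raises(InsufficientDataError):
            field_stats(tracking_error_series(_offsets([(0.1, 0.2)])))

    def test_monte_carlo_matches_folded_normal(self):
        """With offsets ~ N(0, s), E_T pan given the realized baseline b is
        |N(-b, s)| — a folded normal whose closed-form mean/SD the sample
        statistics must match within 3 standard errors."""
        rng = np.random.default_rng(11)
        s, n = 0.5, 4000
        pan = rng.normal(0, s, size=n)
        series = tracking_error_series(_offsets([(p, 0.0) for p in pan]))
        b = pan[0]
        mu = sps.foldnorm.mean(abs(b) / s, scale=s)
        sd = sps.foldnorm.std(abs(b) / s, scale=s)
        vals = series.included_et("pan")[1:]  # baseline zero is not a draw
        assert abs(vals.mean() - mu) < 3 * sd / np.sqrt(n - 1)
        assert abs(vals.std(ddof=1) - sd) < 3 * sd / np.sqrt(2 * (n - 2))


class TestPatientStats:
    def test_single_field_equals_field_stats(self):
        series = tracking_error_series(_offsets([(v / 10, 0.0) for v in range(6)]))
        fs, ps = field_stats(series), patient_stats([series])
        assert ps.pan.mean_mm == pytest.approx(fs.pan.mean_mm)
        assert ps.pan.sd_mm == pytest.approx(fs.pan.sd_mm)

    def test_identical_fields_share_mean(self):
        series = tracking_error_series(_offsets([(v / 10, 0.0) for v in range(6)]))
        ps = patient_stats([series, series])
        assert ps.pan.mean_mm == pytest.approx(field_stats(series).pan.mean_mm)
        assert ps.n_analyzed == 12

    def test_pooling_matches_concatenation_oracle(self):
        rng = np.random.default_rng(12)
        fields = [
            tracking_error_series(
                _offsets([(p, t) for p, t in rng.normal(0, 0.5, size=(m, 2))])
            )
            for m in (5, 9, 14)
        ]
        ps = patient_stats(fields)
        pool = np.concatenate([f.included_et("2d") for f in fields])
        assert ps.d2.mean_mm == pytest.approx(pool.mean())
        assert ps.d2.sd_mm == pytest.approx(pool.std(ddof=1))

    def test_zero_frames_error(self):
        with pytest.raises(InsufficientDataError):
            patient_stats([])
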