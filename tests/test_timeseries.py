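"""Preprocessing: I/O, resampling, gap filling, smoothing, alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from headgait.errors import (
    AlignmentError,
    FormatError,
    InputError,
    InsufficientDataError,
    TrialExcludedError,
)
from headgait.timeseries import (
    TrialPair,
    align_by_xcorr,
    derivative,
    detrend_offset,
    fill_missing_cubic,
    read_pose_csv,
    resample_linear,
    smooth_savgol,
    write_pose_csv,
)

from conftest import make_series


class TestReadPoseCSV:
    def test_basic_parse_infers_rate(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("t,x,y,z,yaw\n0,0,0,1.5,0\n0.02,0.1,0,1.5,1\n0.04,0.2,0,1.5,2\n")
        s = read_pose_csv(p)
        assert len(s) == 3
        assert s.rate == pytest.approx(50.0)
        assert not s.missing_mask.any()

    def test_blank_cell_sets_missing_mask(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("t,x,y,z,yaw\n0,0,0,1.5,0\n0.02,0.1,0,,1\n0.04,0.2,0,1.5,2\n")
        s = read_pose_csv(p)
        assert list(s.missing_mask) == [False, True, False]

    def test_missing_column_is_format_error(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("t,x,y,z\n0,0,0,1.5\n0.02,0,0,1.5\n")
        with pytest.raises(FormatError):
            read_pose_csv(p)

    def test_too_few_rows(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("t,x,y,z,yaw\n0,0,0,1.5,0\n")
        with pytest.raises(InsufficientDataError):
            read_pose_csv(p)

    def test_yaw_unwrapped_on_read(self, tmp_path):
        p = tmp_path / "a.csv"
        rows = "\n".join(f"{i*0.02},0,0,1.5,{((170 + 5*i) + 180) % 360 - 180}"
                         for i in range(10))
        p.write_text("t,x,y,z,yaw\n" + rows + "\n")
        s = read_pose_csv(p)
        assert np.all(np.diff(s.yaw) > 0)  # continuous through the +/-180 wrap

    def test_roundtrip_write_read(self, tmp_path):
        t = np.arange(0, 1, 0.02)
        s = make_series(t, z=1.5 + 0.01 * np.sin(t), yaw=10 * t)
        s.missing_mask[5] = True
        p = tmp_path / "rt.csv"
        write_pose_csv(s, p)
        s2 = read_pose_csv(p)
        assert list(s2.missing_mask) == list(s.missing_mask)
        ok = ~s.missing_mask
        np.testing.assert_allclose(s2.x[ok], s.x[ok], atol=1e-8)
        np.testing.assert_allclose(s2.z[ok], s.z[ok], atol=1e-8)


class TestResampleLinear:
    def test_linear_signal_exact(self):
        t = np.arange(0, 2, 0.01)  # 100 Hz
        s = make_series(t, x=t.copy(), rate=100.0)
        r = resample_linear(s, 50.0)
        np.testing.assert_allclose(r.x, r.t, atol=1e-12)
        assert np.allclose(np.diff(r.t), 0.02, atol=1e-9)

    def test_constant_channel_preserved(self):
        t = np.arange(0, 2, 1 / 60)
        s = make_series(t, z=np.full_like(t, 1.5), rate=60.0)
        r = resample_linear(s, 50.0)
        np.testing.assert_allclose(r.z, 1.5, atol=1e-12)

    @pytest.mark.parametrize("src_rate", [100.0, 90.0])
    def test_sine_within_interpolation_bound(self, src_rate):
        # linear interpolation of sin(2*pi*t): error below (2*pi)^2/(2*rate^2)/2
        t = np.arange(0, 3, 1 / src_rate)
        s = make_series(t, z=np.sin(2 * np.pi * t), rate=src_rate)
        r = resample_linear(s, 50.0)
        bound = (2 * np.pi) ** 2 / (2 * src_rate ** 2) / 2
        assert np.max(np.abs(r.z - np.sin(2 * np.pi * r.t))) < bound

    def test_non_increasing_time_rejected(self):
        s = make_series([0.0, 0.02, 0.02, 0.06])
        with pytest.raises(InputError):
            resample_linear(s, 50.0)

    def test_mask_propagates_to_bracketing_outputs(self):
        t = np.arange(0, 1, 0.01)
        mask = np.zeros(len(t), dtype=bool)
        mask[30] = True
        s = make_series(t, rate=100.0, mask=mask)
        r = resample_linear(s, 50.0)
        # output frame at 0.30 s coincides with the masked input sample
        assert r.missing_mask[15]

    def test_idempotent_at_same_rate(self):
        t = np.arange(0, 2, 0.02)
        s = make_series(t, z=np.sin(t), rate=50.0)
        r1 = resample_linear(s, 50.0)
        r2 = resample_linear(r1, 50.0)
        np.testing.assert_array_equal(r1.t, r2.t)
        np.testing.assert_allclose(r1.z, r2.z, atol=1e-12)


class TestFillMissingCubic:
    def test_no_missing_is_identity(self):
        t = np.arange(0, 1, 0.02)
        s = make_series(t, z=np.sin(t))
        out = fill_missing_cubic(s)
        np.testing.assert_array_equal(out.z, s.z)

    def test_interior_cubic_recovered_exactly(self):
        t = np.linspace(0, 1, 51)
        z = t ** 3
        mask = np.zeros(51, dtype=bool)
        mask[20:25] = True
        zm = z.copy()
        zm[mask] = np.nan
        s = make_series(t, z=zm, mask=mask)
        out = fill_missing_cubic(s)
        np.testing.assert_allclose(out.z, t ** 3, atol=1e-9)

    def test_exclusion_over_ten_percent(self):
        t = np.arange(0, 2, 0.02)
        mask = np.zeros(len(t), dtype=bool)
        mask[: int(0.11 * len(t))] = True
        s = make_series(t, mask=mask)
        with pytest.raises(TrialExcludedError) as exc:
            fill_missing_cubic(s)
        assert exc.value.missing_frac == pytest.approx(0.11, abs=0.005)

    def test_leading_missing_frames_trimmed_not_extrapolated(self):
        t = np.arange(0, 1, 0.02)
        mask = np.zeros(len(t), dtype=bool)
        mask[:3] = True
        s = make_series(t, z=np.sin(t), mask=mask)
        out = fill_missing_cubic(s)
        assert len(out) == len(s) - 3
        assert out.t[0] == pytest.approx(t[3])


class TestSmoothSavgol:
    def test_quadratic_invariant(self):
        t = np.arange(0, 4, 0.02)
        ch = 1.0 + 0.5 * t + 0.25 * t ** 2
        out = smooth_savgol(ch, 2, 61)
        np.testing.assert_allclose(out, ch, atol=1e-9)

    def test_constant_unchanged(self):
        out = smooth_savgol(np.full(200, 3.7), 2, 61)
        np.testing.assert_allclose(out, 3.7, atol=1e-12)

    def test_matches_per_window_least_squares_and_variance(self):
        from oracles import savgol_per_window
        rng = np.random.default_rng(7)
        noise = rng.normal(0, 1.0, 5000)
        out = smooth_savgol(noise, 2, 61)
        ref = savgol_per_window(noise, 2, 61)
        interior = ~np.isnan(ref)
        np.testing.assert_allclose(out[interior], ref[interior], atol=1e-9)
        # analytic variance factor for the centre tap of the (2, 61) filter
        from scipy.signal import savgol_coeffs
        factor = np.sum(savgol_coeffs(61, 2) ** 2)
        assert np.var(out[interior]) == pytest.approx(factor, rel=0.10)

    def test_too_short_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            smooth_savgol(np.zeros(30), 2, 61)

    def test_linearity(self):
        rng = np.random.default_rng(3)
        u, v = rng.normal(size=(2, 500))
        lhs = smooth_savgol(2.0 * u + 3.0 * v, 2, 61)
        rhs = 2.0 * smooth_savgol(u, 2, 61) + 3.0 * smooth_savgol(v, 2, 61)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestDetrendDerivative:
    @pytest.mark.parametrize("vec,expected", [
        ([1.0, 1.0, 1.0], [0.0, 0.0, 0.0]),
        ([0.0, 1.0, 2.0], [-1.0, 0.0, 1.0]),
    ])
    def test_detrend_examples(self, vec, expected):
        np.testing.assert_allclose(detrend_offset(vec), expected, atol=1e-12)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=100))
    @settings(deadline=None, max_examples=50)
    def test_detrend_zero_mean_and_idempotent(self, vec):
        out = detrend_offset(vec)
        scale = max(1.0, np.max(np.abs(vec)))
        assert abs(out.mean()) <= 1e-9 * scale
        np.testing.assert_allclose(detrend_offset(out), out, atol=1e-9 * scale)

    def test_derivative_ramp_and_constant(self):
        rate = 50.0
        ramp = np.arange(100) * (90.0 / rate)
        np.testing.assert_allclose(derivative(ramp, rate), 90.0, atol=1e-9)
        np.testing.assert_allclose(derivative(np.full(50, 2.0), rate), 0.0)

    def test_derivative_sine_within_truncation_bound(self):
        rate = 50.0
        t = np.arange(0, 4, 1 / rate)
        z = 0.02 * np.sin(2 * np.pi * 2 * t)
        vel = derivative(z, rate)
        truth = 0.08 * np.pi * np.cos(2 * np.pi * 2 * t)
        bound = 0.02 * (2 * np.pi * 2) ** 3 / (6 * rate ** 2)  # h^2 f'''/6
        assert np.max(np.abs(vel[1:-1] - truth[1:-1])) < bound * 1.01

    def test_derivative_needs_three_samples(self):
        with pytest.raises(InputError):
            derivative(np.array([1.0, 2.0]), 50.0)


class TestAlignByXcorr:
    def _pair(self, az, rz, rate=50.0):
        t = np.arange(len(az)) / rate
        return TrialPair(ar=make_series(t, z=az, rate=rate, source="ar"),
                         ref=make_series(t[:len(rz)], z=rz, rate=rate, source="ref"))

    def test_identical_series_zero_lag(self):
        t = np.arange(0, 20, 0.02)
        z = 1.5 + 0.05 * np.sin(2 * np.pi * 0.4 * t)
        p = align_by_xcorr(self._pair(z, z.copy()))
        assert p.lag_frames == 0

    def test_constructed_ten_frame_delay(self):
        t = np.arange(0, 20, 0.02)
        z = 1.5 + 0.05 * np.sin(2 * np.pi * 0.4 * t) + 0.02 * np.sin(2.1 * t)
        ref = np.roll(z, 10)  # reference delayed by 10 frames
        p = align_by_xcorr(self._pair(z, ref))
        assert p.lag_frames == 10
        np.testing.assert_allclose(p.ref.z, p.ar.z, atol=1e-6)

    @pytest.mark.parametrize("k", [-100, -37, 0, 55, 100])
    def test_exact_recovery_up_to_two_seconds(self, k):
        tt = np.arange(0, 40, 0.02)
        zfull = 1.5 + 0.05 * np.sin(2 * np.pi * 0.3 * tt) + 0.02 * np.sin(2.3 * tt)
        ar = zfull[250:1250]
        ref = zfull[250 - k:1250 - k]  # ref[i] = ar[i - k]: delayed by k frames
        p = align_by_xcorr(self._pair(ar, ref))
        assert p.lag_frames == k

    def test_noisy_recovery_within_one_frame(self):
        t = np.arange(0, 30, 0.02)
        z = 1.5 + 0.05 * np.sin(2 * np.pi * 0.3 * t) + 0.02 * np.sin(2.3 * t)
        sd = 0.10 * z.std()
        for seed in range(1, 11):
            rng = np.random.default_rng(seed)
            p = align_by_xcorr(self._pair(z + rng.normal(0, sd, len(z)),
                                          np.roll(z, 7) + rng.normal(0, sd, len(z))))
            assert abs(p.lag_frames - 7) <= 1

    def test_insufficient_overlap_raises(self):
        t = np.arange(0, 1.2, 0.02)
        z = np.sin(10 * t)
        pair = self._pair(z, z[:20])
        with pytest.raises(AlignmentError):
            align_by_xcorr(pair, max_lag_s=1.0)
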