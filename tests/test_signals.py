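"""Signal data model, file I/O and preprocessing primitives."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitphase.signals import (
    FilterKind,
    FilterSpec,
    FormatError,
    ImuRecording,
    SchemaError,
    Side,
    UniformSeries,
    apply_filter,
    moving_average,
    read_footswitch,
    read_imu,
    resample,
    sagittal_axis,
    write_footswitch,
    write_imu,
)


class TestIO:
    def test_rate_inferred_from_timestamps(self, tmp_path):
        t = np.arange(30) * 0.02
        path = tmp_path / "imu.csv"
        data = np.column_stack([t] + [np.sin(t + k) for k in range(6)])
        np.savetxt(path, data, delimiter=",",
                   header="time,gx,gy,gz,ax,ay,az", comments="")
        rec = read_imu(path)
        assert rec.rate == pytest.approx(50.0)
        assert len(rec) == 30

    def test_duplicated_timestamp_rejected(self, tmp_path):
        t = np.array([0.0, 0.02, 0.02, 0.04])
        path = tmp_path / "imu.csv"
        np.savetxt(path, np.column_stack([t] + [t] * 6), delimiter=",",
                   header="time,gx,gy,gz,ax,ay,az", comments="")
        with pytest.raises(FormatError):
            read_imu(path)

    def test_jittered_timestamps_rejected(self, tmp_path):
        t = np.arange(50) * 0.02
        t[25] += 0.005  # 25% of a sample step
        path = tmp_path / "imu.csv"
        np.savetxt(path, np.column_stack([t] + [t] * 6), delimiter=",",
                   header="time,gx,gy,gz,ax,ay,az", comments="")
        with pytest.raises(FormatError):
            read_imu(path)

    def test_missing_column_is_schema_error(self, tmp_path):
        path = tmp_path / "fsw.csv"
        path.write_text("time,heel,mt1,mt5\n0,0,0,0\n0.01,1,1,1\n")
        with pytest.raises(SchemaError):
            read_footswitch(path)

    def test_roundtrip_write_read(self, tmp_path, clean_trial):
        imu_path = tmp_path / "imu.csv"
        fsw_path = tmp_path / "fsw.csv"
        write_imu(imu_path, clean_trial.imu)
        write_footswitch(fsw_path, clean_trial.fsw)
        imu2 = read_imu(imu_path, side=clean_trial.imu.side)
        fsw2 = read_footswitch(fsw_path, side=clean_trial.fsw.side)
        np.testing.assert_allclose(imu2.gyro, clean_trial.imu.gyro, atol=1e-9)
        np.testing.assert_allclose(imu2.accel, clean_trial.imu.accel, atol=1e-9)
        np.testing.assert_allclose(fsw2.channels, clean_trial.fsw.channels,
                                   atol=1e-9)
        assert imu2.rate == pytest.approx(clean_trial.imu.rate, rel=1e-9)
        # JSON sidecars carry side and units
        assert (tmp_path / "imu.csv.json").exists()


class TestResample:
    def test_constant_series_any_rate(self):
        s = UniformSeries(np.ones(50), 50.0)
        out = resample(s, 200.0)
        assert out.rate == 200.0
        np.testing.assert_allclose(out.samples, 1.0)

    def test_hold_preserves_binary(self):
        rng = np.random.default_rng(0)
        s = UniformSeries((rng.random(2000) > 0.5).astype(float), 2000.0)
        out = resample(s, 200.0, mode="hold")
        assert set(np.unique(out.samples)) <= {0.0, 1.0}

    def test_sine_against_analytic_oracle(self):
        t = np.arange(0, 2.0, 1 / 50)
        s = UniformSeries(np.sin(2 * np.pi * 1.0 * t), 50.0)
        out = resample(s, 200.0)
        expected = np.sin(2 * np.pi * 1.0 * out.times)
        assert np.max(np.abs(out.samples - expected)) < 0.01

    def test_round_trip_band_limited(self):
        t = np.arange(0, 4.0, 1 / 50)
        x = np.sin(2 * np.pi * 2 * t) + 0.5 * np.cos(2 * np.pi * 5 * t)
        s = UniformSeries(x, 50.0)
        back = resample(resample(s, 200.0), 50.0)
        n = min(len(back), len(s))
        rms = np.sqrt(np.mean((back.samples[:n] - s.samples[:n]) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(s.samples ** 2))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            resample(UniformSeries(np.array([1.0]), 50.0), 200.0)


class TestFilters:
    def test_dc_unit_gain(self):
        s = UniformSeries(np.full(400, 3.7), 200.0)
        spec = FilterSpec(FilterKind.BUTTERWORTH_LOWPASS, cutoff_hz=15.0)
        np.testing.assert_allclose(apply_filter(s, spec).samples, 3.7,
                                   rtol=1e-6)

    def test_zero_phase_preserves_symmetric_pulse_peak(self):
        t = np.arange(400) / 200.0
        s = UniformSeries(np.exp(-0.5 * ((t - 1.0) / 0.05) ** 2), 200.0)
        out = apply_filter(s, FilterSpec(FilterKind.BUTTERWORTH_LOWPASS,
                                         cutoff_hz=10.0))
        assert np.argmax(out.samples) == np.argmax(s.samples)

    def test_stopband_attenuation(self):
        t = np.arange(2000) / 200.0
        s = UniformSeries(np.sin(2 * np.pi * 30.0 * t), 200.0)
        out = apply_filter(s, FilterSpec(FilterKind.BUTTERWORTH_LOWPASS,
                                         cutoff_hz=6.0))
        core = slice(200, -200)  # away from filtfilt edge transients
        atten = np.max(np.abs(out.samples[core]))
        assert atten < 10 ** (-20 / 20)  # >= 20 dB down

    def test_cutoff_above_nyquist_rejected(self):
        s = UniformSeries(np.zeros(100), 50.0)
        with pytest.raises(ValueError):
            apply_filter(s, FilterSpec(FilterKind.BUTTERWORTH_LOWPASS,
                                       cutoff_hz=30.0))

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1), st.floats(-5, 5), st.floats(-5, 5))
    def test_linearity(self, seed, a, b):
        """filter(a x + b y) == a filter(x) + b filter(y)."""
        rng = np.random.default_rng(seed)
        x = rng.normal(size=300)
        y = rng.normal(size=300)
        spec = FilterSpec(FilterKind.BUTTERWORTH_LOWPASS, cutoff_hz=15.0)
        f = lambda v: apply_filter(UniformSeries(v, 200.0), spec).samples
        np.testing.assert_allclose(f(a * x + b * y), a * f(x) + b * f(y),
                                   atol=1e-9 * (1 + abs(a) + abs(b)))


class TestMovingAverage:
    def test_constant_unchanged(self):
        s = UniformSeries(np.full(100, 2.5), 200.0)
        np.testing.assert_allclose(moving_average(s, 0.1).samples, 2.5)

    def test_impulse_plateau(self):
        x = np.zeros(101)
        x[50] = 1.0
        out = moving_average(UniformSeries(x, 1.0), 5.0)
        assert out.samples[50] == pytest.approx(1 / 5)
        np.testing.assert_allclose(out.samples[48:53], 1 / 5)

    def test_against_convolution_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=500)
        w = 25
        out = moving_average(UniformSeries(x, 100.0), w / 100.0).samples
        # direct truncated-window oracle
        expected = np.array([
            np.mean(x[max(0, i - w // 2):min(len(x), i - w // 2 + w)])
            for i in range(len(x))])
        np.testing.assert_allclose(out, expected, atol=1e-12)


def test_sagittal_axis_picks_max_variance():
    rng = np.random.default_rng(1)
    gyro = np.column_stack([rng.normal(0, 1, 500),
                            rng.normal(0, 50, 500),
                            rng.normal(0, 5, 500)])
    assert sagittal_axis(gyro) == 1


def test_imu_recording_validation():
    with pytest.raises(ValueError):
        ImuRecording(Side.LEFT, np.zeros((10, 2)), np.zeros((10, 3)), 50.0)
    with pytest.raises(ValueError):
        ImuRecording(Side.LEFT, np.full((10, 3), np.nan),
                     np.zeros((10, 3)), 50.0)
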