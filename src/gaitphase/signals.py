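"""Sensor-stream data model, delimited-text I/O, and shared preprocessing.

Internal unit conventions are fixed: angular velocity in deg/s, acceleration
in m/s**2, time in seconds.  The sign convention for the sagittal (pitch)
angular velocity is positive at the mid-swing peak, so heel strike and
toe off appear as negative troughs; opposite-handed sensors are handled by
``flip_sign`` at read time or in the detector configs.

All detectors operate on a common uniform evaluation grid (200 Hz by
default): analog channels are resampled with linear interpolation, binary
footswitch channels with a zero-order hold so they stay in {0, 1}.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

#: common evaluation grid used across detectors and evaluation
EVAL_RATE_HZ = 200.0

IMU_COLUMNS = ("time", "gx", "gy", "gz", "ax", "ay", "az")
FOOTSWITCH_COLUMNS = ("time", "heel", "mt1", "mt5", "toe")


class Side(enum.Enum):
    """Body side of a foot-worn sensor."""

    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly sampled scalar series.

    Parameters
    ----------
    samples : ndarray, shape (n,)
        Sample values; must be finite.
    rate : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("UniformSeries samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("UniformSeries samples must be finite")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate

    @property
    def duration(self) -> float:
        return (self.samples.size - 1) / self.rate if self.samples.size else 0.0

    def with_samples(self, samples: np.ndarray) -> "UniformSeries":
        return UniformSeries(np.asarray(samples, dtype=float), self.rate, self.t0)


@dataclass(frozen=True)
class ImuRecording:
    """Per-foot inertial recording: 3-axis gyroscope and accelerometer.

    ``gyro`` is (n, 3) in deg/s, ``accel`` is (n, 3) in m/s**2.
    """

    side: Side
    gyro: np.ndarray
    accel: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        object.__setattr__(self, "gyro", gyro)
        object.__setattr__(self, "accel", accel)
        if gyro.shape[1] != 3 or accel.shape[1] != 3:
            raise ValueError("gyro and accel must each have 3 channels")
        if gyro.shape[0] != accel.shape[0]:
            raise ValueError("gyro and accel must have equal length")
        if not (np.all(np.isfinite(gyro)) and np.all(np.isfinite(accel))):
            raise ValueError("IMU samples must be finite")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.gyro.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate

    def gyro_series(self, axis: int) -> UniformSeries:
        return UniformSeries(self.gyro[:, axis], self.rate, self.t0)

    def accel_series(self, axis: int) -> UniformSeries:
        return UniformSeries(self.accel[:, axis], self.rate, self.t0)


@dataclass(frozen=True)
class FootswitchRecording:
    """Per-foot 4-channel footswitch recording (heel, mt1, mt5, toe).

    Channels are stored as an (n, 4) array; values are either analog force
    levels or, after :func:`gaitphase.reference.binarize`, {0, 1}.
    """

    side: Side
    channels: np.ndarray
    rate: float
    t0: float = 0.0

    CHANNEL_NAMES = ("heel", "mt1", "mt5", "toe")

    def __post_init__(self) -> None:
        channels = np.atleast_2d(np.asarray(self.channels, dtype=float))
        object.__setattr__(self, "channels", channels)
        if channels.shape[1] != 4:
            raise ValueError("footswitch recording needs 4 channels")
        if not np.all(np.isfinite(channels)):
            raise ValueError("footswitch samples must be finite")
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.channels.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.channels, (0.0, 1.0)).all())


class FilterKind(enum.Enum):
    BUTTERWORTH_LOWPASS = "butterworth_lowpass"
    MOVING_AVERAGE = "moving_average"


@dataclass(frozen=True)
class FilterSpec:
    """Specification of the two filter families used by the detectors.

    Butterworth low-pass filters take ``order`` and ``cutoff_hz``; moving
    averages take ``window_s``.  ``zero_phase=True`` (default) applies the
    Butterworth filter forward-backward, which doubles the effective order
    but removes group delay — appropriate for offline event timing.
    """

    kind: FilterKind
    order: int = 2
    cutoff_hz: float | None = None
    window_s: float | None = None
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind is FilterKind.BUTTERWORTH_LOWPASS:
            if self.order < 1:
                raise ValueError("Butterworth order must be >= 1")
            if self.cutoff_hz is None or self.cutoff_hz <= 0:
                raise ValueError("Butterworth filter needs a positive cutoff_hz")
        elif self.kind is FilterKind.MOVING_AVERAGE:
            if self.window_s is None or self.window_s <= 0:
                raise ValueError("moving average needs a positive window_s")


# ---------------------------------------------------------------------------
# File I/O


class SchemaError(ValueError):
    """A required column is missing from a signal file."""


class FormatError(ValueError):
    """Timestamps are non-monotonic, duplicated, or non-uniform."""


def _read_table(path: str | Path, columns: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def _infer_rate(time: np.ndarray, jitter_tol: float = 0.01) -> float:
    if time.size < 2:
        raise FormatError("need at least 2 samples to infer a sampling rate")
    dt = np.diff(time)
    if np.any(dt <= 0):
        raise FormatError("time column must be strictly increasing")
    med = float(np.median(dt))
    if np.any(np.abs(dt - med) > jitter_tol * med):
        raise FormatError("non-uniform sampling: time step jitter exceeds 1%")
    return 1.0 / med


def _parse_side(value: str) -> Side:
    return Side(str(value).lower())


def read_imu(path: str | Path, side: Side | str = Side.RIGHT) -> ImuRecording:
    """Read an IMU recording from a delimited-text file.

    Expected columns: ``time, gx, gy, gz, ax, ay, az`` (header required).
    The rate is inferred from the median time step; files with more than 1%
    timestamp jitter are rejected.
    """
    df = _read_table(path, IMU_COLUMNS)
    time = df["time"].to_numpy(dtype=float)
    rate = _infer_rate(time)
    if isinstance(side, str):
        side = _parse_side(side)
    gyro = df[["gx", "gy", "gz"]].to_numpy(dtype=float)
    accel = df[["ax", "ay", "az"]].to_numpy(dtype=float)
    return ImuRecording(side=side, gyro=gyro, accel=accel, rate=rate, t0=float(time[0]))


def read_footswitch(path: str | Path, side: Side | str = Side.RIGHT) -> FootswitchRecording:
    """Read a footswitch recording (columns ``time, heel, mt1, mt5, toe``)."""
    df = _read_table(path, FOOTSWITCH_COLUMNS)
    time = df["time"].to_numpy(dtype=float)
    rate = _infer_rate(time)
    if isinstance(side, str):
        side = _parse_side(side)
    channels = df[["heel", "mt1", "mt5", "toe"]].to_numpy(dtype=float)
    return FootswitchRecording(side=side, channels=channels, rate=rate, t0=float(time[0]))


def _write_sidecar(path: Path, rec: ImuRecording | FootswitchRecording,
                   meta: dict | None) -> None:
    sidecar = {"side": rec.side.value, "rate_hz": rec.rate, "t0_s": rec.t0}
    if isinstance(rec, ImuRecording):
        sidecar["units"] = {"gyro": "deg/s", "accel": "m/s^2"}
    else:
        sidecar["units"] = {"channels": "force (a.u.) or binary"}
    if meta:
        sidecar.update(meta)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2) + "\n")


def write_imu(path: str | Path, rec: ImuRecording, meta: dict | None = None) -> None:
    """Write an IMU recording as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([rec.times, rec.gyro, rec.accel]), columns=list(IMU_COLUMNS))
    df.to_csv(path, index=False, float_format="%.9g")
    _write_sidecar(path, rec, meta)


def write_footswitch(path: str | Path, rec: FootswitchRecording,
                     meta: dict | None = None) -> None:
    """Write a footswitch recording as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([rec.times, rec.channels]), columns=list(FOOTSWITCH_COLUMNS))
    df.to_csv(path, index=False, float_format="%.9g")
    _write_sidecar(path, rec, meta)


# ---------------------------------------------------------------------------
# Preprocessing primitives


def resample(series: UniformSeries, target_rate: float, mode: str = "linear") -> UniformSeries:
    """Resample a uniform series onto a uniform grid at ``target_rate``.

    ``mode='linear'`` interpolates linearly (analog channels);
    ``mode='hold'`` is a zero-order hold that keeps binary channels binary.
    The output grid starts at the same ``t0`` and covers the same span.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if len(series) < 2:
        raise ValueError("need at least 2 samples to resample")
    n_out = int(np.floor(series.duration * target_rate)) + 1
    t_out = series.t0 + np.arange(n_out) / target_rate
    t_in = series.times
    if mode == "linear":
        out = np.interp(t_out, t_in, series.samples)
    elif mode == "hold":
        # value of the most recent input sample at or before each output time;
        # quarter-sample tolerance absorbs floating-point grid misalignment
        idx = np.searchsorted(t_in, t_out + 0.25 / series.rate, side="right") - 1
        idx = np.clip(idx, 0, len(series) - 1)
        out = series.samples[idx]
    else:
        raise ValueError(f"unknown resampling mode: {mode!r}")
    return UniformSeries(out, target_rate, series.t0)


def apply_filter(series: UniformSeries, spec: FilterSpec) -> UniformSeries:
    """Apply a filter described by ``spec``; output keeps length and grid."""
    if spec.kind is FilterKind.MOVING_AVERAGE:
        return moving_average(series, spec.window_s)
    nyquist = series.rate / 2.0
    if spec.cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {spec.cutoff_hz} Hz is at or above Nyquist ({nyquist} Hz)")
    sos = sps.butter(spec.order, spec.cutoff_hz, btype="low", fs=series.rate,
                     output="sos")
    if spec.zero_phase:
        out = sps.sosfiltfilt(sos, series.samples)
    else:
        out = sps.sosfilt(sos, series.samples)
    return series.with_samples(out)


def butter_lowpass(series: UniformSeries, cutoff_hz: float, order: int = 2,
                   zero_phase: bool = True) -> UniformSeries:
    """Convenience wrapper for the 2nd-order low-pass Butterworth stage."""
    return apply_filter(series, FilterSpec(
        FilterKind.BUTTERWORTH_LOWPASS, order=order, cutoff_hz=cutoff_hz,
        zero_phase=zero_phase))


def moving_average(series: UniformSeries, window_s: float) -> UniformSeries:
    """Centered moving average with a truncated (shrinking) window at edges.

    The window holds ``round(window_s * rate)`` samples; near the edges it is
    truncated to the available samples so the output has the input's length.
    """
    w = int(round(window_s * series.rate))
    if w < 1:
        raise ValueError("window_s * rate must be >= 1")
    x = series.samples
    kernel = np.ones(w)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return series.with_samples(num / den)


def sagittal_axis(gyro: np.ndarray) -> int:
    """Pick the sagittal (pitch) gyroscope axis as the axis of maximal
    variance during walking — the foot rotates dominantly in the sagittal
    plane so the pitch channel carries most signal power."""
    gyro = np.atleast_2d(np.asarray(gyro, dtype=float))
    return int(np.argmax(np.var(gyro, axis=0)))


def sagittal_gyro(rec: ImuRecording, axis: int | None = None,
                  flip_sign: bool = False) -> UniformSeries:
    """Extract the sagittal angular-velocity series from an IMU recording.

    If ``axis`` is None the axis of maximal variance is used.  ``flip_sign``
    accommodates sensors mounted with the opposite handedness.
    """
    if axis is None:
        axis = sagittal_axis(rec.gyro)
    samples = rec.gyro[:, axis]
    if flip_sign:
        samples = -samples
    return UniformSeries(samples, rec.rate, rec.t0)
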