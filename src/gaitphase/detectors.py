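"""Threshold-based gait partitioning: the S-method and the R-method.

S-method (gyroscope): works on the low-pass filtered sagittal angular
velocity.  Per cycle, toe strike and heel off are the instants where |w|
falls below / rises above a 30 deg/s stasis threshold around the flat-foot
quiescence; toe off is the clockwise (negative) extremum between heel off
and the next mid-swing peak; heel strike is the clockwise extremum
following the mid-swing peak.

R-method (accelerometer): works on five reference signals derived from the
resultant of the two sagittal-plane acceleration channels — the 6 Hz
low-pass filtered resultant (c50), its first and second derivatives, and
two moving averages with 1.25 s and 0.30 s windows (cA200, cA50) that act
as constraint bands.  Flat-foot cores are quiescent intervals where c50
stays inside a band around cA200 with a small first derivative; heel off,
toe off, heel strike and toe strike are then located from turning and
inflection points of c50 constrained by cA50.  The published description
of this detector is a summary rather than an algorithm; the concrete
rule-set here is this package's documented interpretation, validated
against the synthetic generator (see docs/methods.md).

Both detectors are exposed as sklearn-style estimators whose ``fit`` is a
no-op (they have no trainable state) and whose ``predict`` maps an
:class:`~gaitphase.signals.ImuRecording` to a
:class:`~gaitphase.phases.PhaseSequence`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from sklearn.base import BaseEstimator

from .phases import EventType, GaitEvent, PhaseSequence, sequence_from_events
from .signals import (
    EVAL_RATE_HZ,
    ImuRecording,
    UniformSeries,
    butter_lowpass,
    moving_average,
    resample,
    sagittal_gyro,
)


@dataclass(frozen=True)
class SMethodConfig:
    """Configuration of the gyroscope threshold detector."""

    stasis_threshold: float = 30.0   # deg/s
    lowpass_hz: float = 15.0
    midswing_min_peak: float = 50.0  # deg/s
    min_phase_ms: float = 40.0

    def __post_init__(self) -> None:
        if min(self.stasis_threshold, self.lowpass_hz,
               self.midswing_min_peak, self.min_phase_ms) <= 0:
            raise ValueError("all S-method thresholds must be positive")


@dataclass(frozen=True)
class RMethodConfig:
    """Configuration of the accelerometer threshold detector."""

    lowpass_hz: float = 6.0
    ma_long_s: float = 1.25
    ma_short_s: float = 0.30
    quiescence_band: float = 0.5     # m/s^2 around cA200
    quiescence_min_ms: float = 100.0
    derivative_eps: float = 2.0      # m/s^3

    def __post_init__(self) -> None:
        if min(self.lowpass_hz, self.ma_long_s, self.ma_short_s,
               self.quiescence_band, self.quiescence_min_ms,
               self.derivative_eps) <= 0:
            raise ValueError("all R-method parameters must be positive")


@dataclass(frozen=True)
class RMethodSignals:
    """The five reference signals of the accelerometer detector."""

    resultant: UniformSeries
    c50: UniformSeries
    d1: UniformSeries
    d2: UniformSeries
    cA200: UniformSeries
    cA50: UniformSeries


# ---------------------------------------------------------------------------
# S-method


def s_method(gyro_sagittal: UniformSeries, cfg: SMethodConfig | None = None,
             eval_rate: float = EVAL_RATE_HZ) -> PhaseSequence:
    """Run the gyroscope threshold detector on a sagittal angular-velocity
    series (any rate; it is resampled onto the evaluation grid)."""
    cfg = cfg or SMethodConfig()
    series = gyro_sagittal
    if abs(series.rate - eval_rate) > 1e-9:
        series = resample(series, eval_rate, mode="linear")
    x = butter_lowpass(series, cfg.lowpass_hz).samples
    rate, t0 = series.rate, series.t0
    thr = cfg.stasis_threshold
    min_run = max(1, int(round(cfg.min_phase_ms / 1000.0 * rate)))

    peaks, _ = find_peaks(x, height=cfg.midswing_min_peak,
                          distance=max(1, int(round(0.5 * rate))))
    if peaks.size == 0:
        warnings.warn("no mid-swing peaks found; returning empty sequence",
                      stacklevel=2)
        return PhaseSequence(labels=np.full(x.size, 3, dtype=np.int8),
                             rate=rate, t0=t0)

    events: list[GaitEvent] = []
    for p, p_next in zip(peaks[:-1], peaks[1:]):
        span = p_next - p
        # heel strike: the clockwise extremum shortly after mid-swing
        hs_window = x[p:p + max(2, int(0.4 * span))]
        hs = p + int(np.argmin(hs_window))
        if x[hs] >= 0:
            continue
        # toe strike: start of the first sustained sub-threshold run
        run = _first_sustained_run(np.abs(x[hs:p_next]) < thr, min_run)
        if run is None:
            continue
        ts = hs + run[0]
        ho = hs + run[1]  # first sample after foot stasis above threshold
        if ho >= p_next:
            continue
        # toe off: the clockwise extremum between heel off and mid-swing
        to = ho + int(np.argmin(x[ho:p_next]))
        if x[to] >= 0:
            continue
        events += [GaitEvent(t0 + hs / rate, EventType.HS),
                   GaitEvent(t0 + ts / rate, EventType.TS),
                   GaitEvent(t0 + ho / rate, EventType.HO),
                   GaitEvent(t0 + to / rate, EventType.TO)]
    return sequence_from_events(events, x.size, rate, t0)


def _first_sustained_run(mask: np.ndarray, min_run: int
                         ) -> tuple[int, int] | None:
    """First run of True at least ``min_run`` long, as (start, stop)."""
    if not mask.any():
        return None
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    starts = np.flatnonzero(np.diff(padded) == 1)
    stops = np.flatnonzero(np.diff(padded) == -1)
    for s, e in zip(starts, stops):
        if e - s >= min_run:
            return int(s), int(e)
    return None


# ---------------------------------------------------------------------------
# R-method


def r_method_signals(accel: ImuRecording | np.ndarray,
                     cfg: RMethodConfig | None = None,
                     axes: tuple[int, int] = (0, 2),
                     rate: float | None = None,
                     t0: float = 0.0,
                     eval_rate: float = EVAL_RATE_HZ) -> RMethodSignals:
    """Compute the five reference signals of the accelerometer detector.

    ``accel`` is an IMU recording (its two sagittal-plane channels, by
    default the anterior and vertical axes, are combined) or an (n, >=2)
    array with ``rate`` given.  The resultant keeps gravity, matching a
    body-fixed sensor at rest reading ~9.81 m/s^2.
    """
    cfg = cfg or RMethodConfig()
    if isinstance(accel, ImuRecording):
        data, rate, t0 = accel.accel, accel.rate, accel.t0
    else:
        data = np.atleast_2d(np.asarray(accel, dtype=float))
        if rate is None:
            raise ValueError("rate is required with array input")
    if data.shape[1] < 2:
        raise ValueError("need at least 2 acceleration channels")
    res = np.hypot(data[:, axes[0]], data[:, axes[1]])
    series = UniformSeries(res, rate, t0)
    if abs(rate - eval_rate) > 1e-9:
        series = resample(series, eval_rate, mode="linear")
    c50 = butter_lowpass(series, cfg.lowpass_hz)
    d1 = c50.with_samples(np.gradient(c50.samples) * series.rate)
    d2 = c50.with_samples(np.gradient(d1.samples) * series.rate)
    return RMethodSignals(
        resultant=series,
        c50=c50,
        d1=d1,
        d2=d2,
        cA200=moving_average(series, cfg.ma_long_s),
        cA50=moving_average(series, cfg.ma_short_s),
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]]).astype(np.int8)
    starts = np.flatnonzero(np.diff(padded) == 1)
    stops = np.flatnonzero(np.diff(padded) == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _zero_crossings(x: np.ndarray) -> np.ndarray:
    sign = np.sign(x)
    return np.flatnonzero(np.diff(sign) != 0)


def r_method(accel: ImuRecording, cfg: RMethodConfig | None = None,
             axes: tuple[int, int] = (0, 2),
             eval_rate: float = EVAL_RATE_HZ) -> PhaseSequence:
    """Run the accelerometer threshold detector on an IMU recording."""
    cfg = cfg or RMethodConfig()
    sig = r_method_signals(accel, cfg, axes=axes, eval_rate=eval_rate)
    c50, d1, d2 = sig.c50.samples, sig.d1.samples, sig.d2.samples
    cA200, cA50 = sig.cA200.samples, sig.cA50.samples
    rate, t0 = sig.c50.rate, sig.c50.t0
    n = c50.size

    quiet = (np.abs(c50 - cA200) < cfg.quiescence_band) \
        & (np.abs(d1) < cfg.derivative_eps)
    min_run = max(1, int(round(cfg.quiescence_min_ms / 1000.0 * rate)))
    q_runs = [r for r in _runs(quiet) if r[1] - r[0] >= min_run]
    if len(q_runs) < 2:
        warnings.warn("fewer than two quiescent intervals; returning empty "
                      "sequence", stacklevel=2)
        return PhaseSequence(labels=np.full(n, 3, dtype=np.int8), rate=rate,
                             t0=t0)

    d2_zc = _zero_crossings(d2)
    events: list[GaitEvent] = []
    for (qs, qe), (qs_next, _) in zip(q_runs[:-1], q_runs[1:]):
        # heel off: end of flat-foot quiescence, refined to an inflection
        # point of c50 in its immediate (10 ms) neighbourhood
        ho = qe
        if d2_zc.size:
            j = d2_zc[np.argmin(np.abs(d2_zc - qe))]
            if abs(j - qe) <= max(1, int(round(0.010 * rate))):
                ho = int(j)
        # toe off: first turning point (local max of c50) after heel off
        seg_peaks, _ = find_peaks(c50[ho:qs_next], prominence=0.05)
        if seg_peaks.size == 0:
            continue
        to = ho + int(seg_peaks[0])
        # heel strike: the largest turning point after toe off that rises
        # above the short moving average
        hs_peaks = seg_peaks[(ho + seg_peaks > to)
                             & (c50[ho + seg_peaks] > cA50[ho + seg_peaks])]
        if hs_peaks.size == 0:
            continue
        hs = ho + int(hs_peaks[np.argmax(c50[ho + hs_peaks])])
        # toe strike: c50 falls back below the short moving average after
        # heel strike; the crossing is refined to the nearest inflection
        below = np.flatnonzero(c50[hs:qs_next + 1] < cA50[hs:qs_next + 1])
        if below.size == 0:
            continue
        ts = hs + int(below[0])
        cand = d2_zc[(d2_zc > hs) & (d2_zc <= qs_next)]
        cand = cand[c50[cand] < cA50[cand]]
        if cand.size and abs(int(cand[0]) - ts) <= int(0.05 * rate):
            ts = int(cand[0])
        events += [GaitEvent(t0 + ho / rate, EventType.HO),
                   GaitEvent(t0 + to / rate, EventType.TO),
                   GaitEvent(t0 + hs / rate, EventType.HS),
                   GaitEvent(t0 + ts / rate, EventType.TS)]
    return sequence_from_events(events, n, rate, t0)


# ---------------------------------------------------------------------------
# Estimator wrappers


class _RuleBasedSegmenter(BaseEstimator):
    """Common sklearn plumbing for the stateless threshold detectors."""

    def fit(self, X=None, y=None):  # noqa: D102 - sklearn signature
        self.is_fitted_ = True
        return self

    def predict(self, X):
        """Segment one recording or a list of recordings."""
        if isinstance(X, (list, tuple)):
            return [self._predict_one(rec) for rec in X]
        return self._predict_one(X)


class SMethodSegmenter(_RuleBasedSegmenter):
    """Gyroscope stasis-threshold gait segmenter (sklearn-style).

    Parameters mirror :class:`SMethodConfig`; ``axis=None`` selects the
    sagittal gyroscope axis by maximal variance, ``flip_sign`` accommodates
    opposite-handed sensor mounting.
    """

    def __init__(self, stasis_threshold: float = 30.0, lowpass_hz: float = 15.0,
                 midswing_min_peak: float = 50.0, min_phase_ms: float = 40.0,
                 axis: int | None = None, flip_sign: bool = False,
                 eval_rate: float = EVAL_RATE_HZ):
        self.stasis_threshold = stasis_threshold
        self.lowpass_hz = lowpass_hz
        self.midswing_min_peak = midswing_min_peak
        self.min_phase_ms = min_phase_ms
        self.axis = axis
        self.flip_sign = flip_sign
        self.eval_rate = eval_rate

    def _predict_one(self, rec: ImuRecording | UniformSeries) -> PhaseSequence:
        cfg = SMethodConfig(self.stasis_threshold, self.lowpass_hz,
                            self.midswing_min_peak, self.min_phase_ms)
        if isinstance(rec, ImuRecording):
            series = sagittal_gyro(rec, axis=self.axis, flip_sign=self.flip_sign)
        else:
            series = rec.with_samples(-rec.samples) if self.flip_sign else rec
        return s_method(series, cfg, eval_rate=self.eval_rate)


class RMethodSegmenter(_RuleBasedSegmenter):
    """Accelerometer reference-signal gait segmenter (sklearn-style)."""

    def __init__(self, lowpass_hz: float = 6.0, ma_long_s: float = 1.25,
                 ma_short_s: float = 0.30, quiescence_band: float = 0.5,
                 quiescence_min_ms: float = 100.0, derivative_eps: float = 2.0,
                 axes: tuple[int, int] = (0, 2),
                 eval_rate: float = EVAL_RATE_HZ):
        self.lowpass_hz = lowpass_hz
        self.ma_long_s = ma_long_s
        self.ma_short_s = ma_short_s
        self.quiescence_band = quiescence_band
        self.quiescence_min_ms = quiescence_min_ms
        self.derivative_eps = derivative_eps
        self.axes = axes
        self.eval_rate = eval_rate

    def _predict_one(self, rec: ImuRecording) -> PhaseSequence:
        cfg = RMethodConfig(self.lowpass_hz, self.ma_long_s, self.ma_short_s,
                            self.quiescence_band, self.quiescence_min_ms,
                            self.derivative_eps)
        return r_method(rec, cfg, axes=self.axes, eval_rate=self.eval_rate)
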