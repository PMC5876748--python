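"""Seeded synthetic gait generator with exact ground-truth events.

Each trial emulates one foot walking in a straight line: a 3-axis gyroscope
and accelerometer stream at the IMU rate (50 Hz) and a 4-channel footswitch
stream (2000 Hz), both derived from a shared list of ground-truth gait
events so every downstream detector can be scored against known truth.

The sagittal angular-velocity template is a per-stride superposition of
asymmetric Gaussian bumps: a negative trough at heel strike, quasi-stasis
(|w| < 10 deg/s) during flat foot, a negative trough at toe off and a large
positive peak at mid-swing.  Bump widths are tied to the drawn phase
durations so that |w| crosses the 30 deg/s stasis threshold at the true toe
strike and heel off instants — the construction the gyroscope threshold
detector relies on.  The accelerometer resultant shows an impact spike at
heel strike, quiescence near g during flat foot, a push-off peak at toe off
and a sub-g dip during swing, keeping its 1.25 s moving average close to g
so the accelerometer detector's quiescence band exists.

Event times are quantized to the 200 Hz evaluation grid, so ground-truth
labels, footswitch transitions and event times are mutually exact when
``chatter_prob = 0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .phases import EventType, GaitEvent, PhaseSequence, events_to_labels
from .signals import EVAL_RATE_HZ, FootswitchRecording, ImuRecording, Side

GRAVITY = 9.80665  # m/s^2

#: stasis threshold the angular-velocity template is anchored to (deg/s)
STASIS_DEG_S = 30.0


class ProfileError(ValueError):
    """A gait profile violates its invariants."""


@dataclass(frozen=True)
class GaitProfile:
    """Parameters of the synthetic gait model.

    ``phase_fractions`` are the mean (LR, FF, PS, Sw) percentages of the
    gait cycle; printed group means may sum to slightly off 100 due to
    rounding, so sums within 100 +/- 0.5 are accepted and renormalized when
    durations are drawn.  ``peak_amps`` are the template trough/peak
    amplitudes (A_HS, A_TO, A_MS) in deg/s.  ``chatter_prob`` is the
    per-edge probability of a short spurious footswitch flip near a contact
    transition (tests debouncing).
    """

    phase_fractions: tuple[float, float, float, float]
    stride_time_s: float = 1.1
    fraction_jitter_sd: float = 1.0      # percentage points
    stride_time_jitter_sd: float = 0.03  # s
    gyro_noise_sd: float = 3.0           # deg/s
    accel_noise_sd: float = 0.15         # m/s^2
    tremor_amp: float = 0.0              # deg/s
    tremor_hz: float = 5.0
    peak_amps: tuple[float, float, float] = (100.0, 200.0, 400.0)
    chatter_prob: float = 0.0
    imu_rate: float = 50.0
    fsw_rate: float = 2000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.phase_fractions, dtype=float)
        if f.shape != (4,) or np.any(f <= 0):
            raise ProfileError("phase_fractions must be 4 positive values")
        if abs(f.sum() - 100.0) > 0.5:
            raise ProfileError(
                f"phase_fractions must sum to ~100, got {f.sum():.3f}")
        if self.stride_time_s <= 0:
            raise ProfileError("stride_time_s must be positive")
        for name in ("fraction_jitter_sd", "stride_time_jitter_sd",
                     "gyro_noise_sd", "accel_noise_sd", "tremor_amp",
                     "chatter_prob"):
            if getattr(self, name) < 0:
                raise ProfileError(f"{name} must be non-negative")
        if any(a <= 0 for a in self.peak_amps):
            raise ProfileError("peak_amps must be positive")


#: presets: healthy phase fractions are published control-group means;
#: the parkinsonian presets shift the distribution toward longer flat foot
#: and shorter swing with damped peaks and 4-6 Hz rest tremor — plausible
#: severity fixtures, not claims about any patient population.
_PRESETS = {
    "healthy": GaitProfile(
        phase_fractions=(6.9, 39.4, 16.2, 37.7),
        stride_time_s=1.1,
    ),
    "pd_mild": GaitProfile(
        phase_fractions=(6.9, 43.4, 14.2, 35.7),
        stride_time_s=1.2,
        fraction_jitter_sd=1.5,
        stride_time_jitter_sd=0.05,
        gyro_noise_sd=4.0,
        peak_amps=(80.0, 160.0, 320.0),
        tremor_amp=10.0,
    ),
    "pd_severe": GaitProfile(
        phase_fractions=(8.0, 48.0, 12.0, 32.0),
        stride_time_s=1.3,
        fraction_jitter_sd=2.0,
        stride_time_jitter_sd=0.07,
        gyro_noise_sd=5.0,
        accel_noise_sd=0.2,
        peak_amps=(60.0, 120.0, 240.0),
        tremor_amp=20.0,
    ),
}


def preset(name: str, **overrides) -> GaitProfile:
    """Return a named gait profile (``healthy``, ``pd_mild``, ``pd_severe``).

    Keyword overrides replace individual fields, e.g. ``preset("healthy",
    seed=7, gyro_noise_sd=0.0)``.
    """
    try:
        base = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None
    return replace(base, **overrides) if overrides else base


def subject_profile(base: GaitProfile, rng: np.random.Generator,
                    fraction_sd: float = 1.5,
                    stride_time_sd: float = 0.08) -> GaitProfile:
    """Draw a stable per-subject variant of a group profile.

    Individuals differ systematically in phase distribution and cadence;
    a subject keeps these traits across repeated trials while the
    per-stride jitter stays within-trial.  ``fraction_sd`` is in
    percentage points, ``stride_time_sd`` in seconds.
    """
    f = np.asarray(base.phase_fractions, dtype=float)
    f = np.clip(f + rng.normal(0.0, fraction_sd, 4), 2.0, None)
    f = f / f.sum() * 100.0
    stride = max(0.6, base.stride_time_s + rng.normal(0.0, stride_time_sd))
    return replace(base, phase_fractions=tuple(f), stride_time_s=stride)


@dataclass
class GroundTruth:
    """Exact gait events and the per-sample reference labels at 200 Hz."""

    side: Side
    events: list[GaitEvent]
    sequence: PhaseSequence
    stride_fractions: np.ndarray  # (n_strides, 4) realized percentages

    def to_json(self) -> str:
        return json.dumps({
            "side": self.side.value,
            "events": [{"type": e.type.value, "time_s": e.time}
                       for e in self.events],
            "labels": [int(v) for v in self.sequence.labels],
            "rate_hz": self.sequence.rate,
            "t0_s": self.sequence.t0,
            "stride_fractions": self.stride_fractions.tolist(),
        })

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        events = [GaitEvent(float(e["time_s"]), EventType(e["type"]))
                  for e in payload["events"]]
        seq = PhaseSequence(
            labels=np.asarray(payload["labels"], dtype=np.int8),
            rate=float(payload["rate_hz"]), t0=float(payload.get("t0_s", 0.0)),
            events=events)
        return cls(side=Side(payload["side"]), events=events, sequence=seq,
                   stride_fractions=np.asarray(payload["stride_fractions"]))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls.from_json(Path(path).read_text())


def _snap(t: float, rate: float = EVAL_RATE_HZ) -> float:
    return round(t * rate) / rate


def _asym_gauss(t: np.ndarray, center: float, sl: float, sr: float) -> np.ndarray:
    d = t - center
    sigma = np.where(d < 0, sl, sr)
    return np.exp(-0.5 * (d / sigma) ** 2)


def _crossing_sigma(amp: float, duration: float) -> float:
    """Width so a bump of height ``amp`` decays to the stasis threshold
    exactly ``duration`` seconds from its center."""
    if amp <= STASIS_DEG_S * 1.2:
        return max(duration, 1e-3)
    return duration / np.sqrt(2.0 * np.log(amp / STASIS_DEG_S))


def _draw_strides(profile: GaitProfile, n_strides: int, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-stride durations and phase fractions (renormalized to 100)."""
    base = np.asarray(profile.phase_fractions, dtype=float)
    fractions = np.empty((n_strides, 4))
    durations = np.empty(n_strides)
    for j in range(n_strides):
        f = base + rng.normal(0.0, profile.fraction_jitter_sd, size=4)
        f = np.clip(f, 1.0, None)
        fractions[j] = f / f.sum() * 100.0
        durations[j] = max(
            0.4, profile.stride_time_s
            + rng.normal(0.0, profile.stride_time_jitter_sd))
    return durations, fractions


def generate_trial(profile: GaitProfile, n_strides: int, side: Side = Side.RIGHT,
                   rng: np.random.Generator | None = None
                   ) -> tuple[ImuRecording, FootswitchRecording, GroundTruth]:
    """Generate one synthetic walking trial for one foot.

    Returns the IMU recording (50 Hz), the analog footswitch recording
    (2000 Hz) and the exact ground truth.  All randomness comes from
    ``rng`` or, if omitted, from ``profile.seed``.
    """
    if n_strides < 1:
        raise ProfileError("n_strides must be >= 1")
    if rng is None:
        rng = np.random.default_rng(profile.seed)

    durations, fractions = _draw_strides(profile, n_strides, rng)

    # --- event schedule, quantized to the 200 Hz evaluation grid
    lead_in = 0.4
    events: list[GaitEvent] = []
    stride_bounds = []  # (HS_j, TS_j, HO_j, TO_j, HS_{j+1})
    t = _snap(lead_in)
    for j in range(n_strides):
        d = durations[j] * fractions[j] / 100.0
        hs = t
        ts = _snap(hs + d[0])
        ho = _snap(ts + d[1])
        to = _snap(ho + d[2])
        nxt = _snap(to + d[3])
        # keep every phase at least one evaluation sample long
        step = 1.0 / EVAL_RATE_HZ
        ts = max(ts, hs + step)
        ho = max(ho, ts + step)
        to = max(to, ho + step)
        nxt = max(nxt, to + step)
        events += [GaitEvent(hs, EventType.HS), GaitEvent(ts, EventType.TS),
                   GaitEvent(ho, EventType.HO), GaitEvent(to, EventType.TO)]
        stride_bounds.append((hs, ts, ho, to, nxt))
        t = nxt
    final_hs = t
    final_ts = _snap(final_hs + durations[-1] * fractions[-1, 0] / 100.0)
    events += [GaitEvent(final_hs, EventType.HS), GaitEvent(final_ts, EventType.TS)]
    t_end = _snap(final_ts + 0.4)

    # --- sagittal angular velocity template at the IMU rate
    n_imu = int(round(t_end * profile.imu_rate)) + 1
    t_imu = np.arange(n_imu) / profile.imu_rate
    a_hs, a_to, a_ms = profile.peak_amps
    omega = np.zeros(n_imu)
    for j, (hs, ts, ho, to, nxt) in enumerate(stride_bounds):
        d_lr, d_ps, d_sw = ts - hs, to - ho, nxt - to
        sw_prev = stride_bounds[j - 1][4] - stride_bounds[j - 1][3] if j else d_sw
        # strides vary in vigour: per-stride amplitude factors (~10% SD)
        g_hs, g_to, g_ms = rng.normal(1.0, 0.10, 3).clip(0.6, 1.4)
        # each stance-edge trough is a sharp symmetric dip centred on its
        # event (so filtered minima stay on the event) riding on a broad
        # shallow lobe whose flank carries the 30 deg/s stasis crossing
        omega -= g_hs * a_hs * _asym_gauss(t_imu, hs + 0.0075, 0.012, 0.012)
        plateau_c = hs + 0.35 * d_lr
        omega -= g_hs * 0.45 * a_hs * _asym_gauss(
            t_imu, plateau_c, 0.25 * d_lr,
            _crossing_sigma(g_hs * 0.45 * a_hs, ts - plateau_c))
        omega -= g_to * a_to * _asym_gauss(t_imu, to, 0.012, 0.012)
        approach_c = to - 0.3 * d_ps
        omega -= g_to * 0.3 * a_to * _asym_gauss(
            t_imu, approach_c,
            _crossing_sigma(g_to * 0.3 * a_to, approach_c - ho), 0.03)
        omega += g_ms * a_ms * _asym_gauss(t_imu, to + 0.34 * d_sw,
                                           0.13 * d_sw, 0.11 * d_sw)
        # moderate dorsiflexion shelf in late swing: the foot keeps
        # rotating until the pre-strike dive (no flat-foot-like plateau)
        omega += 0.15 * g_ms * a_ms * _asym_gauss(t_imu, to + 0.85 * d_sw,
                                                  0.18 * d_sw, 0.05 * d_sw)
    # closing heel strike of the final (n+1 th) cycle
    d_sw_last = stride_bounds[-1][4] - stride_bounds[-1][3]
    d_lr_last = final_ts - final_hs
    omega -= a_hs * _asym_gauss(t_imu, final_hs + 0.0075, 0.012, 0.012)
    omega -= 0.45 * a_hs * _asym_gauss(
        t_imu, final_hs + 0.35 * d_lr_last, 0.25 * d_lr_last,
        _crossing_sigma(0.45 * a_hs, 0.65 * d_lr_last))
    if profile.tremor_amp > 0:
        omega += profile.tremor_amp * np.sin(
            2 * np.pi * profile.tremor_hz * t_imu + rng.uniform(0, 2 * np.pi))
    gyro = np.column_stack([
        rng.normal(0.0, profile.gyro_noise_sd, n_imu) + 0.1 * omega,
        omega + rng.normal(0.0, profile.gyro_noise_sd, n_imu),
        rng.normal(0.0, profile.gyro_noise_sd, n_imu) - 0.05 * omega,
    ])

    # --- accelerometer resultant template (vertical channel carries it)
    res = np.full(n_imu, GRAVITY)
    for hs, ts, ho, to, nxt in stride_bounds:
        d_sw = nxt - to
        res += 2.5 * _asym_gauss(t_imu, hs, 0.04, 0.04)
        res += 2.5 * _asym_gauss(t_imu, to, 0.05, 0.05)
        res -= 1.5 * _asym_gauss(t_imu, to + 0.30 * d_sw, 0.08, 0.08)
    res += 2.5 * _asym_gauss(t_imu, final_hs, 0.04, 0.04)
    accel = np.column_stack([
        0.15 * (res - GRAVITY) + rng.normal(0.0, profile.accel_noise_sd, n_imu),
        rng.normal(0.0, profile.accel_noise_sd, n_imu),
        res + rng.normal(0.0, profile.accel_noise_sd, n_imu),
    ])
    imu = ImuRecording(side=side, gyro=gyro, accel=accel, rate=profile.imu_rate)

    # --- footswitch contact logic: heel on HS..HO, forefoot on TS..TO
    n_fsw = int(round(t_end * profile.fsw_rate)) + 1
    t_fsw = np.arange(n_fsw) / profile.fsw_rate
    heel = np.zeros(n_fsw, dtype=bool)
    fore = np.zeros(n_fsw, dtype=bool)
    eps = 0.25 / profile.fsw_rate  # half-open intervals on the fsw grid
    for hs, ts, ho, to, nxt in stride_bounds:
        heel |= (t_fsw >= hs - eps) & (t_fsw < ho - eps)
        fore |= (t_fsw >= ts - eps) & (t_fsw < to - eps)
    heel |= t_fsw >= final_hs - eps
    fore |= t_fsw >= final_ts - eps
    contact = np.column_stack([heel, fore, fore, fore])
    if profile.chatter_prob > 0:
        contact = _add_chatter(contact, profile.fsw_rate, profile.chatter_prob, rng)
    # analog force levels: slow per-channel undulation while loaded
    level = 0.7 + 0.25 * np.sin(
        2 * np.pi * 0.9 * t_fsw[:, None] + np.arange(4) * 1.3)
    forces = np.clip(contact * level + rng.normal(0.0, 0.01, contact.shape), 0.0, None)
    fsw = FootswitchRecording(side=side, channels=forces, rate=profile.fsw_rate)

    # --- ground truth on the evaluation grid
    n_eval = int(round(t_end * EVAL_RATE_HZ)) + 1
    labels = events_to_labels(events, n_eval, EVAL_RATE_HZ)
    seq = PhaseSequence(labels=labels, rate=EVAL_RATE_HZ, events=list(events))
    truth = GroundTruth(side=side, events=events, sequence=seq,
                        stride_fractions=fractions)
    return imu, fsw, truth


def _add_chatter(contact: np.ndarray, rate: float, prob: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Flip short runs near contact edges to emulate switch bounce.

    For each edge of each channel, with probability ``prob``, a 2-8 ms run
    placed within 15 ms of the edge is inverted — long enough to survive
    the zero-order-hold resampling to 200 Hz, short enough for a 20 ms
    debounce to remove.
    """
    out = contact.copy()
    n = contact.shape[0]
    for ch in range(contact.shape[1]):
        edges = np.flatnonzero(np.diff(contact[:, ch].astype(np.int8)))
        for e in edges:
            if rng.random() >= prob:
                continue
            offset = int(rng.uniform(0.002, 0.015) * rate) * int(rng.choice([-1, 1]))
            length = int(rng.uniform(0.002, 0.008) * rate)
            start = int(np.clip(e + offset, 0, n - 1))
            stop = int(np.clip(start + length, 0, n))
            out[start:stop, ch] = ~contact[start:stop, ch]
    return out


def generate_bilateral(profile: GaitProfile, n_strides: int,
                       rng: np.random.Generator | None = None) -> dict:
    """Generate both feet with a half-stride phase offset between sides."""
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    out = {}
    for side, shift in ((Side.RIGHT, 0.0), (Side.LEFT, 0.5)):
        imu, fsw, truth = generate_trial(profile, n_strides, side=side, rng=rng)
        if shift:
            dt = _snap(shift * profile.stride_time_s)
            imu = ImuRecording(side, imu.gyro, imu.accel, imu.rate, imu.t0 + dt)
            fsw = FootswitchRecording(side, fsw.channels, fsw.rate, fsw.t0 + dt)
            truth = GroundTruth(
                side=side,
                events=[GaitEvent(e.time + dt, e.type) for e in truth.events],
                sequence=PhaseSequence(
                    labels=truth.sequence.labels, rate=truth.sequence.rate,
                    t0=truth.sequence.t0 + dt,
                    events=[GaitEvent(e.time + dt, e.type)
                            for e in truth.sequence.events]),
                stride_fractions=truth.stride_fractions)
        out[side] = (imu, fsw, truth)
    return out
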