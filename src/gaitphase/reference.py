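"""Reference phase sequence from footswitch signals.

The four contact sensors per foot (heel, first and fifth
metatarsophalangeal, toe) define the reference sequence by per-sample
rules: loading response when only the heel switch is pressed, flat foot
when all four are pressed, pre-swing when at least one forefoot switch is
pressed, swing when none is.  Flat foot is checked before pre-swing: "all
pressed" logically implies "some forefoot pressed", so the more specific
condition takes precedence.
"""

from __future__ import annotations

import warnings

import numpy as np

from .phases import (
    GaitPhase,
    PhaseSequence,
    StridePhases,
    labels_to_events,
)
from .signals import EVAL_RATE_HZ, FootswitchRecording, UniformSeries, resample


def binarize(fsw: FootswitchRecording, threshold_frac: float = 0.10
             ) -> FootswitchRecording:
    """Threshold each analog force channel at ``threshold_frac`` of its own
    robust maximum (95th percentile).  Already-binary input passes through
    unchanged; an all-zero channel stays zero (with a warning)."""
    if not 0.0 < threshold_frac < 1.0:
        raise ValueError("threshold_frac must be in (0, 1)")
    if fsw.is_binary:
        return fsw
    out = np.zeros_like(fsw.channels)
    for ch in range(4):
        x = fsw.channels[:, ch]
        robust_max = np.percentile(x, 95)
        if robust_max <= 0:
            warnings.warn(
                f"footswitch channel {FootswitchRecording.CHANNEL_NAMES[ch]!r}"
                " is all zero; leaving it unpressed", stacklevel=2)
            continue
        out[:, ch] = (x >= threshold_frac * robust_max).astype(float)
    return FootswitchRecording(side=fsw.side, channels=out, rate=fsw.rate,
                               t0=fsw.t0)


def _rules_to_labels(channels: np.ndarray) -> np.ndarray:
    heel = channels[:, 0] > 0.5
    fore = channels[:, 1:] > 0.5
    any_fore = fore.any(axis=1)
    all_pressed = heel & fore.all(axis=1)
    labels = np.full(channels.shape[0], int(GaitPhase.SW), dtype=np.int8)
    labels[any_fore] = int(GaitPhase.PS)
    labels[heel & ~any_fore] = int(GaitPhase.LR)
    labels[all_pressed] = int(GaitPhase.FF)
    return labels


def _debounce(labels: np.ndarray, min_run: int) -> np.ndarray:
    """Merge runs shorter than ``min_run`` samples into the previous run."""
    if min_run <= 1:
        return labels
    out = labels.copy()
    boundaries = np.flatnonzero(np.diff(out)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [out.size]])
    for s, e in zip(starts, ends):
        if e - s < min_run and s > 0:
            out[s:e] = out[s - 1]
    return out


def label_phases(fsw: FootswitchRecording, debounce_ms: float = 20.0,
                 eval_rate: float = EVAL_RATE_HZ,
                 threshold_frac: float = 0.10) -> PhaseSequence:
    """Build the reference phase sequence from a footswitch recording.

    Analog input is binarized first; channels are moved to the evaluation
    grid with a zero-order hold; the contact rules are applied per sample;
    runs shorter than ``debounce_ms`` are merged into the preceding phase.
    Events are emitted at label changes that follow the canonical
    HS->TS->HO->TO cycle; residual non-canonical changes are flagged on the
    returned sequence rather than silently kept.
    """
    binary = binarize(fsw, threshold_frac)
    if abs(binary.rate - eval_rate) > 1e-9:
        resampled = np.column_stack([
            resample(UniformSeries(binary.channels[:, ch], binary.rate,
                                   binary.t0), eval_rate, mode="hold").samples
            for ch in range(4)])
        binary = FootswitchRecording(side=binary.side, channels=resampled,
                                     rate=eval_rate, t0=binary.t0)
    labels = _rules_to_labels(binary.channels)
    labels = _debounce(labels, int(round(debounce_ms / 1000.0 * eval_rate)))
    events, flagged = labels_to_events(labels, eval_rate, binary.t0)
    return PhaseSequence(labels=labels, rate=eval_rate, t0=binary.t0,
                         events=events, flagged=flagged)


class StrideSegmentationError(ValueError):
    pass


def segment_strides(seq: PhaseSequence, discard_ends: int = 3
                    ) -> list[StridePhases]:
    """Split a phase sequence into strides and compute phase percentages.

    Strides are delimited by successive heel strikes (Sw->LR transitions in
    the label stream).  The first and last ``discard_ends`` strides are
    dropped to avoid acceleration/deceleration effects.  Strides that do
    not contain the full LR->FF->PS->Sw progression are excluded from the
    output (their count is reported via a warning).
    """
    labels = seq.labels
    lr = int(GaitPhase.LR)
    hs_samples = np.flatnonzero(
        (labels[1:] == lr) & (labels[:-1] == int(GaitPhase.SW))) + 1
    n_strides = hs_samples.size - 1
    if n_strides < 2 * discard_ends + 1:
        raise StrideSegmentationError(
            f"need at least {2 * discard_ends + 1} strides, found {n_strides}")
    keep = range(discard_ends, n_strides - discard_ends)
    out: list[StridePhases] = []
    n_dropped = 0
    for k in keep:
        s, e = hs_samples[k], hs_samples[k + 1]
        chunk = labels[s:e]
        # canonical stride: each phase present, in a single cyclic pass
        counts = np.bincount(chunk, minlength=4)[:4]
        changes = np.flatnonzero(np.diff(chunk)) + 1
        order_ok = (counts > 0).all() and changes.size == 3 and all(
            (int(chunk[i]) - int(chunk[i - 1])) % 4 == 1 for i in changes)
        if not order_ok:
            n_dropped += 1
            continue
        pct = counts / chunk.size * 100.0
        out.append(StridePhases(
            stride_index=k,
            bounds=(seq.t0 + s / seq.rate, seq.t0 + e / seq.rate),
            percentages=pct))
    if n_dropped:
        warnings.warn(f"{n_dropped} stride(s) with non-canonical phase order "
                      "excluded from percentage statistics", stacklevel=2)
    return out


def mean_percentages(strides: list[StridePhases]) -> np.ndarray:
    """Trial-mean phase percentages over a stride list."""
    if not strides:
        raise ValueError("empty stride list")
    return np.mean([s.percentages for s in strides], axis=0)
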