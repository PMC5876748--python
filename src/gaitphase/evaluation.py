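"""Transition-level accuracy metrics and ROC utilities.

A detected gait-event sequence is scored against the footswitch reference
by matching transitions of the same type inside a tolerance window (60 ms,
centered, i.e. +/-30 ms around each reference transition).  Matched
transitions are true positives; unmatched detections false positives;
unmatched reference windows false negatives.  True negatives are counted
at sample level: samples outside every reference window that carry no
detected transition — a definition that gives the true-negative rate a
well-defined denominator (documented prominently in docs/methods.md since
the absolute TNR value depends on it).

The Goodness index G is the Euclidean distance from (TNR, TPR) to the
perfect ROC corner (1, 1):

    G = sqrt((1 - TNR)^2 + (1 - TPR)^2)

classified optimum (G <= 0.25), good (0.25 < G <= 0.7) or random (G > 0.7).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .phases import EventType, PhaseSequence, StridePhases
from .reference import mean_percentages


@dataclass(frozen=True)
class EvalConfig:
    tolerance_ms: float = 60.0  # full window width, centered on transitions
    rate: float = 200.0

    def __post_init__(self) -> None:
        if self.tolerance_ms <= 0 or self.rate <= 0:
            raise ValueError("tolerance_ms and rate must be positive")

    @property
    def half_window_s(self) -> float:
        return self.tolerance_ms / 2000.0


@dataclass
class EvalCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0
    per_type: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class EvalResult:
    counts: EvalCounts
    TPR: float
    TNR: float
    G: float
    performance_class: str


class GridMismatchError(ValueError):
    pass


class UndefinedRateError(ZeroDivisionError):
    pass


def _match_one_type(ref_times: np.ndarray, pred_times: np.ndarray,
                    half_window: float) -> int:
    """One-to-one greedy matching by ascending time distance; ties broken
    by earlier predicted time.  Returns the number of matches."""
    if ref_times.size == 0 or pred_times.size == 0:
        return 0
    dist = np.abs(ref_times[:, None] - pred_times[None, :])
    pairs = np.argwhere(dist <= half_window + 1e-12)
    if pairs.size == 0:
        return 0
    order = np.lexsort((pred_times[pairs[:, 1]], dist[pairs[:, 0], pairs[:, 1]]))
    used_ref = np.zeros(ref_times.size, dtype=bool)
    used_pred = np.zeros(pred_times.size, dtype=bool)
    n = 0
    for r, p in pairs[order]:
        if not used_ref[r] and not used_pred[p]:
            used_ref[r] = used_pred[p] = True
            n += 1
    return n


def match_transitions(reference: PhaseSequence, predicted: PhaseSequence,
                      cfg: EvalConfig | None = None,
                      window: tuple[float, float] | None = None) -> EvalCounts:
    """Count TP/TN/FP/FN between reference and predicted transitions.

    ``window`` optionally restricts scoring to a time interval (e.g. the
    span of retained strides after discarding accelerating/decelerating
    cycles at the trial ends).
    """
    cfg = cfg or EvalConfig()
    if abs(reference.rate - predicted.rate) > 1e-9:
        raise GridMismatchError(
            f"sequences on different grids: {reference.rate} vs "
            f"{predicted.rate} Hz")
    half = cfg.half_window_s
    t_lo = window[0] if window else -np.inf
    t_hi = window[1] if window else np.inf

    counts = EvalCounts()
    all_ref_times = []
    all_pred_times = []
    for kind in EventType:
        rt = np.array([e.time for e in reference.events_of_type(kind)
                       if t_lo <= e.time <= t_hi])
        pt = np.array([e.time for e in predicted.events_of_type(kind)
                       if t_lo <= e.time <= t_hi])
        tp = _match_one_type(rt, pt, half)
        fp = pt.size - tp
        fn = rt.size - tp
        counts.per_type[kind.value] = {"TP": tp, "FP": fp, "FN": fn}
        counts.TP += tp
        counts.FP += fp
        counts.FN += fn
        all_ref_times.append(rt)
        all_pred_times.append(pt)

    # sample-level true negatives on the reference grid
    times = reference.times
    in_window = (times >= t_lo) & (times <= t_hi)
    ref_times = np.concatenate(all_ref_times) if all_ref_times else np.array([])
    near_ref = np.zeros(times.size, dtype=bool)
    if ref_times.size:
        d = np.abs(times[:, None] - ref_times[None, :])
        near_ref = (d <= half + 1e-12).any(axis=1)
    pred_samples = np.unique(np.round(
        (np.concatenate(all_pred_times) - reference.t0) * reference.rate
    ).astype(int)) if any(a.size for a in all_pred_times) else np.array([], int)
    has_pred = np.zeros(times.size, dtype=bool)
    valid = (pred_samples >= 0) & (pred_samples < times.size)
    has_pred[pred_samples[valid]] = True
    counts.TN = int(np.sum(in_window & ~near_ref & ~has_pred))
    return counts


def rates(counts: EvalCounts) -> tuple[float, float]:
    """Sensitivity and specificity: TPR = TP/(TP+FN), TNR = TN/(TN+FP)."""
    if counts.TP + counts.FN == 0:
        raise UndefinedRateError("no reference transitions: TPR undefined")
    if counts.TN + counts.FP == 0:
        raise UndefinedRateError("no negatives: TNR undefined")
    return (counts.TP / (counts.TP + counts.FN),
            counts.TN / (counts.TN + counts.FP))


def goodness(TPR: float, TNR: float) -> tuple[float, str]:
    """Goodness index and its performance class.

    G is the distance from (TNR, TPR) to the perfect ROC point; optimum
    when G <= 0.25, good when 0.25 < G <= 0.7, random beyond.
    """
    if not (0.0 <= TPR <= 1.0 and 0.0 <= TNR <= 1.0):
        raise ValueError("rates must lie in [0, 1]")
    g = float(np.hypot(1.0 - TNR, 1.0 - TPR))
    if g <= 0.25:
        cls = "optimum"
    elif g <= 0.7:
        cls = "good"
    else:
        cls = "random"
    return g, cls


def evaluate_sequences(reference: PhaseSequence, predicted: PhaseSequence,
                       cfg: EvalConfig | None = None,
                       window: tuple[float, float] | None = None
                       ) -> EvalResult:
    """Full transition-level evaluation of one predicted sequence."""
    counts = match_transitions(reference, predicted, cfg, window)
    tpr, tnr = rates(counts)
    g, cls = goodness(tpr, tnr)
    return EvalResult(counts=counts, TPR=tpr, TNR=tnr, G=g,
                      performance_class=cls)


@dataclass
class PhaseErrorResult:
    """Absolute errors of trial-mean phase percentages (and optionally of
    the per-side GPQI distance when a reference distribution is given)."""

    LR_e: float
    FF_e: float
    PS_e: float
    Sw_e: float
    GPQI_e: float | None = None

    def as_array(self) -> np.ndarray:
        return np.array([self.LR_e, self.FF_e, self.PS_e, self.Sw_e])


def phase_errors(reference: list[StridePhases], predicted: list[StridePhases],
                 ref_distribution=None) -> PhaseErrorResult:
    """Absolute difference of trial-mean phase percentages per phase.

    If ``ref_distribution`` (a :class:`gaitphase.gpqi.ReferenceDistribution`)
    is given, also reports |GPQI_ref - GPQI_method| for this side's
    single-side distance.
    """
    if not reference or not predicted:
        raise ValueError("stride lists must be non-empty")
    ref_mean = mean_percentages(reference)
    pred_mean = mean_percentages(predicted)
    err = np.abs(ref_mean - pred_mean)
    gpqi_e = None
    if ref_distribution is not None:
        m = ref_distribution.as_array()
        gpqi_e = float(abs(np.linalg.norm(ref_mean - m)
                           - np.linalg.norm(pred_mean - m)))
    return PhaseErrorResult(LR_e=float(err[0]), FF_e=float(err[1]),
                            PS_e=float(err[2]), Sw_e=float(err[3]),
                            GPQI_e=gpqi_e)


def roc_auc(scores_group_a, scores_group_b) -> float:
    """Area under the ROC curve, in percent, for separating group A (the
    higher-scoring class) from group B, via the rank-sum identity with
    ties counted half."""
    a = np.asarray(scores_group_a, dtype=float)
    b = np.asarray(scores_group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([a, b]))
    u = ranks[:a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size) * 100.0)
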