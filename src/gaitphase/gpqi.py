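"""Gait Phases Quality Index (GPQI) and its reliability statistics.

GPQI summarises how far a subject's gait-phase distribution deviates from
a healthy control-group reference.  For each side i (left, right), the
phase-percentage 4-vector (LR, FF, PS, Sw) is compared with the
control-group means (mLR, mFF, mPS, mSw) by Euclidean distance in the
4-dimensional phase space, and the two per-side distances are summed:

    GPQI = sum_i sqrt((LR_i-mLR)^2 + (FF_i-mFF)^2 + (PS_i-mPS)^2 + (Sw_i-mSw)^2)

GPQI is in percentage points; 0 means both sides match the healthy
distribution exactly.  Test-retest reliability across repeated trials is
quantified with the two-way mixed, consistency, average-measures
intraclass correlation ICC(3,k), the standard error of measurement
SEM = SD * sqrt(1 - ICC), and the minimal detectable change
MDC95 = 1.96 * sqrt(2) * SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phases import StridePhases
from .reference import mean_percentages

#: published control-group phase-percentage means (LR, FF, PS, Sw), %
DEFAULT_CONTROL_MEANS = (6.9, 39.4, 16.2, 37.7)


@dataclass(frozen=True)
class ReferenceDistribution:
    """Control-group mean phase percentages the index is anchored to.

    Printed group means may sum slightly off 100 due to rounding, so sums
    in [98, 102] are accepted.  ``source`` records whether the values are
    the published defaults or were computed from a control cohort.
    """

    mLR: float
    mFF: float
    mPS: float
    mSw: float
    source: str = "computed"

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals <= 0):
            raise ValueError("reference means must be positive")
        if not 98.0 <= vals.sum() <= 102.0:
            raise ValueError(
                f"reference means must sum to ~100, got {vals.sum():.3f}")

    def as_array(self) -> np.ndarray:
        return np.array([self.mLR, self.mFF, self.mPS, self.mSw])

    @classmethod
    def default(cls) -> "ReferenceDistribution":
        """The published control-group distribution."""
        return cls(*DEFAULT_CONTROL_MEANS, source="default")


@dataclass(frozen=True)
class GpqiResult:
    gpqi: float
    per_side_distance: tuple[float, float]
    basis: str = "trial_mean"

    def __post_init__(self) -> None:
        if self.gpqi < 0:
            raise ValueError("GPQI is non-negative by construction")


def _side_distance(vec, ref: ReferenceDistribution) -> float:
    v = np.asarray(vec, dtype=float)
    if v.shape != (4,):
        raise ValueError("phase vector must have 4 components")
    # tolerate printed-rounding slack: published group means sum to 100.2
    if abs(v.sum() - 100.0) > 0.5:
        raise ValueError(f"phase vector must sum to ~100, got {v.sum():.6f}")
    return float(np.linalg.norm(v - ref.as_array()))


def gpqi(left, right, ref: ReferenceDistribution | None = None) -> GpqiResult:
    """GPQI from one phase-percentage 4-vector per side.

    Each vector must sum to 100 (within 1e-6).  The index is the sum of
    the two per-side Euclidean distances to the reference means.
    """
    ref = ref or ReferenceDistribution.default()
    d = (_side_distance(left, ref), _side_distance(right, ref))
    return GpqiResult(gpqi=d[0] + d[1], per_side_distance=d)


def gpqi_trial(strides_left: list[StridePhases],
               strides_right: list[StridePhases],
               ref: ReferenceDistribution | None = None,
               basis: str = "trial_mean") -> GpqiResult:
    """GPQI for a trial from per-side stride tables.

    ``basis='trial_mean'`` (default) feeds the per-side trial-mean
    percentages to :func:`gpqi`; ``basis='per_stride'`` pairs strides by
    temporal index, computes GPQI per pair and averages (mismatched stride
    counts truncate to the shorter side with a warning).
    """
    import warnings

    ref = ref or ReferenceDistribution.default()
    if not strides_left or not strides_right:
        raise ValueError("both sides need at least one stride")
    if basis == "trial_mean":
        left = mean_percentages(strides_left)
        right = mean_percentages(strides_right)
        return gpqi(left, right, ref)
    if basis == "per_stride":
        n = min(len(strides_left), len(strides_right))
        if len(strides_left) != len(strides_right):
            warnings.warn(
                f"stride counts differ ({len(strides_left)} vs "
                f"{len(strides_right)}); truncating to {n}", stacklevel=2)
        per_pair = [gpqi(strides_left[k].percentages,
                         strides_right[k].percentages, ref)
                    for k in range(n)]
        dl = float(np.mean([p.per_side_distance[0] for p in per_pair]))
        dr = float(np.mean([p.per_side_distance[1] for p in per_pair]))
        return GpqiResult(gpqi=float(np.mean([p.gpqi for p in per_pair])),
                          per_side_distance=(dl, dr), basis="per_stride")
    raise ValueError(f"unknown basis {basis!r}")


def control_reference(trials: list[list[StridePhases]]
                      ) -> ReferenceDistribution:
    """Reference distribution computed from healthy trials: the grand mean
    over trials of per-trial mean percentages, sides pooled."""
    if not trials:
        raise ValueError("need at least one healthy trial")
    means = np.array([mean_percentages(t) for t in trials])
    m = means.mean(axis=0)
    return ReferenceDistribution(*[float(v) for v in m], source="computed")


@dataclass(frozen=True)
class ReliabilityResult:
    icc: float
    sem: float
    mdc95: float
    k: int
    reliability_class: str


def _reliability_class(icc: float) -> str:
    if icc < 0.40:
        return "poor"
    if icc < 0.60:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


def icc_3k(measurements) -> ReliabilityResult:
    """ICC(3,k), SEM and MDC95 from a subjects x trials matrix.

    The two-way mixed, consistency, average-measures intraclass
    correlation is computed from the subjects-by-trials ANOVA
    decomposition: ICC = (MS_subjects - MS_error) / MS_subjects.
    SEM = SD(subject means) * sqrt(1 - ICC); MDC95 = 1.96 * sqrt(2) * SEM.
    A matrix with no variance at all is defined as perfectly reliable
    (ICC = 1, SEM = 0).
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise ValueError("measurements must be a 2-D subjects x trials matrix")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 trials")
    if np.any(~np.isfinite(x)):
        raise ValueError("missing cells are not supported")
    grand = x.mean()
    subj_means = x.mean(axis=1)
    trial_means = x.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_trial = n * np.sum((trial_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_trial
    ms_subj = ss_subj / (n - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    if ms_subj <= 0:
        # degenerate: no between-subject variance
        icc = 1.0 if ss_total == 0 else 0.0
    else:
        icc = float((ms_subj - ms_err) / ms_subj)
    sd_between = float(np.std(subj_means, ddof=1))
    sem = sd_between * np.sqrt(max(0.0, 1.0 - icc))
    mdc95 = 1.96 * np.sqrt(2.0) * sem
    return ReliabilityResult(icc=icc, sem=float(sem), mdc95=float(mdc95),
                             k=k, reliability_class=_reliability_class(icc))
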