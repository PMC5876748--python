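"""Scalar continuous-HMM gait segmentation over the four phases.

The model is a 4-state hidden Markov model whose states are the gait
phases in cyclic order LR -> FF -> PS -> Sw -> LR.  The transition matrix
has left-right cyclic structure (a state may only persist or advance to
its successor; the cycle closes so whole multi-stride trials decode
continuously), the initial distribution is uniform over the phases, and
each state emits the low-pass filtered sagittal angular velocity through a
mixture of scalar Gaussians (three components per state by default: the
within-phase velocity distributions, swing especially, are multimodal, and
single-Gaussian states bias decoded boundaries).  An emission SD floor
(10 deg/s by default) keeps EM from collapsing onto the quasi-constant
flat-foot segment and from drifting boundaries away from the footswitch
event semantics.

Training is supervised moment initialization from footswitch-referenced
labels followed by Baum-Welch (EM with scaled forward-backward); decoding
is Viterbi, with a causal forward-filtering variant for online use.  Two
training regimes are provided: subject-specific (train on two of a
subject's three trials, decode the held-out one, rotating folds) and
standard (pool a control group's trials once, decode anyone without
retraining).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .phases import PhaseSequence, labels_to_events
from .signals import (
    EVAL_RATE_HZ,
    ImuRecording,
    UniformSeries,
    butter_lowpass,
    resample,
    sagittal_gyro,
)

N_STATES = 4

#: allowed transitions: self-loops and the cyclic successor
STRUCTURE_MASK = np.eye(N_STATES, dtype=bool) \
    | np.eye(N_STATES, k=1, dtype=bool) | np.eye(N_STATES, k=-(N_STATES - 1),
                                                 dtype=bool)


@dataclass
class HmmModel:
    """Parameters of the 4-state left-right cyclic scalar Gaussian HMM.

    ``weights``, ``means`` and ``sds`` are (4, n_mix) arrays; ``A`` rows sum
    to one with zeros outside the cyclic structure; ``pi`` is uniform by
    default.
    """

    A: np.ndarray
    pi: np.ndarray
    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.sds = np.atleast_2d(np.asarray(self.sds, dtype=float))
        if self.A.shape != (N_STATES, N_STATES):
            raise ValueError("A must be 4x4")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("rows of A must sum to 1")
        if np.any(self.A[~STRUCTURE_MASK] != 0.0):
            raise ValueError("A violates the left-right cyclic structure")
        if self.weights.shape != self.means.shape or \
                self.means.shape != self.sds.shape:
            raise ValueError("mixture parameter shapes must match")
        if not np.allclose(self.weights.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("mixture weights must sum to 1 per state")
        if np.any(self.sds <= 0):
            raise ValueError("emission SDs must be positive")

    @property
    def n_mix(self) -> int:
        return self.means.shape[1]

    def log_emissions(self, x: np.ndarray) -> np.ndarray:
        """Log p(x_t | state i) for all t, i -> (T, 4)."""
        x = np.asarray(x, dtype=float)[:, None, None]
        comp = (-0.5 * ((x - self.means) / self.sds) ** 2
                - np.log(self.sds) - 0.5 * np.log(2 * np.pi)
                + np.log(self.weights))
        m = comp.max(axis=2)
        return m + np.log(np.exp(comp - m[..., None]).sum(axis=2))

    def to_json(self) -> str:
        return json.dumps({
            "A": self.A.tolist(), "pi": self.pi.tolist(),
            "weights": self.weights.tolist(), "means": self.means.tolist(),
            "sds": self.sds.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "HmmModel":
        d = json.loads(text)
        return cls(A=np.asarray(d["A"]), pi=np.asarray(d["pi"]),
                   weights=np.asarray(d["weights"]),
                   means=np.asarray(d["means"]), sds=np.asarray(d["sds"]))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "HmmModel":
        return cls.from_json(Path(path).read_text())


@dataclass
class TrainReport:
    log_likelihood: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


class TrainingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Supervised initialization


def init_supervised(signal: UniformSeries | np.ndarray,
                    labels: PhaseSequence | np.ndarray,
                    n_mix: int = 1, sd_floor: float = 1.0) -> HmmModel:
    """Initialize model parameters from a labeled signal.

    Emission means/SDs are per-phase moments (``n_mix=1``) or a per-phase
    1-D k-means split (``n_mix>1``).  Self-transition probabilities follow
    the mean phase duration: a_ii = 1 - 1/(mean duration in samples), with
    the remaining mass on the cyclic successor.  The initial distribution
    is uniform.
    """
    x = signal.samples if isinstance(signal, UniformSeries) else \
        np.asarray(signal, dtype=float)
    lab = labels.labels if isinstance(labels, PhaseSequence) else \
        np.asarray(labels)
    n = min(x.size, lab.size)
    x, lab = x[:n], lab[:n]
    weights = np.zeros((N_STATES, n_mix))
    means = np.zeros((N_STATES, n_mix))
    sds = np.ones((N_STATES, n_mix))
    A = np.zeros((N_STATES, N_STATES))
    for i in range(N_STATES):
        xi = x[lab == i]
        if xi.size == 0:
            raise TrainingError(
                f"phase {('LR', 'FF', 'PS', 'Sw')[i]} absent from labels")
        if n_mix == 1:
            weights[i, 0] = 1.0
            means[i, 0] = xi.mean()
            sds[i, 0] = max(xi.std(), sd_floor)
        else:
            w, mu, sd = _kmeans_1d(xi, n_mix, sd_floor)
            weights[i], means[i], sds[i] = w, mu, sd
        # mean run length of phase i in samples
        runs = _run_lengths(lab, i)
        mean_dur = float(np.mean(runs)) if runs else 1.0
        a_ii = max(0.0, 1.0 - 1.0 / max(mean_dur, 1.0))
        A[i, i] = a_ii
        A[i, (i + 1) % N_STATES] = 1.0 - a_ii
    pi = np.full(N_STATES, 1.0 / N_STATES)
    return HmmModel(A=A, pi=pi, weights=weights, means=means, sds=sds)


def _run_lengths(labels: np.ndarray, state: int) -> list[int]:
    mask = np.concatenate([[False], labels == state, [False]]).astype(np.int8)
    starts = np.flatnonzero(np.diff(mask) == 1)
    stops = np.flatnonzero(np.diff(mask) == -1)
    return (stops - starts).tolist()


def _kmeans_1d(x: np.ndarray, k: int, sd_floor: float
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic 1-D k-means seeded from quantiles."""
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    for _ in range(50):
        assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array([x[assign == m].mean() if np.any(assign == m)
                        else centers[m] for m in range(k)])
        if np.allclose(new, centers):
            break
        centers = new
    assign = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
    w = np.array([max(np.mean(assign == m), 1e-6) for m in range(k)])
    w /= w.sum()
    sd = np.array([max(x[assign == m].std(), sd_floor) if np.any(assign == m)
                   else sd_floor for m in range(k)])
    return w, centers, sd


# ---------------------------------------------------------------------------
# Forward-backward / Baum-Welch


def _scaled_forward_backward(model: HmmModel, x: np.ndarray):
    """Scaled alpha/beta passes; returns (alpha, beta, scale, B, loglik)."""
    logB = model.log_emissions(x)
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    T = x.size
    alpha = np.empty((T, N_STATES))
    scale = np.empty(T)
    a = model.pi * B[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    A = model.A
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        s = a.sum()
        if not np.isfinite(s) or s <= 0:
            raise TrainingError(f"degenerate likelihood at sample {t}")
        scale[t] = s
        alpha[t] = a / s
    beta = np.empty((T, N_STATES))
    beta[T - 1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / scale[t + 1]
    loglik = float(np.log(scale).sum() + shift.sum())
    return alpha, beta, scale, B, loglik


def baum_welch(model: HmmModel, signals: list[UniformSeries | np.ndarray],
               tol: float = 1e-4, max_iter: int = 100, sd_floor: float = 1.0,
               freeze_transitions: bool = False
               ) -> tuple[HmmModel, TrainReport]:
    """Baum-Welch EM over one or more observation sequences.

    Stops when the total log-likelihood changes by less than ``tol`` or
    after ``max_iter`` iterations.  Structural zeros of the transition
    matrix and the emission SD floor are enforced at every M-step; the
    initial distribution stays uniform (a fixed model choice, not
    re-estimated).
    """
    if not signals:
        raise TrainingError("need at least one training sequence")
    xs = [s.samples if isinstance(s, UniformSeries) else
          np.asarray(s, dtype=float) for s in signals]
    model = HmmModel(model.A.copy(), model.pi.copy(), model.weights.copy(),
                     model.means.copy(), model.sds.copy())
    report = TrainReport()
    prev_ll = -np.inf
    for it in range(1, max_iter + 1):
        xi_sum = np.zeros((N_STATES, N_STATES))
        gamma_trans = np.zeros(N_STATES)
        r_sum = np.zeros_like(model.weights)
        rx_sum = np.zeros_like(model.weights)
        rxx_sum = np.zeros_like(model.weights)
        gamma_tot = np.zeros(N_STATES)
        total_ll = 0.0
        for x in xs:
            alpha, beta, scale, B, ll = _scaled_forward_backward(model, x)
            total_ll += ll
            gamma = alpha * beta
            gamma /= gamma.sum(axis=1, keepdims=True)
            xi_sum += model.A * (alpha[:-1].T
                                 @ (B[1:] * beta[1:] / scale[1:, None]))
            gamma_trans += gamma[:-1].sum(axis=0)
            gamma_tot += gamma.sum(axis=0)
            # mixture responsibilities r[t, i, m]
            comp = (-0.5 * ((x[:, None, None] - model.means)
                            / model.sds) ** 2
                    - np.log(model.sds) + np.log(model.weights))
            comp -= comp.max(axis=2, keepdims=True)
            comp = np.exp(comp)
            comp /= comp.sum(axis=2, keepdims=True)
            r = gamma[:, :, None] * comp
            r_sum += r.sum(axis=0)
            rx_sum += (r * x[:, None, None]).sum(axis=0)
            rxx_sum += (r * x[:, None, None] ** 2).sum(axis=0)
        report.log_likelihood.append(total_ll)
        report.n_iter = it
        if not freeze_transitions:
            A_new = np.where(STRUCTURE_MASK, xi_sum, 0.0)
            rows = A_new.sum(axis=1, keepdims=True)
            rows[rows == 0] = 1.0
            model.A = A_new / rows
        denom = np.maximum(r_sum, 1e-12)
        model.means = rx_sum / denom
        var = rxx_sum / denom - model.means ** 2
        model.sds = np.sqrt(np.maximum(var, sd_floor ** 2))
        model.weights = r_sum / np.maximum(
            r_sum.sum(axis=1, keepdims=True), 1e-12)
        if abs(total_ll - prev_ll) <= tol:
            report.converged = True
            break
        prev_ll = total_ll
    return model, report


# ---------------------------------------------------------------------------
# Decoding


def viterbi_path(model: HmmModel, x: np.ndarray) -> np.ndarray:
    """Maximum-probability state path (log space, ties to lower index)."""
    logB = model.log_emissions(x)
    with np.errstate(divide="ignore"):
        logA = np.log(model.A)
        logpi = np.log(model.pi)
    T = x.size
    delta = logpi + logB[0]
    back = np.zeros((T, N_STATES), dtype=np.int8)
    for t in range(1, T):
        cand = delta[:, None] + logA
        back[t] = np.argmax(cand, axis=0)  # first max -> lower state index
        delta = cand[back[t], np.arange(N_STATES)] + logB[t]
    path = np.empty(T, dtype=np.int8)
    path[T - 1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def viterbi(model: HmmModel, signal: UniformSeries) -> PhaseSequence:
    """Decode a signal into a phase sequence with events at label changes."""
    path = viterbi_path(model, signal.samples)
    events, flagged = labels_to_events(path, signal.rate, signal.t0)
    return PhaseSequence(labels=path, rate=signal.rate, t0=signal.t0,
                         events=events, flagged=flagged)


def forward_filter(model: HmmModel, x: np.ndarray) -> np.ndarray:
    """Causal filtered posteriors p(state_t | x_1..t) -> (T, 4)."""
    logB = model.log_emissions(x)
    B = np.exp(logB - logB.max(axis=1, keepdims=True))
    T = x.size
    post = np.empty((T, N_STATES))
    a = model.pi * B[0]
    post[0] = a / a.sum()
    for t in range(1, T):
        a = (post[t - 1] @ model.A) * B[t]
        post[t] = a / a.sum()
    return post


def decode_online(model: HmmModel, signal: UniformSeries
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Causal per-sample decoding: argmax of the filtered posterior.

    Returns (labels, posteriors).  This is an online approximation to
    Viterbi: no future evidence is used, so boundaries may lag slightly.
    """
    post = forward_filter(model, signal.samples)
    return np.argmax(post, axis=1).astype(np.int8), post


# ---------------------------------------------------------------------------
# Estimator and training regimes


def hmm_feature(rec: ImuRecording | UniformSeries, lowpass_hz: float = 17.0,
                axis: int | None = None, flip_sign: bool = False,
                eval_rate: float = EVAL_RATE_HZ) -> UniformSeries:
    """The scalar HMM input: low-pass filtered sagittal angular velocity on
    the evaluation grid."""
    series = sagittal_gyro(rec, axis=axis, flip_sign=flip_sign) \
        if isinstance(rec, ImuRecording) else rec
    if abs(series.rate - eval_rate) > 1e-9:
        series = resample(series, eval_rate, mode="linear")
    return butter_lowpass(series, lowpass_hz)


class HmmSegmenter(BaseEstimator):
    """Scalar continuous-HMM gait segmenter (sklearn-style).

    ``fit(X, y)`` takes a list of recordings (or angular-velocity series)
    and their reference :class:`~gaitphase.phases.PhaseSequence` labels;
    ``predict`` Viterbi-decodes new recordings.  Fitted attributes:
    ``model_`` (the trained :class:`HmmModel`) and ``report_`` (the EM
    trace).
    """

    def __init__(self, n_mix: int = 3, lowpass_hz: float = 17.0,
                 sd_floor: float = 10.0, tol: float = 1e-4, max_iter: int = 100,
                 freeze_transitions: bool = False, axis: int | None = None,
                 flip_sign: bool = False, eval_rate: float = EVAL_RATE_HZ):
        self.n_mix = n_mix
        self.lowpass_hz = lowpass_hz
        self.sd_floor = sd_floor
        self.tol = tol
        self.max_iter = max_iter
        self.freeze_transitions = freeze_transitions
        self.axis = axis
        self.flip_sign = flip_sign
        self.eval_rate = eval_rate

    def _feature(self, rec) -> UniformSeries:
        return hmm_feature(rec, self.lowpass_hz, self.axis, self.flip_sign,
                           self.eval_rate)

    def fit(self, X, y):
        """Supervised initialization on pooled (signal, labels) pairs, then
        Baum-Welch refinement over the individual sequences."""
        if not isinstance(X, (list, tuple)):
            X, y = [X], [y]
        if len(X) != len(y):
            raise ValueError("X and y must have equal length")
        feats = [self._feature(rec) for rec in X]
        pooled_x, pooled_lab = [], []
        for f, seq in zip(feats, y):
            lab = seq.labels if isinstance(seq, PhaseSequence) else \
                np.asarray(seq)
            n = min(len(f), lab.size)
            pooled_x.append(f.samples[:n])
            pooled_lab.append(lab[:n])
        init = init_supervised(np.concatenate(pooled_x),
                               np.concatenate(pooled_lab),
                               n_mix=self.n_mix, sd_floor=self.sd_floor)
        self.model_, self.report_ = baum_welch(
            init, feats, tol=self.tol, max_iter=self.max_iter,
            sd_floor=self.sd_floor,
            freeze_transitions=self.freeze_transitions)
        return self

    def predict(self, X):
        if isinstance(X, (list, tuple)):
            return [self._predict_one(rec) for rec in X]
        return self._predict_one(X)

    def _predict_one(self, rec) -> PhaseSequence:
        if not hasattr(self, "model_"):
            raise RuntimeError("HmmSegmenter is not fitted")
        return viterbi(self.model_, self._feature(rec))

    def predict_online(self, rec) -> tuple[np.ndarray, np.ndarray]:
        """Causal decoding of one recording; see :func:`decode_online`."""
        if not hasattr(self, "model_"):
            raise RuntimeError("HmmSegmenter is not fitted")
        return decode_online(self.model_, self._feature(rec))


def train_sst(trials: list[tuple], held_out: int, **kwargs
              ) -> tuple[HmmSegmenter, PhaseSequence]:
    """Subject-specific training: fit on two of a subject's three labeled
    trials and decode the held-out one.

    ``trials`` is a list of exactly three ``(recording, reference)`` pairs;
    ``held_out`` indexes the test trial.  Keyword arguments are forwarded
    to :class:`HmmSegmenter`.
    """
    if len(trials) != 3:
        raise ValueError(f"subject-specific training needs exactly 3 trials, "
                         f"got {len(trials)}")
    if not 0 <= held_out < 3:
        raise ValueError("held_out must be 0, 1 or 2")
    train = [trials[i] for i in range(3) if i != held_out]
    seg = HmmSegmenter(**kwargs).fit([t[0] for t in train],
                                     [t[1] for t in train])
    return seg, seg.predict(trials[held_out][0])


def sst_folds(trials: list[tuple], **kwargs
              ) -> list[tuple[HmmSegmenter, PhaseSequence]]:
    """Rotate :func:`train_sst` over all three leave-one-trial-out folds."""
    return [train_sst(trials, k, **kwargs) for k in range(3)]


def train_spt(control_trials: list[tuple], **kwargs) -> HmmSegmenter:
    """Standard training: fit once on a pooled control group's labeled
    trials; the returned segmenter decodes any trial without retraining."""
    if not control_trials:
        raise ValueError("control-group training pool is empty")
    return HmmSegmenter(**kwargs).fit([t[0] for t in control_trials],
                                      [t[1] for t in control_trials])
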