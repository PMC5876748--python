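"""End-to-end harness: synthetic cohorts -> segmentation -> evaluation.

This module wires the stages together the way a study would run them:
generate (or load) trials, build the footswitch reference, run the four
segmenters, score each against the reference inside the span of retained
strides (the first and last three cycles are discarded as acceleration /
deceleration effects), and aggregate Goodness-index, phase-error and GPQI
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detectors import RMethodSegmenter, SMethodSegmenter
from .evaluation import (
    EvalConfig,
    EvalResult,
    evaluate_sequences,
    phase_errors,
    roc_auc,
)
from .gpqi import ReferenceDistribution, control_reference, gpqi_trial, icc_3k
from .hmm import train_spt, train_sst
from .phases import PhaseSequence
from .reference import label_phases, segment_strides
from .signals import FootswitchRecording, ImuRecording, Side
from .simulate import (GaitProfile, GroundTruth, generate_trial, preset,
                       subject_profile)

METHODS = ("s_method", "r_method", "hmm_sst", "hmm_spt")

#: EM iteration cap used by the cohort harnesses; with supervised
#: initialization the likelihood is near-converged well before this
HARNESS_MAX_ITER = 25


@dataclass
class Trial:
    """One simulated (or loaded) trial with its footswitch reference."""

    imu: ImuRecording
    fsw: FootswitchRecording
    truth: GroundTruth | None
    reference: PhaseSequence

    @property
    def side(self) -> Side:
        return self.imu.side


def make_trial(imu: ImuRecording, fsw: FootswitchRecording,
               truth: GroundTruth | None = None,
               debounce_ms: float = 20.0) -> Trial:
    return Trial(imu=imu, fsw=fsw, truth=truth,
                 reference=label_phases(fsw, debounce_ms=debounce_ms))


def _seed_sequence(seed) -> np.random.SeedSequence:
    return seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)


def make_cohort(profile: GaitProfile, n_trials: int, n_strides: int,
                seed) -> list[Trial]:
    """Generate a seeded cohort of independent single-foot trials."""
    seqs = _seed_sequence(seed).spawn(n_trials)
    out = []
    for ss in seqs:
        rng = np.random.default_rng(ss)
        imu, fsw, truth = generate_trial(profile, n_strides, rng=rng)
        out.append(make_trial(imu, fsw, truth))
    return out


def reference_window(reference: PhaseSequence, discard_ends: int = 3
                     ) -> tuple[float, float]:
    """Time span of the retained strides of the reference sequence."""
    strides = segment_strides(reference, discard_ends=discard_ends)
    return strides[0].bounds[0], strides[-1].bounds[1]


def score_sequence(trial: Trial, predicted: PhaseSequence,
                   cfg: EvalConfig | None = None,
                   discard_ends: int = 3) -> EvalResult:
    """Score a predicted sequence against the trial's footswitch reference
    within the retained-stride window."""
    window = reference_window(trial.reference, discard_ends)
    return evaluate_sequences(trial.reference, predicted, cfg, window=window)


def healthy_benchmark(seed, n_trials: int = 20, n_strides: int = 30,
                      n_train: int = 10,
                      profile: GaitProfile | None = None) -> dict:
    """Train/test benchmark of S-method, R-method and the standard-trained
    HMM on a seeded healthy cohort.

    The cohort is split into ``n_train`` training trials (used only to fit
    the pooled-control HMM) and the rest as test trials; all three methods
    are scored on the same test trials.  Returns per-method per-trial G
    lists and their means.
    """
    profile = profile or preset("healthy")
    cohort = make_cohort(profile, n_trials, n_strides, seed)
    train, test = cohort[:n_train], cohort[n_train:]
    spt = train_spt([(t.imu, t.reference) for t in train],
                    max_iter=HARNESS_MAX_ITER)
    segmenters = {
        "s_method": SMethodSegmenter().fit(),
        "r_method": RMethodSegmenter().fit(),
        "hmm_spt": spt,
    }
    results: dict = {name: {"G": [], "TPR": [], "TNR": []}
                     for name in segmenters}
    for trial in test:
        for name, seg in segmenters.items():
            res = score_sequence(trial, seg.predict(trial.imu))
            results[name]["G"].append(res.G)
            results[name]["TPR"].append(res.TPR)
            results[name]["TNR"].append(res.TNR)
    for name in results:
        results[name]["mean_G"] = float(np.mean(results[name]["G"]))
        results[name]["mean_TPR"] = float(np.mean(results[name]["TPR"]))
        results[name]["mean_TNR"] = float(np.mean(results[name]["TNR"]))
    results["n_test"] = len(test)
    return results


def sst_benchmark(seed, n_subjects: int = 5, n_strides: int = 30,
                  profile: GaitProfile | None = None) -> dict:
    """Leave-one-trial-out benchmark of the subject-specific HMM.

    Each synthetic subject contributes three trials; the segmenter is
    trained on two and scored on the held-out one, rotating all folds.
    """
    profile = profile or preset("healthy")
    subject_seeds = _seed_sequence(seed).spawn(n_subjects)
    gs = []
    for ss in subject_seeds:
        rng = np.random.default_rng(ss)
        trials = [make_trial(*generate_trial(profile, n_strides, rng=rng)[:2])
                  for _ in range(3)]
        for held_out in range(3):
            _, decoded = train_sst(
                [(t.imu, t.reference) for t in trials], held_out,
                max_iter=HARNESS_MAX_ITER)
            gs.append(score_sequence(trials[held_out], decoded).G)
    return {"G": gs, "mean_G": float(np.mean(gs)), "n_folds": len(gs)}


def bilateral_trial_gpqi(profile: GaitProfile, n_strides: int,
                         rng: np.random.Generator,
                         ref: ReferenceDistribution,
                         discard_ends: int = 3) -> float:
    """GPQI of one bilateral trial, from the footswitch reference."""
    sides = {}
    for side in (Side.LEFT, Side.RIGHT):
        imu, fsw, truth = generate_trial(profile, n_strides, side=side,
                                         rng=rng)
        seq = label_phases(fsw)
        sides[side] = segment_strides(seq, discard_ends=discard_ends)
    return gpqi_trial(sides[Side.LEFT], sides[Side.RIGHT], ref).gpqi


def gpqi_group_report(seed, n_per_group: int = 10, n_strides: int = 20
                      ) -> dict:
    """GPQI comparison of healthy vs parkinsonian-like synthetic cohorts.

    Computes per-trial GPQI against the control reference computed from
    the healthy cohort itself, the group AUCs, and the healthy-cohort
    test-retest reliability across three repeated trials per subject.
    """
    root = _seed_sequence(seed)
    ss_by_group = dict(zip(("healthy", "pd_mild", "pd_severe"),
                           root.spawn(3)))
    # control reference from the healthy cohort's stride tables
    healthy_rng = np.random.default_rng(ss_by_group["healthy"])
    healthy_tables = []
    for _ in range(n_per_group):
        _, fsw, _ = generate_trial(preset("healthy"), n_strides,
                                   rng=healthy_rng)
        healthy_tables.append(segment_strides(label_phases(fsw)))
    ref = control_reference(healthy_tables)

    scores = {}
    for name, ss in ss_by_group.items():
        rng = np.random.default_rng(ss)
        # one synthetic subject per trial: stable traits + per-stride jitter
        scores[name] = [
            bilateral_trial_gpqi(subject_profile(preset(name), rng),
                                 n_strides, rng, ref)
            for _ in range(n_per_group)]

    # reliability: subjects x 3 repeated trials, traits fixed per subject
    rel_rng = np.random.default_rng(root.spawn(1)[0])
    matrix = np.array([
        [bilateral_trial_gpqi(subj, n_strides, rel_rng, ref)
         for _ in range(3)]
        for subj in (subject_profile(preset("healthy"), rel_rng)
                     for _ in range(max(5, n_per_group // 2)))])
    rel = icc_3k(matrix)
    return {
        "reference": ref,
        "gpqi": scores,
        "auc_mild_vs_healthy": roc_auc(scores["pd_mild"], scores["healthy"]),
        "auc_severe_vs_healthy": roc_auc(scores["pd_severe"],
                                         scores["healthy"]),
        "icc": rel.icc,
        "mdc95": rel.mdc95,
    }


def run_pipeline(seed: int, n_trials: int = 6, n_strides: int = 20,
                 n_subjects_sst: int = 2) -> dict:
    """Full replication harness on synthetic cohorts.

    For each preset (healthy, pd_mild, pd_severe) and each of the four
    methods, reports mean TPR, TNR, G, the performance class and the mean
    per-phase absolute errors — one row per (method, preset) — plus the
    GPQI group report.  Deterministic given ``seed``.
    """
    root = np.random.SeedSequence(seed)
    ss_train, ss_cohorts, ss_sst, ss_gpqi = root.spawn(4)

    # pooled-control HMM trained once on a healthy pool
    train_pool = make_cohort(preset("healthy"), n_trials, n_strides,
                             ss_train)
    spt = train_spt([(t.imu, t.reference) for t in train_pool],
                    max_iter=HARNESS_MAX_ITER)

    rows = []
    cohort_seeds = ss_cohorts.spawn(3)
    sst_seeds = ss_sst.spawn(3)
    for (name, c_ss, s_ss) in zip(("healthy", "pd_mild", "pd_severe"),
                                  cohort_seeds, sst_seeds):
        profile = preset(name)
        cohort = make_cohort(profile, n_trials, n_strides, c_ss)
        per_method: dict = {m: [] for m in METHODS}
        err_rows: dict = {m: [] for m in METHODS}
        rule_based = {"s_method": SMethodSegmenter().fit(),
                      "r_method": RMethodSegmenter().fit(),
                      "hmm_spt": spt}
        for trial in cohort:
            for m, seg in rule_based.items():
                pred = seg.predict(trial.imu)
                per_method[m].append(score_sequence(trial, pred))
                err_rows[m].append(_safe_phase_errors(trial, pred))
        # subject-specific folds on dedicated 3-trial subjects
        subj_seeds = s_ss.spawn(n_subjects_sst)
        for ss in subj_seeds:
            rng = np.random.default_rng(ss)
            trials = [make_trial(
                *generate_trial(profile, n_strides, rng=rng)[:2])
                for _ in range(3)]
            for held_out in range(3):
                _, decoded = train_sst(
                    [(t.imu, t.reference) for t in trials], held_out,
                    max_iter=HARNESS_MAX_ITER)
                per_method["hmm_sst"].append(
                    score_sequence(trials[held_out], decoded))
                err_rows["hmm_sst"].append(
                    _safe_phase_errors(trials[held_out], decoded))
        for m in METHODS:
            res = per_method[m]
            errs = np.array([e for e in err_rows[m] if e is not None])
            from .evaluation import goodness
            mean_tpr = float(np.mean([r.TPR for r in res]))
            mean_tnr = float(np.mean([r.TNR for r in res]))
            mean_g = float(np.mean([r.G for r in res]))
            rows.append({
                "preset": name, "method": m, "n": len(res),
                "TPR": mean_tpr, "TNR": mean_tnr, "G": mean_g,
                "class": goodness(mean_tpr, mean_tnr)[1],
                "LR_e": float(np.mean(errs[:, 0])) if errs.size else np.nan,
                "FF_e": float(np.mean(errs[:, 1])) if errs.size else np.nan,
                "PS_e": float(np.mean(errs[:, 2])) if errs.size else np.nan,
                "Sw_e": float(np.mean(errs[:, 3])) if errs.size else np.nan,
            })
    summary = pd.DataFrame(rows)
    gpqi_report = gpqi_group_report(ss_gpqi,
                                    n_per_group=n_trials,
                                    n_strides=n_strides)
    return {"summary": summary, "gpqi": gpqi_report}


def _safe_phase_errors(trial: Trial, predicted: PhaseSequence):
    """Per-phase absolute errors, or None when the predicted sequence has
    too few clean strides to segment."""
    try:
        ref_strides = segment_strides(trial.reference)
        pred_strides = segment_strides(predicted)
        e = phase_errors(ref_strides, pred_strides)
        return e.as_array()
    except Exception:
        return None
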