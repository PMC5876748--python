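"""Transition matching, sensitivity/specificity, Goodness index, AUC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gaitphase.evaluation import (
    EvalConfig,
    GridMismatchError,
    UndefinedRateError,
    evaluate_sequences,
    goodness,
    match_transitions,
    phase_errors,
    rates,
    roc_auc,
)
from gaitphase.gpqi import ReferenceDistribution
from gaitphase.phases import (
    EventType,
    GaitEvent,
    PhaseSequence,
    StridePhases,
    sequence_from_events,
)


def seq_from(times_by_type: dict, duration_s: float = 10.0,
             rate: float = 200.0) -> PhaseSequence:
    events = [GaitEvent(t, EventType(k)) for k, ts in times_by_type.items()
              for t in ts]
    return sequence_from_events(sorted(events), int(duration_s * rate) + 1,
                                rate)


def stride_cycle(*hs_times):
    """Canonical HS/TS/HO/TO cycles starting at each given heel strike."""
    out = {"HS": [], "TS": [], "HO": [], "TO": []}
    for hs in hs_times:
        out["HS"].append(hs)
        out["TS"].append(hs + 0.075)
        out["HO"].append(hs + 0.5)
        out["TO"].append(hs + 0.68)
    return out


class TestMatchTransitions:
    def test_prediction_inside_window_is_tp(self):
        ref = seq_from(stride_cycle(1.0, 2.0, 3.0))
        shifted = {k: [t + 0.025 for t in v]
                   for k, v in stride_cycle(1.0, 2.0, 3.0).items()}
        counts = match_transitions(ref, seq_from(shifted))
        assert counts.FN == 0 and counts.FP == 0
        assert counts.TP == 12

    def test_prediction_outside_window_is_fp_and_fn(self):
        ref = seq_from({"HS": [1.0]})
        pred = seq_from({"HS": [1.040]})  # 40 ms > half-window
        counts = match_transitions(ref, pred)
        assert (counts.TP, counts.FP, counts.FN) == (0, 1, 1)

    def test_identity_gives_perfect_rates(self, noisy_trial):
        res = evaluate_sequences(noisy_trial.reference, noisy_trial.reference)
        assert res.TPR == 1.0 and res.TNR == 1.0 and res.G == 0.0
        assert res.performance_class == "optimum"

    def test_types_are_not_cross_matched(self):
        ref = seq_from({"HS": [1.0]})
        pred = seq_from({"TS": [1.0]})
        counts = match_transitions(ref, pred)
        assert counts.TP == 0

    def test_one_to_one_matching_no_double_count(self):
        ref = seq_from({"HS": [1.0]})
        # two raw detections inside one window (bypasses canonical filter)
        pred = PhaseSequence(
            labels=np.zeros(2001, dtype=np.int8), rate=200.0,
            events=[GaitEvent(0.99, EventType.HS),
                    GaitEvent(1.01, EventType.HS)])
        counts = match_transitions(ref, pred)
        assert counts.TP == 1 and counts.FP == 1

    def test_swap_symmetry(self):
        a = seq_from(stride_cycle(1.0, 2.0))
        b = seq_from(stride_cycle(1.02, 2.3))
        ab = match_transitions(a, b)
        ba = match_transitions(b, a)
        assert (ab.TP, ab.FP, ab.FN) == (ba.TP, ba.FN, ba.FP)

    def test_window_restricts_scoring(self):
        ref = seq_from(stride_cycle(1.0, 2.0, 3.0, 4.0))
        pred = seq_from(stride_cycle(1.0, 2.0, 3.0))
        counts = match_transitions(ref, pred, window=(1.9, 3.8))
        assert counts.FN == 0  # the missing 4th cycle lies outside

    def test_grid_mismatch_rejected(self):
        a = seq_from({"HS": [1.0]}, rate=200.0)
        b = PhaseSequence(labels=np.zeros(100, dtype=np.int8), rate=100.0)
        with pytest.raises(GridMismatchError):
            match_transitions(a, b)


class TestRates:
    def test_exact_ratios(self):
        from gaitphase.evaluation import EvalCounts
        tpr, tnr = rates(EvalCounts(TP=9, TN=7, FP=3, FN=1))
        assert tpr == pytest.approx(0.9)
        assert tnr == pytest.approx(0.7)

    def test_zero_denominator_raises(self):
        from gaitphase.evaluation import EvalCounts
        with pytest.raises(UndefinedRateError):
            rates(EvalCounts(TP=0, TN=5, FP=1, FN=0))

    def test_counts_against_hand_tally(self, clean_trial):
        """Pooled TP/FN must equal a manual per-event tally."""
        from gaitphase.detectors import SMethodSegmenter
        pred = SMethodSegmenter().fit().predict(clean_trial.imu)
        counts = match_transitions(clean_trial.reference, pred)
        tally_tp = 0
        for kind in EventType:
            rt = [e.time for e in clean_trial.reference.events
                  if e.type is kind]
            pt = [e.time for e in pred.events if e.type is kind]
            used = set()
            for p in pt:
                close = [(abs(p - r), i) for i, r in enumerate(rt)
                         if abs(p - r) <= 0.030 + 1e-12 and i not in used]
                if close:
                    used.add(min(close)[1])
                    tally_tp += 1
        assert counts.TP == tally_tp


class TestGoodness:
    @pytest.mark.parametrize("tpr,tnr,expected", [
        (1.0, 1.0, 0.0),
        (0.8, 0.7, 0.36055512754639896),
        (1.0, 0.9, 0.1),
        (0.0, 0.0, np.sqrt(2)),
    ])
    def test_distance_to_perfect_corner(self, tpr, tnr, expected):
        g, _ = goodness(tpr, tnr)
        assert g == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("tpr,tnr,cls", [
        (1.0, 1.0, "optimum"), (0.95, 0.85, "optimum"),
        (0.8, 0.7, "good"), (0.5, 0.5, "random"),
    ])
    def test_performance_classes(self, tpr, tnr, cls):
        assert goodness(tpr, tnr)[1] == cls

    def test_rates_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            goodness(1.2, 0.5)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_each_rate(self, tpr, tnr, delta):
        """Raising either rate never increases G."""
        g0, _ = goodness(tpr, tnr)
        assert goodness(min(1.0, tpr + delta), tnr)[0] <= g0 + 1e-12
        assert goodness(tpr, min(1.0, tnr + delta))[0] <= g0 + 1e-12


class TestPhaseErrors:
    def strides(self, pct, n=5):
        return [StridePhases(i, (float(i), i + 1.0), np.asarray(pct, float))
                for i in range(n)]

    def test_identical_inputs_zero_error(self):
        s = self.strides([7, 40, 16, 37])
        e = phase_errors(s, s)
        assert e.as_array().tolist() == [0, 0, 0, 0]

    def test_shifted_ff_ps(self):
        ref = self.strides([7, 40, 16, 37])
        pred = self.strides([7, 42, 14, 37])
        e = phase_errors(ref, pred)
        np.testing.assert_allclose(e.as_array(), [0, 2, 2, 0], atol=1e-12)

    def test_gpqi_error_with_reference_distribution(self):
        ref = self.strides([6.9, 39.4, 16.2, 37.5])
        pred = self.strides([6.9, 42.4, 13.2, 37.5])
        e = phase_errors(ref, pred, ReferenceDistribution.default())
        anchor = ReferenceDistribution.default().as_array()
        d_ref = np.linalg.norm(np.array([6.9, 39.4, 16.2, 37.5]) - anchor)
        d_pred = np.linalg.norm(np.array([6.9, 42.4, 13.2, 37.5]) - anchor)
        assert e.GPQI_e == pytest.approx(abs(d_pred - d_ref), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            phase_errors([], self.strides([7, 40, 16, 37]))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([10, 11, 12], [1, 2, 3]) == pytest.approx(100.0)

    def test_identical_groups_are_worthless(self):
        assert roc_auc([5.0], [5.0]) == pytest.approx(50.0)

    def test_random_equal_distributions_near_50(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(size=200), rng.normal(size=200)
        assert abs(roc_auc(a, b) - 50.0) < 5.0

    def test_against_sklearn_oracle(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(21)
        a = rng.normal(1.0, 1.0, 37)
        b = rng.normal(0.0, 1.0, 29)
        y = np.concatenate([np.ones_like(a), np.zeros_like(b)])
        expected = roc_auc_score(y, np.concatenate([a, b])) * 100
        assert roc_auc(a, b) == pytest.approx(expected, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([], [1.0])
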