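"""Left-right cyclic scalar Gaussian HMM: training and decoding."""

import numpy as np
import pytest

from gaitphase.hmm import (
    HmmModel,
    HmmSegmenter,
    N_STATES,
    STRUCTURE_MASK,
    TrainingError,
    baum_welch,
    decode_online,
    forward_filter,
    hmm_feature,
    init_supervised,
    train_spt,
    train_sst,
    viterbi,
    viterbi_path,
)
from gaitphase.phases import GaitPhase
from gaitphase.pipeline import score_sequence
from gaitphase.signals import UniformSeries


from tests_helpers_hmm import brute_force_path, cyclic_model, sample_from


class TestInitSupervised:
    def test_moment_estimates_on_constant_phases(self):
        labels = np.repeat([0, 1, 2, 3], 50)
        x = np.repeat([10.0, 0.0, -20.0, 40.0], 50)
        m = init_supervised(x, labels, n_mix=1)
        np.testing.assert_allclose(m.means.ravel(), [10, 0, -20, 40])

    def test_self_transition_from_mean_duration(self):
        labels = np.tile(np.repeat([0, 1, 2, 3], 50), 4)
        x = np.random.default_rng(0).normal(size=labels.size)
        m = init_supervised(x, labels)
        np.testing.assert_allclose(np.diag(m.A), 1 - 1 / 50)

    def test_uniform_initial_distribution(self):
        m = init_supervised(np.arange(40.0), np.repeat([0, 1, 2, 3], 10))
        np.testing.assert_allclose(m.pi, 0.25)

    def test_missing_phase_errors_with_name(self):
        with pytest.raises(TrainingError, match="PS"):
            init_supervised(np.arange(30.0), np.repeat([0, 1, 3], 10))


class TestBaumWelch:
    def test_log_likelihood_monotone(self, healthy_pool):
        feats = [hmm_feature(t.imu) for t in healthy_pool[:2]]
        labels = healthy_pool[0].reference
        init = init_supervised(feats[0], labels, n_mix=2, sd_floor=10.0)
        _, rep = baum_welch(init, feats, max_iter=8, sd_floor=10.0)
        ll = rep.log_likelihood
        assert all(b >= a - 1e-6 * abs(a) for a, b in zip(ll, ll[1:]))

    def test_infinite_tol_stops_after_one_iteration(self, healthy_pool):
        f = hmm_feature(healthy_pool[0].imu)
        init = init_supervised(f, healthy_pool[0].reference, sd_floor=10.0)
        _, rep = baum_welch(init, [f], tol=np.inf, max_iter=50)
        assert rep.n_iter == 1
        assert rep.converged

    def test_parameter_recovery_from_known_model(self):
        """EM recovers emission means within 5% on self-generated data."""
        rng = np.random.default_rng(77)
        true = HmmModel(
            A=np.array([[0.93, 0.07, 0, 0], [0, 0.97, 0.03, 0],
                        [0, 0, 0.94, 0.06], [0.04, 0, 0, 0.96]]),
            pi=np.full(4, 0.25),
            weights=np.ones((4, 1)),
            means=np.array([[-80.0], [0.0], [-150.0], [250.0]]),
            sds=np.array([[20.0], [12.0], [30.0], [60.0]]))
        xs, labs = zip(*(sample_from(true, 3000, rng) for _ in range(3)))
        init = init_supervised(np.concatenate(xs), np.concatenate(labs))
        est, rep = baum_welch(init, list(xs), max_iter=50, sd_floor=1.0)
        scale = np.maximum(np.abs(true.means), 20.0)
        assert np.all(np.abs(est.means - true.means) / scale < 0.05)
        # self-transitions recovered too
        np.testing.assert_allclose(np.diag(est.A), np.diag(true.A), atol=0.02)

    def test_structure_preserved_through_training(self, trained_spt):
        m = trained_spt.model_
        np.testing.assert_allclose(m.A.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(m.A[~STRUCTURE_MASK] == 0.0)
        assert np.all(m.sds >= trained_spt.sd_floor - 1e-12)

    def test_freeze_transitions(self, healthy_pool):
        f = hmm_feature(healthy_pool[0].imu)
        init = init_supervised(f, healthy_pool[0].reference, sd_floor=10.0)
        est, _ = baum_welch(init, [f], max_iter=3, freeze_transitions=True,
                            sd_floor=10.0)
        np.testing.assert_array_equal(est.A, init.A)

    def test_empty_pool_rejected(self):
        m = cyclic_model(np.random.default_rng(0))
        with pytest.raises(TrainingError):
            baum_welch(m, [])


class TestViterbi:
    def test_equals_exhaustive_search_on_short_sequences(self):
        """Viterbi against brute-force enumeration, 30 random models."""
        rng = np.random.default_rng(123)
        for _ in range(30):
            model = cyclic_model(rng, n_mix=rng.integers(1, 3))
            x, _ = sample_from(model, 8, rng)
            fast = viterbi_path(model, x)
            slow, slow_lp = brute_force_path(model, x)
            np.testing.assert_array_equal(fast, slow)

    def test_path_respects_cyclic_structure(self, trained_spt, noisy_trial):
        path = trained_spt.predict(noisy_trial.imu).labels
        steps = (np.diff(path.astype(int)) % 4)
        assert set(np.unique(steps)) <= {0, 1}

    def test_well_separated_emissions_recover_labels(self):
        rng = np.random.default_rng(5)
        labels = np.repeat(np.tile([0, 1, 2, 3], 6), 40)
        means = np.array([[-80.0], [0.0], [-160.0], [250.0]])
        x = means[labels, 0] + rng.normal(0, 2.0, labels.size)
        m = init_supervised(x, labels, sd_floor=2.0)
        decoded = viterbi_path(m, x)
        assert np.mean(decoded == labels) > 0.999


class TestOnlineDecoding:
    def test_agreement_with_viterbi(self, trained_spt, noisy_trial):
        online, _ = trained_spt.predict_online(noisy_trial.imu)
        offline = trained_spt.predict(noisy_trial.imu).labels
        assert np.mean(online == offline) >= 0.95

    def test_posteriors_normalized(self, trained_spt, noisy_trial):
        _, post = trained_spt.predict_online(noisy_trial.imu)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-9)

    def test_first_phase_of_midswing_start_is_swing(self, trained_spt,
                                                    noisy_trial):
        feat = hmm_feature(noisy_trial.imu)
        # cut the signal at a mid-swing peak (clearly positive sample)
        start = int(np.argmax(feat.samples[:1000]))
        cut = UniformSeries(feat.samples[start:], feat.rate)
        labels, _ = decode_online(trained_spt.model_, cut)
        assert labels[0] == int(GaitPhase.SW)


class TestTrainingRegimes:
    def test_sst_contract(self, healthy_pool):
        trials = [(t.imu, t.reference) for t in healthy_pool[:3]]
        with pytest.raises(ValueError, match="3 trials"):
            train_sst(trials[:2], 0)
        seg, decoded = train_sst(trials, held_out=2, max_iter=5)
        assert hasattr(seg, "model_")
        assert len(decoded.events) > 0
        # training really used two trials: the held-out one decodes unseen
        res = score_sequence(healthy_pool[2], decoded)
        assert res.G < 0.25

    def test_sst_fold_rotation(self, healthy_pool):
        from gaitphase.hmm import sst_folds
        out = sst_folds([(t.imu, t.reference) for t in healthy_pool[:3]],
                        max_iter=3)
        assert len(out) == 3

    def test_spt_decodes_unseen_trial(self, trained_spt, healthy_pool):
        res = score_sequence(healthy_pool[4],
                             trained_spt.predict(healthy_pool[4].imu))
        assert res.G <= 0.25

    def test_spt_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            train_spt([])


class TestModelPersistence:
    def test_json_roundtrip(self, trained_spt, tmp_path):
        path = tmp_path / "model.json"
        trained_spt.model_.save(path)
        loaded = HmmModel.load(path)
        np.testing.assert_allclose(loaded.A, trained_spt.model_.A)
        np.testing.assert_allclose(loaded.means, trained_spt.model_.means)

    def test_invalid_structure_rejected(self):
        A = np.full((4, 4), 0.25)
        with pytest.raises(ValueError, match="structure"):
            HmmModel(A=A, pi=np.full(4, 0.25), weights=np.ones((4, 1)),
                     means=np.zeros((4, 1)), sds=np.ones((4, 1)))


def test_decoding_agrees_with_hmmlearn_oracle():
    """Viterbi cross-checked against an independent HMM implementation."""
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    rng = np.random.default_rng(99)
    model = cyclic_model(rng, n_mix=1)
    x, _ = sample_from(model, 400, rng)
    ref = hmmlearn.GaussianHMM(n_components=4, covariance_type="diag",
                               init_params="")
    ref.startprob_ = model.pi
    ref.transmat_ = model.A
    ref.means_ = model.means
    ref.covars_ = model.sds ** 2
    expected = ref.predict(x[:, None])
    got = viterbi_path(model, x)
    assert np.mean(got == expected) > 0.999
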