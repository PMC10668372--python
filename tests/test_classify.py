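"""Balanced forest, HMM estimation, Viterbi decoding, intensity split."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_epochs
from wristtime import classify
from wristtime.classify import (CLASSES3, BalancedRandomForest,
                                BehaviourModel, BehaviourSequence, HmmParams,
                                LabelledEpochSet, NotTrainedError,
                                confusion_matrix, estimate_hmm, predict,
                                split_intensity, train_forest, viterbi)


def separable_set(n_per_class=(200, 200, 50), sd=1.0, gap=3.0, seed=0,
                  n_features=6):
    """3-class Gaussian blobs with class means ``gap`` SDs apart."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for k, (cls, n) in enumerate(zip(CLASSES3, n_per_class)):
        X.append(rng.normal(k * gap * sd, sd, (n, n_features)))
        y += [cls] * n
    X = np.vstack(X)
    y = np.array(y)
    pid = np.zeros(len(y), dtype=int)
    return LabelledEpochSet(features=X, labels=y, participant=pid,
                            feature_names=tuple(f"f{i}" for i in range(n_features)))


def path_logprob(path_idx, obs, hmm):
    lp = np.log(hmm.prior[path_idx[0]]) + np.log(hmm.emission[path_idx[0], obs[0]])
    for t in range(1, len(obs)):
        lp += np.log(hmm.transition[path_idx[t - 1], path_idx[t]])
        lp += np.log(hmm.emission[path_idx[t], obs[t]])
    return lp


def brute_force_viterbi(obs, hmm):
    """Independent oracle: enumerate all 3^n state paths.

    Returns (best path, best log-prob, unique?) — distinct paths can tie
    exactly (same multiset of factors), in which case only optimality of
    the decoder's path is checkable, not path identity.
    """
    k = len(hmm.prior)
    best, best_lp, n_best = None, -np.inf, 0
    for path in itertools.product(range(k), repeat=len(obs)):
        lp = path_logprob(path, obs, hmm)
        if lp > best_lp + 1e-9:
            best, best_lp, n_best = path, lp, 1
        elif lp > best_lp - 1e-9:
            n_best += 1
    labels = np.array([hmm.classes[i] for i in best], dtype=object)
    return labels, best_lp, n_best == 1


def assert_viterbi_optimal(obs, hmm):
    out = viterbi(obs, hmm)
    order = {c: i for i, c in enumerate(hmm.classes)}
    out_idx = [order[v] for v in out]
    oracle, best_lp, unique = brute_force_viterbi(obs, hmm)
    assert path_logprob(out_idx, obs, hmm) >= best_lp - 1e-9
    if unique:
        assert np.array_equal(out, oracle)


def random_hmm(rng):
    prior = rng.dirichlet(np.ones(3))
    trans = rng.dirichlet(np.ones(3), size=3)
    emis = rng.dirichlet(np.ones(3), size=3)
    return HmmParams(prior=prior, transition=trans, emission=emis)


class TestBalancedForest:
    def test_separable_classes_high_oob_accuracy(self):
        ts = separable_set()
        forest = train_forest(ts, n_trees=50, seed=1)
        assert forest.oob_accuracy(ts.labels) > 0.95

    def test_bootstrap_balanced_at_minority_size(self):
        ts = separable_set(n_per_class=(300, 300, 25))
        forest = train_forest(ts, n_trees=10, seed=2)
        assert forest.per_tree_class_counts_ == 25

    def test_same_seed_identical_predictions(self):
        ts = separable_set(seed=3)
        p1 = train_forest(ts, 30, seed=9).predict(ts.features)
        p2 = train_forest(ts, 30, seed=9).predict(ts.features)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="2 classes"):
            BalancedRandomForest(10, 0).fit(np.zeros((10, 3)),
                                            np.array(["sleep"] * 10))

    def test_untrained_forest_refuses_to_predict(self):
        with pytest.raises(NotTrainedError):
            BalancedRandomForest(10, 0).predict(np.zeros((2, 3)))


class TestEstimateHmm:
    def seq_set(self, labels, pid=None):
        labels = np.array(labels)
        pid = np.zeros(len(labels), dtype=int) if pid is None else np.array(pid)
        X = np.zeros((len(labels), 2))
        return LabelledEpochSet(X, labels, pid)

    def test_all_sleep_add_one_arithmetic(self):
        ts = self.seq_set(["sleep"] * 10)
        hmm = estimate_hmm(ts, np.array(["sleep"] * 10))
        # 9 sleep->sleep transitions, add-one over 3 states: (9+1)/(9+3)
        assert hmm.transition[0, 0] == pytest.approx(10 / 12)
        assert hmm.transition[0, 1] == pytest.approx(1 / 12)

    def test_alternating_labels_off_diagonal_dominant(self):
        ts = self.seq_set(["sleep", "sedentary"] * 20)
        hmm = estimate_hmm(ts, ts.labels)
        assert hmm.transition[0, 1] > hmm.transition[0, 0]
        assert hmm.transition[1, 0] > hmm.transition[1, 1]
        assert np.argmax(hmm.emission[0]) == 0   # near-identity emission

    def test_rows_normalise_and_stay_positive(self):
        rng = np.random.default_rng(0)
        labels = rng.choice(CLASSES3, 100)
        pred = rng.choice(CLASSES3, 100)
        ts = self.seq_set(labels, pid=rng.integers(0, 3, 100))
        hmm = estimate_hmm(ts, pred)
        for mat in (hmm.transition, hmm.emission):
            assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-9)
            assert (mat > 0).all()
        assert hmm.prior.sum() == pytest.approx(1.0)
        assert (hmm.prior > 0).all()

    def test_transitions_not_counted_across_participants(self):
        ts = self.seq_set(["sleep"] * 5 + ["sedentary"] * 5,
                          pid=[0] * 5 + [1] * 5)
        hmm = estimate_hmm(ts, ts.labels)
        # no sleep->sedentary transition observed: only smoothing mass
        assert hmm.transition[0, 1] == pytest.approx(1 / (4 + 3))


class TestViterbi:
    def test_identity_emission_uniform_transitions_is_passthrough(self):
        hmm = HmmParams(prior=np.full(3, 1 / 3),
                        transition=np.full((3, 3), 1 / 3),
                        emission=np.eye(3) * 0.98 + 0.01)
        obs = np.array(["sleep", "non-sedentary", "sedentary", "sleep"])
        assert np.array_equal(viterbi(obs, hmm), obs)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            hmm = random_hmm(rng)
            obs = rng.integers(0, 3, int(rng.integers(1, 9)))
            assert_viterbi_optimal(obs, hmm)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_brute_force_property(self, seed):
        rng = np.random.default_rng(seed)
        hmm = random_hmm(rng)
        obs = rng.integers(0, 3, int(rng.integers(1, 9)))
        assert_viterbi_optimal(obs, hmm)

    def test_sticky_transitions_flip_isolated_epoch(self):
        diag = 0.98
        trans = np.full((3, 3), (1 - diag) / 2)
        np.fill_diagonal(trans, diag)
        emis = np.full((3, 3), 0.1)
        np.fill_diagonal(emis, 0.8)
        hmm = HmmParams(prior=np.full(3, 1 / 3), transition=trans,
                        emission=emis)
        obs = np.array(["sleep"] * 6 + ["non-sedentary"] + ["sleep"] * 6)
        out = viterbi(obs, hmm)
        assert (out == "sleep").all()

    def test_empty_sequence(self):
        hmm = HmmParams(np.full(3, 1 / 3), np.full((3, 3), 1 / 3), np.eye(3))
        assert len(viterbi(np.array([], dtype=int), hmm)) == 0


class TestIntensitySplit:
    def seq(self, labels):
        return np.array(labels, dtype=object)

    def test_threshold_rules(self):
        ep = make_epochs(np.full(3, 60.0), enmo_mg=[120.0, 80.0, 150.0])
        out = split_intensity(self.seq(["non-sedentary", "non-sedentary",
                                        "sedentary"]), ep)
        assert list(out.labels) == ["MVPA", "LIPA", "sedentary"]

    def test_grid_mismatch_rejected(self):
        ep = make_epochs(np.full(3, 60.0))
        with pytest.raises(ValueError, match="grid"):
            split_intensity(self.seq(["sleep"]), ep)

    def test_boundary_value_is_mvpa(self):
        ep = make_epochs(np.full(1, 60.0), enmo_mg=[100.0])
        out = split_intensity(self.seq(["non-sedentary"]), ep)
        assert out.labels[0] == "MVPA"


class TestPredict:
    def test_end_to_end_accuracy_on_week_fixture(self, week_processed,
                                                 week_raw, week_prediction):
        epochs, _, _ = week_processed
        _, _, truth = week_raw
        n = min(epochs.n_epochs, len(truth.epoch_label))
        acc = classify.accuracy(BehaviourSequence(week_prediction.labels[:n]),
                                truth.epoch_label[:n])
        assert acc > 0.80

    def test_all_sleep_fixture_mostly_sleep(self, trained_model, cfg25):
        import wristtime as wt
        _, model = trained_model
        sched = wt.synth.make_schedule("all_sleep", days=1, seed=2)
        dev = wt.synth.DeviceModel(sample_rate=25.0)
        rec, _ = wt.synth.synthesize_recording(sched, dev, seed=2)
        donor = wt.rawproc.CalibrationModel(offset=np.zeros(3),
                                            gain=np.ones(3), source="self",
                                            sphere_coverage_ok=True,
                                            device_id=dev.device_id)
        epochs, _, _ = wt.process_recording(rec, cfg25, donor=donor)
        seq = predict(epochs, model)
        assert np.mean(seq.labels == "sleep") >= 0.95

    def test_empty_epochs_empty_sequence(self, trained_model):
        _, model = trained_model
        ep = make_epochs(np.empty(0))
        assert len(predict(ep, model).labels) == 0

    def test_label_time_conservation(self, week_processed, week_prediction):
        epochs, _, _ = week_processed
        labels = week_prediction.labels
        n_classified = sum(int((labels == b).sum())
                           for b in ("sleep", "sedentary", "LIPA", "MVPA"))
        assert n_classified + int((labels == "missing").sum()) == epochs.n_epochs
        assert n_classified == int((~epochs.missing).sum())


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self):
        truth = np.array(["sleep", "sedentary", "LIPA", "MVPA"] * 5)
        cm = confusion_matrix(BehaviourSequence(truth.copy()), truth)
        off = cm.iloc[:4, :4].to_numpy() - np.diag([5, 5, 5, 5])
        assert (off == 0).all()

    def test_totals_and_minutes(self):
        truth = np.array(["sleep"] * 6 + ["MVPA"] * 4)
        pred = np.array(["sleep"] * 5 + ["sedentary"] + ["MVPA"] * 4)
        cm = confusion_matrix(BehaviourSequence(pred.astype(object)), truth)
        assert cm.loc["total", "total"] == 10
        assert cm.attrs["minutes"].loc["total", "total"] == 5.0

    def test_missing_epochs_excluded(self):
        truth = np.array(["sleep", "nonwear", "MVPA"], dtype=object)
        pred = np.array(["sleep", "missing", "MVPA"], dtype=object)
        cm = confusion_matrix(BehaviourSequence(pred), truth)
        assert cm.loc["total", "total"] == 2


class TestModelPersistence:
    def test_save_load_round_trip(self, trained_model, tmp_path):
        ts, model = trained_model
        model.save(tmp_path / "model")
        back = BehaviourModel.load(tmp_path / "model")
        assert np.array_equal(back.hmm.transition, model.hmm.transition)
        assert np.array_equal(back.hmm.emission, model.hmm.emission)
        assert back.intensity_threshold == model.intensity_threshold
        X = ts.features[:50]
        assert np.array_equal(back.forest.predict(X), model.forest.predict(X))
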