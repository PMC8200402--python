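"""Classifier designs and LOSO cross-validation contracts."""

import numpy as np
import pytest

from neobg.classifiers import (ClassifierSpec, MFNNClassifier, PairwiseSVMECOC,
                               RNNClassifier, SubjectData, TrainingConfig,
                               loso_cross_validate, zscore_fit_apply)
from neobg.classifiers.hierarchical import HierarchicalClassifier
from neobg.core import REJECT
from neobg.labels import ScoreSeries


def toy_multiclass(n_per_class=40, k=3, n_feat=6, seed=0, spread=4.0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(k):
        mu = np.zeros(n_feat)
        mu[c % n_feat] = spread
        X.append(rng.normal(mu, 1.0, size=(n_per_class, n_feat)))
        y.append(np.full(n_per_class, c))
    return np.concatenate(X), np.concatenate(y)


class TestZScore:
    def test_population_sd_convention(self):
        train = np.array([[1.0], [2.0], [3.0]])
        tr, te = zscore_fit_apply(train, np.array([[2.0]]))
        assert tr[:, 0] == pytest.approx([-1.224744871, 0.0, 1.224744871])
        assert te[0, 0] == pytest.approx(0.0)

    def test_constant_column_centred_with_warning(self):
        train = np.full((4, 1), 7.0)
        with pytest.warns(UserWarning):
            tr, te = zscore_fit_apply(train, np.array([[7.0]]))
        assert np.all(tr == 0)
        assert te[0, 0] == 0.0

    def test_empty_train_errors(self):
        with pytest.raises(ValueError):
            zscore_fit_apply(np.empty((0, 2)), np.zeros((1, 2)))


class TestSVM:
    def test_k5_instantiates_10_binary_learners(self):
        X, y = toy_multiclass(k=5, n_per_class=20)
        model = PairwiseSVMECOC(C=1.0).fit(X, y)
        assert model.n_binary_learners == 10  # K(K-1)/2

    def test_separable_toy_resubstitution_perfect(self):
        X = np.array([[0.0, 0], [0, 1], [4, 0], [4, 1]])
        y = np.array([0, 0, 1, 1])
        model = PairwiseSVMECOC(C=1.0).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_posteriors_sum_to_one(self, rng):
        X, y = toy_multiclass(k=4, seed=1)
        model = PairwiseSVMECOC(C=1.0).fit(X, y)
        p = model.predict_proba(rng.normal(size=(50, X.shape[1])))
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(p >= 0)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            PairwiseSVMECOC(C=1.0).fit(np.zeros((5, 2)), np.zeros(5))

    def test_bayesian_optimization_improves_or_matches(self):
        X, y = toy_multiclass(k=3, spread=1.0, seed=2)
        tuned = PairwiseSVMECOC(n_evals=8, seed=0).fit(X, y)
        assert tuned.C_ is not None and 1e-3 <= tuned.C_ <= 1e3

    def test_class_permutation_equivariance(self):
        X, y = toy_multiclass(k=3, seed=3)
        m1 = PairwiseSVMECOC(C=1.0, seed=0).fit(X, y)
        relabel = {0: 2, 1: 0, 2: 1}
        y2 = np.array([relabel[v] for v in y])
        m2 = PairwiseSVMECOC(C=1.0, seed=0).fit(X, y2)
        p1 = m1.predict_proba(X[:10])
        p2 = m2.predict_proba(X[:10])
        for old, new in relabel.items():
            col_old = list(m1.classes_).index(old)
            col_new = list(m2.classes_).index(new)
            # equal up to the tolerance of the sigmoid-calibration solver
            assert np.allclose(p1[:, col_old], p2[:, col_new], atol=1e-4)


class TestMFNN:
    def test_xor_learnable(self):
        X = np.array([[0.0, 0], [0, 1], [1, 0], [1, 1]])
        y = np.array([0, 1, 1, 0])
        cfg = TrainingConfig(hidden_sizes=(4, 2), seed=0)
        model = MFNNClassifier(cfg).fit(X, y)
        assert np.mean(model.predict(X) == y) == 1.0

    def test_lr_schedule(self):
        cfg = TrainingConfig()
        assert cfg.lr_at(1) == pytest.approx(0.1)
        assert cfg.lr_at(6000) == pytest.approx(0.1)
        assert cfg.lr_at(6001) == pytest.approx(0.025)
        assert cfg.lr_at(12001) == pytest.approx(0.00625)  # schedule repeats

    def test_predicted_label_is_argmax(self, rng):
        X, y = toy_multiclass(k=3, n_per_class=15)
        cfg = TrainingConfig(hidden_sizes=(8, 4), max_iters=2000, seed=0)
        model = MFNNClassifier(cfg).fit(X, y)
        Xt = rng.normal(size=(20, X.shape[1]))
        p = model.predict_proba(Xt)
        assert np.array_equal(model.predict(Xt),
                              model.classes_[np.argmax(p, axis=1)])
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_validation_fraction_bounds(self):
        with pytest.raises(ValueError):
            TrainingConfig(validation_fraction=0.0)


class TestRNN:
    def _mfnn(self, X, y):
        cfg = TrainingConfig(hidden_sizes=(6, 3), max_iters=1500, seed=0)
        return MFNNClassifier(cfg).fit(X, y)

    def test_zero_recurrent_untrained_equals_mfnn(self):
        X, y = toy_multiclass(k=3, n_per_class=12)
        mfnn = self._mfnn(X, y)
        rnn = RNNClassifier(mfnn, recurrent_scale=0.0, n_passes=0)
        assert np.allclose(rnn.predict_proba_sequence(X),
                           mfnn.predict_proba(X), atol=1e-12)

    def test_state_reset_makes_subject_order_irrelevant(self):
        X, y = toy_multiclass(k=3, n_per_class=12, seed=4)
        mfnn = self._mfnn(X, y)
        rnn = RNNClassifier(mfnn, recurrent_scale=0.01, n_passes=0, seed=0)
        seq_a, seq_b = X[:18], X[18:]
        pa1 = rnn.predict_proba_sequence(seq_a)
        pb1 = rnn.predict_proba_sequence(seq_b)
        pb2 = rnn.predict_proba_sequence(seq_b)  # other order
        pa2 = rnn.predict_proba_sequence(seq_a)
        assert np.allclose(pa1, pa2) and np.allclose(pb1, pb2)

    def test_unordered_epochs_rejected(self):
        X, y = toy_multiclass(k=2, n_per_class=6)
        rnn = RNNClassifier(self._mfnn(X, y), n_passes=1)
        with pytest.raises(ValueError):
            rnn.fit_sequences([(X[:4], y[:4])],
                              epoch_indices=[np.array([0, 2, 1, 3])])

    def test_rnn_exploits_temporal_persistence(self):
        """On sequences where the class persists over time with noisy
        features, RTRL fine-tuning does not hurt and typically helps."""
        rng = np.random.default_rng(0)
        k, n_feat = 3, 4

        def make_sequences(n_subj, seed):
            r = np.random.default_rng(seed)
            seqs = []
            for _ in range(n_subj):
                y = np.repeat(r.integers(0, k, size=4), 10)
                mu = np.zeros((len(y), n_feat))
                mu[np.arange(len(y)), y % n_feat] = 1.2
                X = mu + r.normal(0, 1.0, size=mu.shape)
                seqs.append((X, y))
            return seqs

        train = make_sequences(6, 1)
        test = make_sequences(4, 2)
        Xtr = np.concatenate([s[0] for s in train])
        ytr = np.concatenate([s[1] for s in train])
        cfg = TrainingConfig(hidden_sizes=(8, 4), max_iters=3000, seed=0)
        mfnn = MFNNClassifier(cfg).fit(Xtr, ytr)
        rnn = RNNClassifier(mfnn, base_lr=2e-3, n_passes=3, seed=0)
        rnn.fit_sequences(train)
        acc_m = np.mean([np.mean(mfnn.predict(X) == y) for X, y in test])
        acc_r = np.mean([np.mean(rnn.predict_sequence(X) == y) for X, y in test])
        assert acc_r >= acc_m - 0.02


class TestHierarchical:
    def test_posterior_total_probability(self):
        X, y = toy_multiclass(k=5, n_per_class=25, seed=5)
        model = HierarchicalClassifier(
            lambda: PairwiseSVMECOC(C=1.0), "severity", scheme="7")
        # treat toy classes 0..4 as scores 0..4
        model.fit(X, y)
        p = model.predict_proba(X[:30])
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-9)

    def test_severity_vs_flat_comparable_on_separable_data(self):
        X, y = toy_multiclass(k=5, n_per_class=30, seed=6)
        flat = PairwiseSVMECOC(C=1.0).fit(X, y)
        hier = HierarchicalClassifier(
            lambda: PairwiseSVMECOC(C=1.0), "severity").fit(X, y)
        acc_f = np.mean(flat.predict(X) == y)
        acc_h = np.mean(hier.predict(X) == y)
        assert abs(acc_f - acc_h) < 0.1


def tiny_cohort(n_subjects=4, n_epochs=30, seed=0, k=4):
    """Fast synthetic LOSO dataset with class-dependent feature means."""
    rng = np.random.default_rng(seed)
    dataset = []
    for i in range(n_subjects):
        truth = np.repeat(rng.integers(0, k, size=n_epochs // 5), 5)[:n_epochs]
        mu = np.zeros((n_epochs, 6))
        mu[np.arange(n_epochs), truth % 6] = 5.0
        feats = mu + rng.normal(0, 0.8, size=mu.shape)
        e1 = truth.copy()
        e2 = truth.copy()
        flip = rng.random(n_epochs) < 0.08
        e2[flip] = np.clip(e2[flip] + 1, 0, 6)
        dataset.append(SubjectData(
            subject_id=f"S{i}", features=feats,
            e1=ScoreSeries(f"S{i}", "E1", e1),
            e2=ScoreSeries(f"S{i}", "E2", e2)))
    return dataset


class TestLoso:
    def spec(self, **kw):
        base = dict(design="svm", approach="flat", mode="ALL", scheme="7",
                    smooth_annotations=None, smooth_output=None,
                    svm_C=1.0, seed=0)
        base.update(kw)
        return ClassifierSpec(**base)

    def test_n_subjects_gives_n_folds(self):
        data = tiny_cohort(5)
        res = loso_cross_validate(data, self.spec())
        assert len(res.subjects) == 5

    def test_no_subject_in_its_own_training_fold(self):
        data = tiny_cohort(4)
        res = loso_cross_validate(data, self.spec())
        for sid, train in res.train_subjects.items():
            assert sid not in train

    def test_deterministic_given_seed(self):
        data = tiny_cohort(3)
        r1 = loso_cross_validate(data, self.spec(seed=7))
        r2 = loso_cross_validate(data, self.spec(seed=7))
        for sid in r1.subjects:
            assert np.array_equal(r1.pred[sid], r2.pred[sid])
            assert np.allclose(r1.probs[sid], r2.probs[sid])

    def test_accuracy_is_epoch_weighted_mean_of_subject_accuracies(self):
        data = tiny_cohort(4)
        res = loso_cross_validate(data, self.spec())
        per = res.per_subject_accuracy()
        weights = {}
        for sid in res.subjects:
            r = res.references[sid]["cons"]
            weights[sid] = int(np.sum(r != REJECT))
        pooled = sum(per[s] * weights[s] for s in per) / sum(weights.values())
        assert res.accuracy() == pytest.approx(pooled)

    def test_output_smoothing_never_hurts_on_blockwise_constant_truth(self):
        """Median smoothing (window 7) of predicted labels does not decrease
        accuracy when true labels are constant over long blocks."""
        rng = np.random.default_rng(3)
        dataset = []
        for i in range(4):
            truth = np.repeat(rng.integers(0, 3, size=5), 8)  # 40-min blocks
            mu = np.zeros((len(truth), 5))
            mu[np.arange(len(truth)), truth] = 3.0
            feats = mu + rng.normal(0, 1.5, size=mu.shape)  # noisy -> errors
            dataset.append(SubjectData(
                subject_id=f"S{i}", features=feats,
                e1=ScoreSeries(f"S{i}", "E1", truth)))
        res = loso_cross_validate(dataset, self.spec(smooth_output=7))
        acc_raw = res.accuracy(smoothed=False)
        acc_smooth = res.accuracy(smoothed=True)
        assert acc_smooth >= acc_raw

    def test_smote_inside_fold(self):
        data = tiny_cohort(3, seed=2)
        res = loso_cross_validate(data, self.spec(smote=True))
        assert len(res.subjects) == 3

    def test_mfnn_design_runs(self):
        data = tiny_cohort(3, n_epochs=20, seed=4, k=3)
        cfg = TrainingConfig(hidden_sizes=(8, 4), max_iters=800, seed=0)
        res = loso_cross_validate(data, self.spec(design="mfnn",
                                                  mfnn_config=cfg))
        assert res.accuracy() > 0.5

    def test_hierarchical_probabilities_sum_to_one(self):
        data = tiny_cohort(3, seed=5)
        res = loso_cross_validate(data, self.spec(approach="severity"))
        for sid in res.subjects:
            assert np.allclose(res.probs[sid].sum(axis=1), 1.0, atol=1e-6)

    def test_two_subjects_minimum(self):
        with pytest.raises(ValueError):
            loso_cross_validate(tiny_cohort(1), self.spec())

    def test_mfnn_comparable_to_svm_on_separable_data(self):
        """The two single-epoch designs land within a few points of each
        other when classes are well separated."""
        data = tiny_cohort(4, n_epochs=30, seed=8, k=3)
        res_svm = loso_cross_validate(data, self.spec())
        cfg = TrainingConfig(hidden_sizes=(12, 6), max_iters=4000, seed=0)
        res_mfnn = loso_cross_validate(
            data, self.spec(design="mfnn", mfnn_config=cfg))
        assert abs(res_svm.accuracy() - res_mfnn.accuracy()) <= 0.05
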