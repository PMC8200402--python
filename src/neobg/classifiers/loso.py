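"""Leave-one-subject-out cross-validation of the background classifiers.

Each fold holds out one infant entirely; z-score normalization, missing-value
imputation, SMOTE and hyperparameter tuning happen inside the training fold
only.  The fold's predictions are kept with provenance so leakage can be
asserted after the fact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from ..core import REJECT, child_seed
from ..labels import (ScoreSeries, build_training_set, concat_training_sets,
                      merge_7_to_5, smooth_scores, smote_balance)
from .hierarchical import HierarchicalClassifier
from .mfnn import MFNNClassifier, TrainingConfig
from .normalize import ZScaler
from .rnn import RNNClassifier
from .svm import PairwiseSVMECOC

__all__ = ["SubjectData", "ClassifierSpec", "LosoResult", "loso_cross_validate"]


@dataclass
class SubjectData:
    """One subject's aligned features and expert annotations (7-score)."""

    subject_id: str
    features: np.ndarray
    e1: ScoreSeries
    e2: ScoreSeries | None = None
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        if len(self.e1) != len(self.features):
            raise ValueError("annotation/feature epoch counts differ")
        if self.e2 is not None and len(self.e2) != len(self.features):
            raise ValueError("annotation/feature epoch counts differ")


@dataclass
class ClassifierSpec:
    """What to train and how, for one LOSO experiment."""

    design: str = "svm"            # svm | mfnn | rnn
    approach: str = "flat"         # flat | continuity | severity
    mode: str = "ALL"              # CONS | ALL
    scheme: str = "5"              # 5 | 7
    smooth_annotations: int | None = 5
    smooth_output: int | None = 7
    smote: bool = False
    smote_k: int = 10
    seed: int = 0
    svm_C: float | None = None
    svm_n_evals: int = 30
    mfnn_config: TrainingConfig | None = None
    rnn_base_lr: float = 1e-3
    rnn_passes: int = 2

    def __post_init__(self) -> None:
        if self.design not in ("svm", "mfnn", "rnn"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.approach not in ("flat", "continuity", "severity"):
            raise ValueError(f"unknown approach {self.approach!r}")
        if self.design == "rnn" and self.approach != "flat":
            raise ValueError("the RNN requires ordered sequences; only the flat "
                             "approach is supported")


def _prepare_series(s: ScoreSeries, spec: ClassifierSpec) -> ScoreSeries:
    if spec.scheme == "5" and s.scheme == "7":
        s = merge_7_to_5(s)
    if spec.smooth_annotations:
        s = smooth_scores(s, spec.smooth_annotations)
    return s


def _make_flat(spec: ClassifierSpec, seed: int):
    if spec.design == "svm":
        return PairwiseSVMECOC(C=spec.svm_C, n_evals=spec.svm_n_evals, seed=seed)
    cfg = spec.mfnn_config or TrainingConfig()
    return MFNNClassifier(replace(cfg, seed=seed))


@dataclass
class LosoResult:
    """Results-style container for one LOSO experiment.

    Holds per-subject posterior matrices, raw and smoothed predicted scores,
    and the reference series (consensus / E1 / E2) each fold was never
    trained on.
    """

    spec: ClassifierSpec
    class_set: np.ndarray
    subjects: list[str]
    probs: dict[str, np.ndarray]
    pred: dict[str, np.ndarray]
    pred_smoothed: dict[str, np.ndarray]
    references: dict[str, dict[str, np.ndarray]]
    train_subjects: dict[str, list[str]] = field(default_factory=dict)

    def predictions(self, smoothed: bool = True) -> dict[str, np.ndarray]:
        return self.pred_smoothed if smoothed else self.pred

    def pooled(self, reference: str = "cons", smoothed: bool = True
               ) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated (pred, ref) over subjects, REJECT pairs excluded."""
        preds, refs = [], []
        for s in self.subjects:
            p = self.predictions(smoothed)[s]
            r = self.references[s][reference]
            keep = r != REJECT
            preds.append(p[keep])
            refs.append(r[keep])
        return np.concatenate(preds), np.concatenate(refs)

    def agreement(self, reference: str = "cons", smoothed: bool = True):
        from ..evaluation import confusion_and_scores

        pred, ref = self.pooled(reference, smoothed)
        return confusion_and_scores(pred, ref)

    def accuracy(self, reference: str = "cons", smoothed: bool = True) -> float:
        pred, ref = self.pooled(reference, smoothed)
        return float(np.mean(pred == ref))

    def per_subject_accuracy(self, reference: str = "cons",
                             smoothed: bool = True) -> dict[str, float]:
        out = {}
        for s in self.subjects:
            p = self.predictions(smoothed)[s]
            r = self.references[s][reference]
            keep = r != REJECT
            out[s] = float(np.mean(p[keep] == r[keep])) if keep.any() else float("nan")
        return out

    def summary(self, reference: str = "cons") -> str:
        res = self.agreement(reference)
        lines = [
            f"LOSO {self.spec.design.upper()} ({self.spec.approach}, "
            f"{self.spec.mode}, {self.spec.scheme}-score)",
            "=" * 54,
            f"{'subjects':<28}{len(self.subjects):>10}",
            f"{'epochs (gradable pairs)':<28}{res.n_epochs:>10}",
            f"{'accuracy':<28}{res.accuracy:>10.3f}",
            f"{'Cohen kappa':<28}{res.kappa:>10.3f}",
            f"{'macro F1':<28}{res.macro_f1:>10.3f}",
            f"{'weighted F1':<28}{res.weighted_f1:>10.3f}",
            "-" * 54,
            "per-subject accuracy:",
        ]
        for s, a in self.per_subject_accuracy(reference).items():
            lines.append(f"  {s:<26}{a:>10.3f}")
        return "\n".join(lines)


def loso_cross_validate(dataset: list[SubjectData],
                        spec: ClassifierSpec) -> LosoResult:
    """Run the full LOSO experiment described by ``spec``."""
    if len(dataset) < 2:
        raise ValueError("LOSO needs at least two subjects")

    subjects = [d.subject_id for d in dataset]
    probs, pred, pred_smoothed, references = {}, {}, {}, {}
    train_subjects = {}
    class_set: np.ndarray | None = None

    for fold, test in enumerate(dataset):
        train = [d for d in dataset if d.subject_id != test.subject_id]
        seed = child_seed(spec.seed, "fold", fold)

        sets = []
        for d in train:
            e1 = _prepare_series(d.e1, spec)
            e2 = _prepare_series(d.e2 if d.e2 is not None else d.e1, spec)
            sets.append(build_training_set(e1, e2, d.features, spec.mode,
                                           missing=None))
        ts = concat_training_sets(sets)
        if len(np.unique(ts.y)) < 2:
            warnings.warn(f"fold {test.subject_id}: fewer than two classes in "
                          "training data; fold skipped")
            continue

        # training-fold median imputation
        med = np.nanmedian(ts.X, axis=0)
        med = np.where(np.isfinite(med), med, 0.0)
        Xtr = np.where(np.isfinite(ts.X), ts.X, med)
        Xte = np.where(np.isfinite(test.features), test.features, med)

        scaler = ZScaler().fit(Xtr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Xtr_z = scaler.transform(Xtr)
            Xte_z = scaler.transform(Xte)

        ytr = ts.y
        groups = ts.subjects
        if spec.smote:
            Xtr_z, ytr = smote_balance(Xtr_z, ytr, k=spec.smote_k, seed=seed)
            groups = None  # synthetic rows have no subject identity

        if spec.approach != "flat":
            model = HierarchicalClassifier(
                lambda: _make_flat(spec, seed), spec.approach, spec.scheme)
            model.fit(Xtr_z, ytr, subjects=groups if groups is not None else None)
            p = model.predict_proba(Xte_z)
            cls = model.classes_
        elif spec.design == "rnn":
            cfg = spec.mfnn_config or TrainingConfig()
            mfnn = MFNNClassifier(replace(cfg, seed=seed)).fit(Xtr_z, ytr)
            seqs = _sequences(ts, Xtr_z, ytr, smote=spec.smote)
            rnn = RNNClassifier(mfnn, base_lr=spec.rnn_base_lr,
                                n_passes=spec.rnn_passes, seed=seed)
            rnn.fit_sequences(seqs)
            p = rnn.predict_proba_sequence(Xte_z)
            cls = rnn.classes_
        else:
            model = _make_flat(spec, seed)
            if spec.design == "svm":
                model.fit(Xtr_z, ytr, groups=groups)
            else:
                model.fit(Xtr_z, ytr)
            p = model.predict_proba(Xte_z)
            cls = model.classes_

        if class_set is None:
            class_set = np.asarray(cls)
        elif not np.array_equal(class_set, cls):
            # align fold class set onto the global one
            aligned = np.zeros((len(p), len(class_set)))
            pos = {c: i for i, c in enumerate(class_set)}
            for i, c in enumerate(cls):
                if int(c) in pos:
                    aligned[:, pos[int(c)]] = p[:, i]
            p = aligned / np.maximum(p.sum(axis=1, keepdims=True), 1e-12)

        sid = test.subject_id
        probs[sid] = p
        raw = class_set[np.argmax(p, axis=1)]
        pred[sid] = raw
        if spec.smooth_output:
            sm = smooth_scores(ScoreSeries(sid, "clf", raw, scheme=spec.scheme),
                               spec.smooth_output)
            pred_smoothed[sid] = sm.scores
        else:
            pred_smoothed[sid] = raw.copy()

        e1 = _prepare_series(test.e1, spec)
        e2 = _prepare_series(test.e2 if test.e2 is not None else test.e1, spec)
        cons = np.where((e1.scores == e2.scores) & (e1.scores != REJECT),
                        e1.scores, REJECT)
        references[sid] = {"cons": cons, "e1": e1.scores, "e2": e2.scores}
        train_subjects[sid] = [d.subject_id for d in train]

    return LosoResult(spec=spec, class_set=class_set, subjects=list(probs),
                      probs=probs, pred=pred, pred_smoothed=pred_smoothed,
                      references=references, train_subjects=train_subjects)


def _sequences(ts, X_z: np.ndarray, y: np.ndarray, smote: bool
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per-(subject, rater) time-ordered sequences for RTRL training."""
    if smote:
        # SMOTE rows carry no temporal identity; fall back to original rows
        n = len(ts.y)
        X_z, y = X_z[:n], y[:n]
    seqs = []
    keys = list(dict.fromkeys(zip(ts.subjects, ts.raters)))
    for subj, rater in keys:
        sel = (ts.subjects == subj) & (ts.raters == rater)
        order = np.argsort(ts.epochs[sel], kind="stable")
        seqs.append((X_z[sel][order], y[sel][order]))
    return seqs
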