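"""Performance measures: confusion, accuracy/F1 (macro & weighted), Cohen's
kappa, bootstrap confidence intervals, per-subject and per-channel reports.

All metrics exclude REJECT pairs symmetrically: an epoch is dropped when
either series marks it REJECT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import REJECT

__all__ = ["AgreementResult", "BootstrapCI", "confusion_and_scores",
           "bootstrap_ci", "composite_agreement", "per_subject_report",
           "per_channel_report"]


@dataclass
class AgreementResult:
    """Confusion counts and the derived agreement metrics."""

    classes: np.ndarray
    confusion: np.ndarray   # rows = prediction, columns = reference
    accuracy: float
    kappa: float
    macro_acc: float
    weighted_acc: float
    macro_f1: float
    weighted_f1: float
    n_epochs: int


def _drop_rejects(pred: np.ndarray, ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    ref = np.asarray(ref)
    if pred.shape != ref.shape:
        raise ValueError("series must be aligned")
    keep = (pred != REJECT) & (ref != REJECT)
    return pred[keep], ref[keep]


def confusion_and_scores(pred: np.ndarray, ref: np.ndarray) -> AgreementResult:
    """Confusion matrix, accuracy, Cohen's kappa and macro/weighted scores.

    Kappa is (p_o - p_e) / (1 - p_e) with chance agreement from the
    marginals; when p_e = 1 the value is 1 if observed agreement is also 1,
    else 0.  Per-class F1 with no predictions and no references contributes 0
    to the macro average (with a warning).
    """
    pred, ref = _drop_rejects(pred, ref)
    if len(pred) == 0:
        raise ValueError("no overlapping gradable epochs")
    classes = np.unique(np.concatenate([pred, ref]))
    k = len(classes)
    pos = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((k, k), dtype=int)
    for p, r in zip(pred, ref):
        conf[pos[p], pos[r]] += 1
    n = conf.sum()
    p_o = np.trace(conf) / n
    p_e = float((conf.sum(axis=1) / n) @ (conf.sum(axis=0) / n))
    if p_e >= 1.0 - 1e-15:
        kappa = 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)

    support = conf.sum(axis=0)          # reference counts per class
    tp = np.diag(conf).astype(float)
    pred_n = conf.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(support > 0, tp / support, np.nan)
        precision = np.where(pred_n > 0, tp / pred_n, np.nan)
        f1 = np.where(np.nan_to_num(precision) + np.nan_to_num(recall) > 0,
                      2 * np.nan_to_num(precision) * np.nan_to_num(recall)
                      / (np.nan_to_num(precision) + np.nan_to_num(recall)), 0.0)
    absent = (support == 0) & (pred_n == 0)
    if absent.any():
        warnings.warn("classes absent from both series contribute 0 to the "
                      "macro averages", stacklevel=2)
    class_acc = np.where(support > 0, tp / np.maximum(support, 1), 0.0)
    w = support / n
    macro_acc = float(np.mean(class_acc))
    weighted_acc = float(np.sum(class_acc * w))
    macro_f1 = float(np.mean(f1))
    weighted_f1 = float(np.sum(f1 * w))
    return AgreementResult(classes=classes, confusion=conf, accuracy=float(p_o),
                           kappa=float(kappa), macro_acc=macro_acc,
                           weighted_acc=weighted_acc, macro_f1=macro_f1,
                           weighted_f1=weighted_f1, n_epochs=int(n))


@dataclass
class BootstrapCI:
    metric: str
    point: float
    lo: float
    hi: float
    n_resamples: int
    seed: int


def bootstrap_ci(metric_fn, pred: np.ndarray, ref: np.ndarray,
                 n_resamples: int = 1000, seed: int = 0,
                 name: str = "metric") -> BootstrapCI:
    """Percentile bootstrap CI95 by resampling epochs with replacement."""
    pred, ref = _drop_rejects(pred, ref)
    if len(pred) < 10:
        raise ValueError("need at least 10 gradable epochs for a bootstrap CI")
    point = float(metric_fn(pred, ref))
    rng = np.random.default_rng(seed)
    stats = np.empty(n_resamples)
    n = len(pred)
    for i in range(n_resamples):
        idx = rng.integers(0, n, size=n)
        stats[i] = metric_fn(pred[idx], ref[idx])
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return BootstrapCI(metric=name, point=point, lo=float(min(lo, point)),
                       hi=float(max(hi, point)), n_resamples=n_resamples,
                       seed=seed)


def composite_agreement(e1: np.ndarray, e2: np.ndarray,
                        clf: np.ndarray) -> dict:
    """Pairwise kappa between the two experts and the classifier.

    The non-inferiority flag is True when the classifier agrees with each
    expert at least as well as the experts agree with each other.
    """
    k12 = confusion_and_scores(e1, e2).kappa
    k1c = confusion_and_scores(clf, e1).kappa
    k2c = confusion_and_scores(clf, e2).kappa
    return {"kappa_e1_e2": k12, "kappa_e1_clf": k1c, "kappa_e2_clf": k2c,
            "non_inferior": bool(min(k1c, k2c) >= k12)}


def per_subject_report(result) -> "pd.DataFrame":
    """Accuracy per subject against consensus, E1 and E2 annotations."""
    import pandas as pd

    rows = []
    for sid in result.subjects:
        row = {"subject": sid}
        for refname in ("cons", "e1", "e2"):
            p = result.predictions()[sid]
            r = result.references[sid][refname]
            keep = r != REJECT
            if not keep.any():
                warnings.warn(f"subject {sid}: all-REJECT {refname} reference; "
                              "excluded", stacklevel=2)
                row[f"acc_{refname}"] = np.nan
            else:
                row[f"acc_{refname}"] = float(np.mean(p[keep] == r[keep]))
        rows.append(row)
    return pd.DataFrame(rows)


def per_channel_report(run_fn, channels: list[str]) -> "pd.DataFrame":
    """Accuracy per channel-restricted classifier.

    ``run_fn(channel)`` must re-run the LOSO experiment on features computed
    from that channel only and return pooled accuracy.
    """
    import pandas as pd

    rows = [{"channel": ch, "accuracy": float(run_fn(ch))} for ch in channels]
    return pd.DataFrame(rows)
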