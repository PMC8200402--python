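"""Hierarchical two-level classification (continuity or severity grouping).

Level 1 classifies the epoch into one of three clinically defined groups;
level 2 assigns the final score within the predicted group.  The multiclass
posterior is the product P(group) * P(score | group), which sums to one over
the full score set by the law of total probability.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from ..labels import CONTINUITY_GROUPS, MERGE_MAP, SEVERITY_GROUPS

__all__ = ["HierarchicalClassifier"]


class HierarchicalClassifier:
    """Level-1 group classifier + per-group level-2 score classifiers.

    ``make_base`` is a factory returning a fresh probabilistic classifier
    (fit / predict_proba / classes_) for each level.
    """

    def __init__(self, make_base: Callable, strategy: str, scheme: str = "7",
                 groups: dict[str, tuple[int, ...]] | None = None):
        if groups is None:
            if strategy == "severity":
                groups = SEVERITY_GROUPS
            elif strategy == "continuity":
                groups = CONTINUITY_GROUPS
            else:
                raise ValueError(f"unknown strategy {strategy!r}")
        if scheme == "5":
            groups = {g: tuple(sorted({MERGE_MAP[s] for s in ss}))
                      for g, ss in groups.items()}
        self.groups = groups
        self.make_base = make_base
        self._score_to_group = {s: g for g, ss in groups.items() for s in ss}

    def fit(self, X: np.ndarray, y: np.ndarray,
            subjects: np.ndarray | None = None) -> "HierarchicalClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        g_labels = np.array([self._score_to_group[s] for s in y], dtype=object)
        self.group_names_ = sorted(set(g_labels))
        if len(self.group_names_) >= 2:
            self.level1_ = self.make_base()
            self._fit_base(self.level1_, X, g_labels, subjects)
        else:
            self.level1_ = None  # degenerate: single group present
        self.level2_: dict[str, object] = {}
        self.group_constant_: dict[str, int] = {}
        for g in self.group_names_:
            sel = g_labels == g
            scores = np.unique(y[sel])
            if len(scores) >= 2:
                model = self.make_base()
                self._fit_base(model, X[sel], y[sel],
                               subjects[sel] if subjects is not None else None)
                self.level2_[g] = model
            else:
                self.group_constant_[g] = int(scores[0])
        return self

    @staticmethod
    def _fit_base(model, X, y, subjects):
        try:
            model.fit(X, y, groups=subjects)
        except TypeError:
            model.fit(X, y)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        n = len(X)
        out = np.zeros((n, len(self.classes_)))
        col = {c: i for i, c in enumerate(self.classes_)}
        if self.level1_ is not None:
            g_probs = self.level1_.predict_proba(X)
            g_cols = {g: i for i, g in enumerate(self.level1_.classes_)}
        for g in self.group_names_:
            pg = (g_probs[:, g_cols[g]] if self.level1_ is not None
                  else np.ones(n))
            if g in self.level2_:
                sub = self.level2_[g]
                sub_probs = sub.predict_proba(X)
                for i, c in enumerate(sub.classes_):
                    out[:, col[int(c)]] += pg * sub_probs[:, i]
            else:
                out[:, col[self.group_constant_[g]]] += pg
        return out / out.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
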