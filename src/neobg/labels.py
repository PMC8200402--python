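"""Expert score series: merging, smoothing, training-set construction, SMOTE.

Scores follow the seven-grade clinical scheme (0 best .. 6 worst) plus a
REJECT sentinel for ungradable epochs.  The 7->5 merger combines the
normal/near-normal grades {0, 1, 2} into one score and renumbers:
{0,1,2}->0, 3->1, 4->2, 5->3, 6->4.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .core import REJECT

__all__ = [
    "ScoreSeries", "TrainingSet", "merge_7_to_5", "smooth_scores",
    "build_training_set", "group_hierarchy", "smote_balance",
    "SEVERITY_GROUPS", "CONTINUITY_GROUPS",
]

MERGE_MAP = {0: 0, 1: 0, 2: 0, 3: 1, 4: 2, 5: 3, 6: 4}

#: default level-1 groupings of the 7-score scheme.  Severity follows the
#: clinical normal/moderate/severe reading; continuity splits the
#: continuity-defined grades from the amplitude-defined ones.
SEVERITY_GROUPS = {"normal": (0, 1, 2), "moderate": (3, 4), "severe": (5, 6)}
CONTINUITY_GROUPS = {"continuity": (0, 1, 2), "discontinuous": (3, 5),
                     "amplitude": (4, 6)}


@dataclass
class ScoreSeries:
    """Per-epoch ordinal background scores for one subject and rater."""

    subject_id: str
    rater_id: str
    scores: np.ndarray
    scheme: str = "7"  # "7" or "5"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        hi = 6 if self.scheme == "7" else 4
        valid = (self.scores == REJECT) | ((self.scores >= 0) & (self.scores <= hi))
        if not valid.all():
            bad = self.scores[~valid]
            raise ValueError(f"scores outside 0..{hi} (or REJECT): {bad[:5]}")

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def gradable(self) -> np.ndarray:
        return self.scores != REJECT


def merge_7_to_5(series: ScoreSeries) -> ScoreSeries:
    """Merge grades {0,1,2} and renumber to the 5-score scheme."""
    if series.scheme != "7":
        raise ValueError("series is already in the 5-score scheme")
    out = np.array([REJECT if s == REJECT else MERGE_MAP[s] for s in series.scores])
    return replace(series, scores=out, scheme="5")


def smooth_scores(series: ScoreSeries, window: int = 5) -> ScoreSeries:
    """Centred running median over non-REJECT neighbours.

    REJECT positions are excluded from every window and never overwritten.
    Edges use the available (shrunken) window.  The median of an even number
    of ordinal values is the lower middle value, so the output is always a
    valid score present in the window.
    """
    if window % 2 == 0 or window < 3 or window > 13:
        raise ValueError("window must be odd and within 3..13")
    half = window // 2
    src = series.scores
    out = src.copy()
    n = len(src)
    for i in range(n):
        if src[i] == REJECT:
            continue
        lo, hi = max(0, i - half), min(n, i + half + 1)
        vals = [s for s in src[lo:hi] if s != REJECT]
        vals.sort()
        out[i] = vals[(len(vals) - 1) // 2]  # lower middle for even counts
    return replace(series, scores=out)


@dataclass
class TrainingSet:
    """Feature rows with labels and provenance for classifier training.

    ``mode="CONS"`` keeps only epochs where the raters agree (one row per
    epoch); ``mode="ALL"`` emits one row per rater per epoch, so consensus
    epochs carry twice the weight.
    """

    mode: str
    X: np.ndarray
    y: np.ndarray
    subjects: np.ndarray
    epochs: np.ndarray
    raters: np.ndarray
    missing: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.y)


def build_training_set(e1: ScoreSeries, e2: ScoreSeries, features: np.ndarray,
                       mode: str, missing: np.ndarray | None = None) -> TrainingSet:
    """Combine two raters' annotations with the feature matrix.

    CONS keeps agreeing epochs once (epochs rejected by either rater are
    excluded); ALL emits each rater's gradable epochs separately, doubling
    consensus epochs.
    """
    if mode not in ("CONS", "ALL"):
        raise ValueError("mode must be CONS or ALL")
    if len(e1) != len(e2) or len(e1) != len(features):
        raise ValueError("annotations and features must have aligned epoch counts")
    if e1.scheme != e2.scheme:
        raise ValueError("raters must use the same scheme")
    feats = np.asarray(features, dtype=float)
    rows_X, rows_y, rows_ep, rows_rater = [], [], [], []
    rows_missing = []
    for i in range(len(e1)):
        s1, s2 = e1.scores[i], e2.scores[i]
        if mode == "CONS":
            if s1 != REJECT and s2 != REJECT and s1 == s2:
                rows_X.append(feats[i]); rows_y.append(s1)
                rows_ep.append(i); rows_rater.append("CONS")
                if missing is not None:
                    rows_missing.append(missing[i])
        else:
            for rater, s in ((e1.rater_id, s1), (e2.rater_id, s2)):
                if s != REJECT:
                    rows_X.append(feats[i]); rows_y.append(s)
                    rows_ep.append(i); rows_rater.append(rater)
                    if missing is not None:
                        rows_missing.append(missing[i])
    return TrainingSet(
        mode=mode,
        X=np.asarray(rows_X, dtype=float).reshape(len(rows_y), feats.shape[1]),
        y=np.asarray(rows_y, dtype=int),
        subjects=np.full(len(rows_y), e1.subject_id, dtype=object),
        epochs=np.asarray(rows_ep, dtype=int),
        raters=np.asarray(rows_rater, dtype=object),
        missing=np.asarray(rows_missing, dtype=bool) if missing is not None else None,
    )


def concat_training_sets(sets: list[TrainingSet]) -> TrainingSet:
    """Stack per-subject training sets into one."""
    if not sets:
        raise ValueError("no training sets to concatenate")
    mode = sets[0].mode
    return TrainingSet(
        mode=mode,
        X=np.concatenate([s.X for s in sets]),
        y=np.concatenate([s.y for s in sets]),
        subjects=np.concatenate([s.subjects for s in sets]),
        epochs=np.concatenate([s.epochs for s in sets]),
        raters=np.concatenate([s.raters for s in sets]),
        missing=(np.concatenate([s.missing for s in sets])
                 if all(s.missing is not None for s in sets) else None),
    )


def group_hierarchy(series: ScoreSeries, strategy: str,
                    groups: dict[str, tuple[int, ...]] | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Two-level hierarchical labels.

    Returns ``(level1, level2)`` where ``level1[i]`` is the group name and
    ``level2[i]`` the original score (classified only within its group).
    REJECT maps to ("REJECT", REJECT).
    """
    if groups is None:
        if strategy == "severity":
            groups = SEVERITY_GROUPS
        elif strategy == "continuity":
            groups = CONTINUITY_GROUPS
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
    if series.scheme == "5":
        # translate 7-score group definitions through the merger
        groups = {g: tuple(sorted({MERGE_MAP[s] for s in ss}))
                  for g, ss in groups.items()}
    score_to_group = {}
    for g, ss in groups.items():
        for s in ss:
            score_to_group[s] = g
    level1 = np.array([("REJECT" if s == REJECT else score_to_group[s])
                       for s in series.scores], dtype=object)
    level2 = series.scores.copy()
    return level1, level2


def smote_balance(X: np.ndarray, y: np.ndarray, k: int = 10,
                  seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling (SMOTE) to the majority class count.

    Each synthetic row is a convex combination of a minority row and one of
    its k nearest minority neighbours (k capped at class size - 1).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    rng = np.random.default_rng(seed)
    new_X, new_y = [X], [y]
    for cls, cnt in zip(classes, counts):
        if cnt == n_max:
            continue
        if cnt < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 members; cannot SMOTE")
        Xc = X[y == cls]
        kk = min(k, cnt - 1)
        nn = NearestNeighbors(n_neighbors=kk + 1).fit(Xc)
        _, idx = nn.kneighbors(Xc)  # idx[:, 0] is the point itself
        need = n_max - cnt
        base = rng.integers(0, cnt, size=need)
        nbr = idx[base, rng.integers(1, kk + 1, size=need)]
        lam = rng.random(need)[:, None]
        synth = Xc[base] + lam * (Xc[nbr] - Xc[base])
        new_X.append(synth)
        new_y.append(np.full(need, cls, dtype=y.dtype))
    return np.concatenate(new_X), np.concatenate(new_y)
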