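"""Genetic-algorithm wrapper feature selection.

Bitmask chromosomes over the 98-feature registry; fitness is the inner
subject-grouped cross-validation accuracy of the wrapped classifier on the
masked features.  Fitness-proportional (roulette) parent selection with
elitism of one, two-point crossover (rate 0.6), per-gene mutation (rate
0.1); termination at 50 generations or 5,000 fitness evaluations, whichever
comes first.  Evaluated chromosomes are memoized, so the evaluation budget
counts unique subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.svm import SVC

from .core import child_seed

__all__ = ["GAConfig", "SelectionReport", "ga_select", "threshold_sweep",
           "accuracy_vs_count_curve"]


@dataclass
class GAConfig:
    population_size: int = 100
    crossover_rate: float = 0.6
    mutation_rate: float = 0.1
    generations: int = 50
    max_evaluations: int = 5_000
    init_density: float = 0.3
    inner_folds: int = 5
    elitism: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")
        if self.population_size % 2:
            raise ValueError("population size must be even (for pairing)")


@dataclass
class GAResult:
    best_mask: np.ndarray
    best_fitness: float
    selection_counts: np.ndarray  # per-feature count in the final population
    n_evaluations: int
    history: list[float] = field(default_factory=list)


@dataclass
class SelectionReport:
    """Per-threshold GA outcomes plus cross-threshold robustness."""

    thresholds: list[float]
    per_threshold: dict[float, GAResult]
    robust_features: np.ndarray  # selected in > half the final population at
    # every threshold


def _default_fitness_fn(X, y, groups, inner_folds: int, seed: int):
    """Inner subject-grouped CV accuracy of a fixed-C linear SVM wrapper."""

    def fitness(mask: np.ndarray) -> float:
        Xm = X[:, mask]
        uniq = np.unique(groups) if groups is not None else []
        if groups is not None and len(uniq) >= inner_folds:
            splits = GroupKFold(n_splits=inner_folds).split(Xm, y, groups)
        else:
            n = max(2, min(inner_folds,
                           np.bincount(np.unique(y, return_inverse=True)[1]).min()))
            splits = StratifiedKFold(n_splits=n, shuffle=True,
                                     random_state=seed).split(Xm, y)
        accs = []
        for tr, te in splits:
            if len(np.unique(y[tr])) < 2:
                continue
            clf = SVC(kernel="linear", C=1.0, random_state=seed)
            clf.fit(Xm[tr], y[tr])
            accs.append(float(np.mean(clf.predict(Xm[te]) == y[te])))
        return float(np.mean(accs)) if accs else 0.0

    return fitness


def ga_select(X: np.ndarray, y: np.ndarray, config: GAConfig,
              groups: np.ndarray | None = None,
              fitness_fn=None) -> GAResult:
    """Run the GA wrapper search and return the best subset found."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    n_feat = X.shape[1]
    rng = np.random.default_rng(config.seed)
    if fitness_fn is None:
        fitness_fn = _default_fitness_fn(X, y, groups, config.inner_folds,
                                         child_seed(config.seed, "inner"))

    cache: dict[bytes, float] = {}
    n_evals = 0

    def evaluate(mask: np.ndarray) -> float:
        nonlocal n_evals
        key = np.packbits(mask).tobytes()
        if key in cache:
            return cache[key]
        if n_evals >= config.max_evaluations:
            return cache.get(key, 0.0)
        n_evals += 1
        fit = fitness_fn(mask)
        cache[key] = fit
        return fit

    def repair(mask: np.ndarray) -> np.ndarray:
        if not mask.any():
            mask = mask.copy()
            mask[rng.integers(n_feat)] = True
        return mask

    pop = rng.random((config.population_size, n_feat)) < config.init_density
    pop = np.array([repair(m) for m in pop])
    fits = np.array([evaluate(m) for m in pop])
    history = [float(fits.max())]

    for _ in range(config.generations):
        if n_evals >= config.max_evaluations:
            break
        # roulette selection on shifted fitness
        w = fits - fits.min() + 1e-9
        probs = w / w.sum()
        order = np.argsort(fits)[::-1]
        elite = pop[order[: config.elitism]].copy()
        children = []
        while len(children) < config.population_size - config.elitism:
            i, j = rng.choice(config.population_size, size=2, p=probs)
            a, b = pop[i].copy(), pop[j].copy()
            if rng.random() < config.crossover_rate and n_feat > 2:
                p1, p2 = sorted(rng.choice(n_feat - 1, size=2, replace=False) + 1)
                a[p1:p2], b[p1:p2] = b[p1:p2].copy(), a[p1:p2].copy()
            for child in (a, b):
                flip = rng.random(n_feat) < config.mutation_rate
                child ^= flip
                children.append(repair(child))
        pop = np.concatenate([elite, np.array(children[: config.population_size
                                                       - config.elitism])])
        fits = np.array([evaluate(m) for m in pop])
        history.append(float(fits.max()))

    best = int(np.argmax(fits))
    return GAResult(best_mask=pop[best].copy(), best_fitness=float(fits[best]),
                    selection_counts=pop.sum(axis=0).astype(int),
                    n_evaluations=n_evals, history=history)


def threshold_sweep(make_dataset, thresholds=(0.0, 0.10, 0.25, 0.50),
                    config: GAConfig = GAConfig()) -> SelectionReport:
    """GA selection at several artifact-rejection thresholds.

    ``make_dataset(threshold)`` must rebuild ``(X, y, groups)`` with channel
    rejection recomputed at that threshold.  A feature is *robust* when it is
    selected by more than half of the final population at every threshold.
    """
    per = {}
    robust = None
    for thr in thresholds:
        X, y, groups = make_dataset(thr)
        res = ga_select(X, y, GAConfig(**{**config.__dict__,
                                          "seed": child_seed(config.seed, str(thr))}),
                        groups=groups)
        per[thr] = res
        over_half = res.selection_counts > config.population_size / 2
        robust = over_half if robust is None else (robust & over_half)
    return SelectionReport(thresholds=list(thresholds), per_threshold=per,
                           robust_features=np.flatnonzero(robust))


def accuracy_vs_count_curve(ranking: np.ndarray, evaluate_subset) -> np.ndarray:
    """LOSO accuracy as features are added one at a time along ``ranking``.

    ``evaluate_subset(indices)`` returns the accuracy for that feature
    subset; the curve has one entry per subset size 1..len(ranking).
    """
    ranking = np.asarray(ranking, dtype=int)
    return np.array([float(evaluate_subset(ranking[: k + 1]))
                     for k in range(len(ranking))])
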