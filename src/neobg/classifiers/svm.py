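"""Error-correcting output-code SVM: one-vs-one linear binaries.

For K classes the model trains K(K-1)/2 linear SVMs, calibrates each pair
with a Platt sigmoid on training decision values, and couples the pairwise
probabilities into a multiclass posterior (Wu-Lin second method).  The
regularization strength C is tuned by Bayesian optimization (Gaussian
process + expected improvement) over log10 C in [-3, 3] using an internal
five-fold cross-validation grouped by subject when subject ids are given.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern, WhiteKernel
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GroupKFold, StratifiedKFold
from sklearn.svm import SVC

__all__ = ["PairwiseSVMECOC", "pairwise_coupling"]


def pairwise_coupling(R: np.ndarray, pairs: list[tuple[int, int]], k: int) -> np.ndarray:
    """Couple pairwise probabilities into a multiclass posterior.

    ``R[n, p]`` is P(class i beats class j) for ``pairs[p] = (i, j)``.
    Solves the Wu-Lin quadratic problem per row via its KKT linear system;
    rows sum to one exactly.
    """
    n = R.shape[0]
    out = np.empty((n, k))
    for row in range(n):
        r = np.zeros((k, k))
        for p, (i, j) in enumerate(pairs):
            r[i, j] = np.clip(R[row, p], 1e-12, 1 - 1e-12)
            r[j, i] = 1.0 - r[i, j]
        Q = np.zeros((k, k))
        for i in range(k):
            for j in range(k):
                if i == j:
                    Q[i, i] = sum(r[j2, i] ** 2 for j2 in range(k) if j2 != i)
                else:
                    Q[i, j] = -r[j, i] * r[i, j]
        A = np.zeros((k + 1, k + 1))
        A[:k, :k] = Q
        A[:k, k] = 1.0
        A[k, :k] = 1.0
        b = np.zeros(k + 1)
        b[k] = 1.0
        try:
            sol = np.linalg.solve(A, b)[:k]
        except np.linalg.LinAlgError:
            sol = np.full(k, 1.0 / k)
        sol = np.clip(sol, 0.0, None)
        total = sol.sum()
        out[row] = sol / total if total > 0 else np.full(k, 1.0 / k)
    return out


class PairwiseSVMECOC:
    """One-vs-one linear SVM ensemble with calibrated posteriors.

    Parameters
    ----------
    C : float, optional
        Fixed regularization strength; when None it is tuned by Bayesian
        optimization.
    n_evals : int
        Total objective evaluations of the Bayesian optimization.
    inner_folds : int
        Folds of the internal cross-validation used as the tuning objective.
    seed : int
    """

    def __init__(self, C: float | None = None, n_evals: int = 30,
                 inner_folds: int = 5, seed: int = 0):
        self.C = C
        self.n_evals = n_evals
        self.inner_folds = inner_folds
        self.seed = seed
        self.classes_: np.ndarray | None = None
        self.binary_learners_: dict[tuple[int, int], SVC] = {}
        self.calibrators_: dict[tuple[int, int], LogisticRegression] = {}
        self.C_: float | None = None

    # -- tuning --------------------------------------------------------------

    def _cv_accuracy(self, X, y, groups, C: float) -> float:
        y = np.asarray(y)
        uniq_groups = np.unique(groups) if groups is not None else []
        if groups is not None and len(uniq_groups) >= self.inner_folds:
            splitter = GroupKFold(n_splits=self.inner_folds)
            splits = splitter.split(X, y, groups)
        else:
            n_splits = min(self.inner_folds, np.bincount(
                np.unique(y, return_inverse=True)[1]).min())
            n_splits = max(n_splits, 2)
            splitter = StratifiedKFold(n_splits=n_splits, shuffle=True,
                                       random_state=self.seed)
            splits = splitter.split(X, y)
        accs = []
        for tr, te in splits:
            if len(np.unique(y[tr])) < 2:
                continue
            model = PairwiseSVMECOC(C=C, seed=self.seed)
            model.fit(X[tr], y[tr])
            accs.append(float(np.mean(model.predict(X[te]) == y[te])))
        return float(np.mean(accs)) if accs else 0.0

    def _tune(self, X, y, groups) -> float:
        rng = np.random.default_rng(self.seed)
        lo, hi = -3.0, 3.0
        n_init = min(5, self.n_evals)
        xs = list(np.linspace(lo, hi, n_init))
        ys = [self._cv_accuracy(X, y, groups, 10.0 ** x) for x in xs]
        kernel = Matern(length_scale=1.0, nu=2.5) + WhiteKernel(1e-4)
        grid = np.linspace(lo, hi, 256)[:, None]
        while len(xs) < self.n_evals:
            gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                          random_state=self.seed)
            gp.fit(np.array(xs)[:, None], np.array(ys))
            mu, sd = gp.predict(grid, return_std=True)
            best = max(ys)
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (mu - best - 1e-4) / np.maximum(sd, 1e-12)
                ei = (mu - best - 1e-4) * norm.cdf(z) + sd * norm.pdf(z)
            ei[sd < 1e-12] = 0.0
            x_next = float(grid[int(np.argmax(ei)), 0])
            if any(abs(x_next - x) < 1e-6 for x in xs):
                x_next = float(rng.uniform(lo, hi))
            xs.append(x_next)
            ys.append(self._cv_accuracy(X, y, groups, 10.0 ** x_next))
        return 10.0 ** xs[int(np.argmax(ys))]

    # -- fitting -------------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray,
            groups: np.ndarray | None = None) -> "PairwiseSVMECOC":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        self.C_ = self.C if self.C is not None else self._tune(X, y, groups)
        self.binary_learners_ = {}
        self.calibrators_ = {}
        for i, j in combinations(range(len(self.classes_)), 2):
            ci, cj = self.classes_[i], self.classes_[j]
            sel = (y == ci) | (y == cj)
            Xp, yp = X[sel], (y[sel] == ci).astype(int)  # 1 = class i wins
            svc = SVC(kernel="linear", C=self.C_, random_state=self.seed)
            svc.fit(Xp, yp)
            dec = svc.decision_function(Xp)
            cal = LogisticRegression(C=1e6, max_iter=1000)
            cal.fit(dec[:, None], yp)
            self.binary_learners_[(i, j)] = svc
            self.calibrators_[(i, j)] = cal
        return self

    @property
    def n_binary_learners(self) -> int:
        return len(self.binary_learners_)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        pairs = sorted(self.binary_learners_)
        R = np.empty((len(X), len(pairs)))
        for p, key in enumerate(pairs):
            dec = self.binary_learners_[key].decision_function(X)
            R[:, p] = self.calibrators_[key].predict_proba(dec[:, None])[:, 1]
        probs = pairwise_coupling(R, pairs, len(self.classes_))
        return probs / probs.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
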