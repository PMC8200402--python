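"""Multilayer feed-forward network with tanh hidden and output layers.

Training is full-batch gradient descent with a constant momentum factor and
a staged learning-rate schedule: the LR starts at 0.1 and is cut by 75%
(multiplied by 0.25) after every 6,000 iterations.  Training stops at
120,000 iterations, when the training RMSE falls below 1e-3, or when the
inner-validation loss (10% of the training rows, held out) stops improving.
Class probabilities are the softmax of the tanh output activations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TrainingConfig", "MFNNClassifier"]


@dataclass
class TrainingConfig:
    """Hyperparameters of the MFNN/RNN training procedures."""

    lr_initial: float = 0.1
    lr_decay_every: int = 6_000
    lr_decay_factor: float = 0.75  # fraction removed at each stage
    momentum: float = 0.8
    max_iters: int = 120_000
    rmse_stop: float = 1e-3
    validation_fraction: float = 0.10
    patience_checks: int = 25
    check_every: int = 200
    hidden_sizes: tuple[int, int] = (30, 15)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in (0, 1)")
        for name in ("lr_initial", "lr_decay_every", "momentum", "max_iters",
                     "rmse_stop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def lr_at(self, iteration: int) -> float:
        """Learning rate at a 1-based iteration index (repeating schedule)."""
        stage = (iteration - 1) // self.lr_decay_every
        return self.lr_initial * (1.0 - self.lr_decay_factor) ** stage


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class MFNNClassifier:
    """Two-hidden-layer tanh network trained by batch SGD with momentum."""

    def __init__(self, config: TrainingConfig | None = None):
        self.config = config or TrainingConfig()
        self.classes_: np.ndarray | None = None
        self.weights_: list[np.ndarray] | None = None
        self.biases_: list[np.ndarray] | None = None
        self.n_iter_: int = 0

    def _init_params(self, n_in: int, n_out: int, rng: np.random.Generator):
        h1, h2 = self.config.hidden_sizes
        sizes = [(n_in, h1), (h1, h2), (h2, n_out)]
        W = [rng.normal(0, 1.0 / np.sqrt(a), size=(a, b)) for a, b in sizes]
        b = [np.zeros(s[1]) for s in sizes]
        return W, b

    def _forward(self, X, W, b):
        a1 = np.tanh(X @ W[0] + b[0])
        a2 = np.tanh(a1 @ W[1] + b[1])
        out = np.tanh(a2 @ W[2] + b[2])
        return a1, a2, out

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MFNNClassifier":
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least two classes")
        k = len(self.classes_)
        T = np.full((len(y), k), -1.0)
        T[np.arange(len(y)), np.searchsorted(self.classes_, y)] = 1.0

        rng = np.random.default_rng(cfg.seed)
        n_val = max(1, int(round(cfg.validation_fraction * len(y)))) \
            if len(y) >= 10 else 0
        perm = rng.permutation(len(y))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        Xtr, Ttr = X[tr_idx], T[tr_idx]
        Xval, Tval = X[val_idx], T[val_idx]

        W, b = self._init_params(X.shape[1], k, rng)
        vW = [np.zeros_like(w) for w in W]
        vb = [np.zeros_like(x) for x in b]
        best_val = np.inf
        best = None
        stall = 0
        n = len(Xtr)

        for it in range(1, cfg.max_iters + 1):
            lr = cfg.lr_at(it)
            a1, a2, out = self._forward(Xtr, W, b)
            err = out - Ttr
            rmse = float(np.sqrt(np.mean(err ** 2)))
            if rmse < cfg.rmse_stop:
                self.n_iter_ = it
                break
            # backprop of mean-squared error through tanh layers
            d3 = 2.0 * err * (1 - out ** 2) / n
            d2 = (d3 @ W[2].T) * (1 - a2 ** 2)
            d1 = (d2 @ W[1].T) * (1 - a1 ** 2)
            grads_W = [Xtr.T @ d1, a1.T @ d2, a2.T @ d3]
            grads_b = [d1.sum(0), d2.sum(0), d3.sum(0)]
            if any(not np.isfinite(g).all() for g in grads_W):
                raise FloatingPointError(
                    f"non-finite gradient at iteration {it} (lr={lr:.4g})")
            for li in range(3):
                vW[li] = cfg.momentum * vW[li] - lr * grads_W[li]
                vb[li] = cfg.momentum * vb[li] - lr * grads_b[li]
                W[li] = W[li] + vW[li]
                b[li] = b[li] + vb[li]

            if n_val and it % cfg.check_every == 0:
                _, _, vout = self._forward(Xval, W, b)
                vloss = float(np.mean((vout - Tval) ** 2))
                if vloss < best_val - 1e-9:
                    best_val = vloss
                    best = ([w.copy() for w in W], [x.copy() for x in b])
                    stall = 0
                else:
                    stall += 1
                    if stall >= cfg.patience_checks:
                        self.n_iter_ = it
                        break
        else:
            self.n_iter_ = cfg.max_iters

        if best is not None and n_val and stall >= cfg.patience_checks:
            W, b = best
        self.weights_, self.biases_ = W, b
        return self

    def output_activations(self, X: np.ndarray) -> np.ndarray:
        _, _, out = self._forward(np.asarray(X, dtype=float),
                                  self.weights_, self.biases_)
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _softmax(self.output_activations(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
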