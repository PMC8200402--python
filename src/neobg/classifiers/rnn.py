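"""Recurrent classifier: MFNN with a one-step-delay feedback layer.

The second hidden layer receives its own previous activation through a
recurrent weight matrix (one epoch delay).  Forward-path weights are
initialized from a trained MFNN; recurrent weights start small-random.
Training uses Real-Time Recurrent Learning: exact online sensitivities of
the recurrent state are carried for the recurrent-layer parameters (W2, b2,
Wr), while the input and output layers are updated with instantaneous
gradients.  Per-class learning rates are scaled inversely to the class
frequency in the training data.  The hidden state is reset at subject
boundaries.
"""

from __future__ import annotations

import numpy as np

from .mfnn import MFNNClassifier, _softmax

__all__ = ["RNNClassifier"]


class RNNClassifier:
    """RTRL-trained recurrent network pre-initialized from an MFNN.

    Parameters
    ----------
    mfnn : MFNNClassifier
        Trained source network supplying the forward-path weights.
    base_lr : float
        Small fine-tuning learning rate; the per-class rate is
        ``base_lr * mean_class_count / count(class)``.
    recurrent_scale : float
        SD of the small-random recurrent weight initialization (0 keeps the
        RNN exactly equivalent to the source MFNN before training).
    n_passes : int
        Full passes over the training sequences (0 = no training).
    """

    def __init__(self, mfnn: MFNNClassifier, base_lr: float = 1e-3,
                 recurrent_scale: float = 0.01, n_passes: int = 2,
                 seed: int = 0):
        if mfnn.weights_ is None:
            raise ValueError("source MFNN must be trained")
        self.classes_ = mfnn.classes_.copy()
        self.W = [w.copy() for w in mfnn.weights_]
        self.b = [x.copy() for x in mfnn.biases_]
        h2 = self.W[1].shape[1]
        rng = np.random.default_rng(seed)
        self.Wr = (rng.normal(0, recurrent_scale, size=(h2, h2))
                   if recurrent_scale > 0 else np.zeros((h2, h2)))
        self.base_lr = base_lr
        self.n_passes = n_passes
        self.seed = seed

    # -- forward -------------------------------------------------------------

    def _step(self, x: np.ndarray, h_prev: np.ndarray):
        a1 = np.tanh(x @ self.W[0] + self.b[0])
        pre = a1 @ self.W[1] + self.b[1] + h_prev @ self.Wr
        h = np.tanh(pre)
        out = np.tanh(h @ self.W[2] + self.b[2])
        return a1, h, out

    def predict_proba_sequence(self, X: np.ndarray) -> np.ndarray:
        """Posterior per epoch for one subject's time-ordered feature rows."""
        X = np.asarray(X, dtype=float)
        h = np.zeros(self.W[1].shape[1])
        outs = np.empty((len(X), len(self.classes_)))
        for t, x in enumerate(X):
            _, h, out = self._step(x, h)
            outs[t] = out
        return _softmax(outs)

    def predict_sequence(self, X: np.ndarray) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba_sequence(X), axis=1)]

    # -- RTRL training -------------------------------------------------------

    def fit_sequences(self, sequences: list[tuple[np.ndarray, np.ndarray]],
                      epoch_indices: list[np.ndarray] | None = None
                      ) -> "RNNClassifier":
        """Train on per-subject (features, labels) sequences in time order.

        ``epoch_indices``, when given, are checked to be strictly increasing
        within each subject.
        """
        if epoch_indices is not None:
            for idx in epoch_indices:
                if np.any(np.diff(idx) <= 0):
                    raise ValueError("epochs must be in temporal order within a subject")
        all_y = np.concatenate([y for _, y in sequences])
        classes, counts = np.unique(all_y, return_counts=True)
        lr_map = {}
        mean_count = counts.mean()
        for cls, cnt in zip(classes, counts):
            lr_map[cls] = self.base_lr * mean_count / cnt

        h1_n = self.W[1].shape[0]
        h2_n = self.W[1].shape[1]
        k = len(self.classes_)
        cls_pos = {c: i for i, c in enumerate(self.classes_)}

        for _ in range(self.n_passes):
            for X_seq, y_seq in sequences:
                X_seq = np.asarray(X_seq, dtype=float)
                h_prev = np.zeros(h2_n)
                S_W2 = np.zeros((h2_n, h1_n, h2_n))  # dh[k]/dW2[i,j]
                S_Wr = np.zeros((h2_n, h2_n, h2_n))  # dh[k]/dWr[m,j]
                S_b2 = np.zeros((h2_n, h2_n))        # dh[k]/db2[j]
                for x, yt in zip(X_seq, y_seq):
                    a1, h, out = self._step(x, h_prev)
                    d = 1.0 - h ** 2
                    # sensitivity recursions: direct term + mixing through Wr
                    mix_W2 = np.einsum("mk,mij->kij", self.Wr, S_W2)
                    mix_Wr = np.einsum("mk,mij->kij", self.Wr, S_Wr)
                    mix_b2 = self.Wr.T @ S_b2
                    S_W2 = mix_W2
                    S_W2[np.arange(h2_n), :, np.arange(h2_n)] += a1[None, :]
                    S_W2 *= d[:, None, None]
                    S_Wr = mix_Wr
                    S_Wr[np.arange(h2_n), :, np.arange(h2_n)] += h_prev[None, :]
                    S_Wr *= d[:, None, None]
                    S_b2 = mix_b2
                    S_b2[np.arange(h2_n), np.arange(h2_n)] += 1.0
                    S_b2 *= d[:, None]

                    target = np.full(k, -1.0)
                    target[cls_pos[yt]] = 1.0
                    e_out = 2.0 * (out - target) * (1.0 - out ** 2)
                    g_h = e_out @ self.W[2].T          # dL/dh
                    lr = lr_map[yt]
                    # recurrent-layer updates through RTRL sensitivities
                    gW2 = np.einsum("k,kij->ij", g_h, S_W2)
                    gWr = np.einsum("k,kij->ij", g_h, S_Wr)
                    gb2 = g_h @ S_b2
                    # instantaneous updates for input and output layers
                    gW3 = np.outer(h, e_out)
                    gb3 = e_out
                    d_h_local = g_h * d
                    g_a1 = d_h_local @ self.W[1].T
                    d_a1 = g_a1 * (1.0 - a1 ** 2)
                    gW1 = np.outer(x, d_a1)
                    gb1 = d_a1

                    self.W[2] -= lr * gW3
                    self.b[2] -= lr * gb3
                    self.W[1] -= lr * gW2
                    self.b[1] -= lr * gb2
                    self.Wr -= lr * gWr
                    self.W[0] -= lr * gW1
                    self.b[0] -= lr * gb1
                    h_prev = h
        return self
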