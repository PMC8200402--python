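"""Per-feature z-score normalization fitted on the training fold only."""

from __future__ import annotations

import warnings

import numpy as np

__all__ = ["ZScaler", "zscore_fit_apply"]


class ZScaler:
    """Z-score scaler using training-fold population statistics (ddof=0).

    Constant features (zero SD) are centred only, with a warning.
    """

    def __init__(self) -> None:
        self.mean_: np.ndarray | None = None
        self.sd_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "ZScaler":
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("cannot fit scaler on an empty training set")
        self.mean_ = np.nanmean(X, axis=0)
        self.sd_ = np.nanstd(X, axis=0)
        if np.any(self.sd_ == 0):
            warnings.warn("constant feature(s): centred only", stacklevel=2)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("scaler not fitted")
        sd = np.where(self.sd_ == 0, 1.0, self.sd_)
        return (np.asarray(X, dtype=float) - self.mean_) / sd


def zscore_fit_apply(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fit z-scores on ``train`` and apply to both matrices."""
    scaler = ZScaler().fit(train)
    return scaler.transform(train), scaler.transform(test)
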