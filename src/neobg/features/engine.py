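"""Feature extraction engine: per-channel computation + channel-median pooling.

Features are computed on every non-rejected channel of each epoch and pooled
across channels with the median.  Synchrony features are computed on channel
pairs and pooled with the median over pairs; a channel's per-channel value is
the median over the pairs it participates in.  Rejected epochs (or epochs
where every channel is rejected) yield NaN values with the ``missing`` flag
set.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from itertools import combinations

import numpy as np

from ..core import EpochSet
from . import measures as M
from .registry import FEATURE_REGISTRY, FeatureRegistry

__all__ = ["ChannelContext", "FeatureTable", "compute_feature_table"]


class ChannelContext:
    """Lazily-cached intermediates for one channel of one epoch."""

    def __init__(self, x: np.ndarray, fs: float = M.FS):
        self.x = np.asarray(x, dtype=float)
        self.fs = fs

    @cached_property
    def psd(self):
        return M.periodogram_welch(self.x, self.fs)

    @cached_property
    def total_power(self) -> float:
        return M.band_power(self.x, (0.5, 30.0), psd=self.psd)

    @cached_property
    def env(self) -> np.ndarray:
        """Smoothed analytic-signal envelope (uV, amplitude scale)."""
        return M.smoothed_envelope(self.x, self.fs)

    @cached_property
    def env_p2p(self) -> np.ndarray:
        """Short-window peak-to-peak envelope (0.5 s windows, 0.25 s step)."""
        env, self.fs_env = M.p2p_envelope(self.x, self.fs)
        return env

    @cached_property
    def reeg(self) -> np.ndarray:
        return M.reeg(self.x, self.fs)

    @cached_property
    def hjorth(self):
        return M.hjorth_parameters(self.x)

    @cached_property
    def ent_segment(self) -> np.ndarray:
        return self.x[: M.ENTROPY_SEGMENT]

    @cached_property
    def mse_curve(self) -> np.ndarray:
        return M.multiscale_entropy_curve(self.ent_segment)

    @cached_property
    def ibi_stats(self) -> dict:
        env = self.env_p2p  # also sets fs_env
        return M.ibi_statistics(env, self.fs_env)


@dataclass
class FeatureTable:
    """Epochs x features matrix with provenance.

    ``values[e, f]`` is the channel-median aggregate; ``missing[e, f]`` is
    True when no channel could provide the feature (rejected epoch, all
    channels rejected, or a pairwise feature with fewer than two channels).
    """

    values: np.ndarray
    missing: np.ndarray
    feature_ids: list[str]
    subject_id: str
    per_channel: np.ndarray | None = None
    channel_labels: list[str] | None = None

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=self.feature_ids)


def compute_feature_table(epochset: EpochSet,
                          registry: FeatureRegistry = FEATURE_REGISTRY,
                          keep_per_channel: bool = False,
                          channel_subset: list[str] | None = None) -> FeatureTable:
    """Compute the full feature bank for every epoch of an :class:`EpochSet`.

    ``channel_subset`` restricts the computation to the named channels (used
    for the per-channel performance analysis); rejection flags still apply.
    """
    n_e, n_c = epochset.n_epochs, epochset.n_channels
    if channel_subset is None:
        ch_idx = list(range(n_c))
    else:
        ch_idx = [epochset.channel_labels.index(c) for c in channel_subset]
    n_f = len(registry)
    values = np.full((n_e, n_f), np.nan)
    missing = np.ones((n_e, n_f), dtype=bool)
    per_channel = (np.full((n_e, n_c, n_f), np.nan) if keep_per_channel else None)

    single_entries = [(j, e) for j, e in enumerate(registry) if not e.pairwise]
    pair_entries = [(j, e) for j, e in enumerate(registry) if e.pairwise]

    for ei in range(n_e):
        if epochset.epoch_rejected[ei]:
            continue
        good = [c for c in ch_idx if not epochset.channel_rejected[ei, c]]
        if not good:
            continue
        contexts = {c: ChannelContext(epochset.epochs[ei, c]) for c in good}

        for j, entry in single_entries:
            vals = np.array([entry.func(contexts[c]) for c in good], dtype=float)
            if per_channel is not None:
                for k, c in enumerate(good):
                    per_channel[ei, c, j] = vals[k]
            if np.isfinite(vals).any():
                values[ei, j] = float(np.nanmedian(vals))
                missing[ei, j] = False

        if len(good) >= 2:
            pairs = list(combinations(good, 2))
            for j, entry in pair_entries:
                pv = {}
                for a, b in pairs:
                    pv[(a, b)] = entry.func(contexts[a], contexts[b])
                arr = np.array(list(pv.values()), dtype=float)
                if np.isfinite(arr).any():
                    values[ei, j] = float(np.nanmedian(arr))
                    missing[ei, j] = False
                if per_channel is not None:
                    for c in good:
                        mine = [v for (a, b), v in pv.items() if c in (a, b)]
                        if mine:
                            per_channel[ei, c, j] = float(np.nanmedian(mine))

    return FeatureTable(values=values, missing=missing, feature_ids=registry.ids,
                        subject_id=epochset.subject_id, per_channel=per_channel,
                        channel_labels=list(epochset.channel_labels))
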