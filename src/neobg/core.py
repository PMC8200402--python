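"""Core data containers shared across the pipeline.

A :class:`Recording` holds continuous multi-channel EEG in microvolts with
10-20 channel labels; an :class:`EpochSet` holds the preprocessed 64 Hz,
5-minute epochs together with artifact masks and rejection flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: target sampling rate of the preprocessed signal (Hz)
FS_TARGET = 64
#: epoch duration (s)
EPOCH_SECONDS = 300
#: samples per channel in one preprocessed epoch
EPOCH_SAMPLES = FS_TARGET * EPOCH_SECONDS  # 19,200

#: sentinel for epochs an expert (or the pipeline) declared ungradable
REJECT = -1


@dataclass
class Recording:
    """Continuous multi-channel EEG.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        10-20 system electrode names (referential) or ``"A-B"`` strings for
        bipolar derivations.
    montage : {"referential", "bipolar"}
    artifact_mask : ndarray of bool, optional
        Same shape as ``data``; True marks artifactual samples.
    subject_id : str
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    montage: str = "referential"
    artifact_mask: np.ndarray | None = None
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.artifact_mask is not None:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != self.data.shape:
                raise ValueError("artifact_mask shape must match data")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not present in recording") from None


@dataclass
class EpochSet:
    """Preprocessed 5-minute epochs at 64 Hz.

    ``epochs`` has shape (n_epochs, n_channels, 19200); ``artifact_mask`` is a
    boolean array of the same shape.  ``channel_rejected[e, c]`` is True when
    at least the configured fraction of channel ``c`` in epoch ``e`` is
    artifactual; ``epoch_rejected[e]`` is True when at least half of the
    channels are rejected.
    """

    epochs: np.ndarray
    artifact_mask: np.ndarray
    channel_labels: list[str]
    subject_id: str = "S0"
    montage: str = "referential"
    channel_rejected: np.ndarray = field(default=None)  # type: ignore[assignment]
    epoch_rejected: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.ndim != 3 or self.epochs.shape[2] != EPOCH_SAMPLES:
            raise ValueError(
                f"epochs must be (n_epochs, n_channels, {EPOCH_SAMPLES})"
            )
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != self.epochs.shape:
            raise ValueError("artifact_mask shape must match epochs")
        n_e, n_c = self.epochs.shape[:2]
        if self.channel_rejected is None:
            self.channel_rejected = np.zeros((n_e, n_c), dtype=bool)
        if self.epoch_rejected is None:
            self.epoch_rejected = np.zeros(n_e, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


def child_seed(seed: int, *keys: int | str) -> int:
    """Derive a deterministic child seed (< 2**31) from a master seed.

    String keys are hashed with CRC32 so the derivation is stable across
    processes (unlike the built-in randomized ``hash``).
    """
    import zlib

    def _key(k: int | str) -> int:
        if isinstance(k, str):
            return zlib.crc32(k.encode()) & 0x7FFFFFFF
        return int(k) & 0x7FFFFFFF

    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF] + [_key(k) for k in keys])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
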