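"""Automated preprocessing: artifact scan, filtering, resampling, epoching.

The chain is fixed in this order:

1. per-sample artifact scan on the native-rate signal (|x| > 500 uV, flat
   runs >= 1 s, NaN),
2. 0.5-35 Hz band-pass (5th-order Chebyshev II, zero-phase),
3. resampling to 64 Hz with an anti-aliasing polyphase filter,
4. segmentation into non-overlapping 5-minute epochs (19,200 samples),
5. channel/epoch rejection (>= 25% artifactual samples rejects a channel,
   >= 50% rejected channels rejects the epoch; thresholds configurable).

The artifact mask is computed at the native rate (thresholding after
filtering would blur true amplitudes) and carried to 64 Hz by nearest-sample
mapping.
"""

from __future__ import annotations

import warnings
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .core import EPOCH_SAMPLES, FS_TARGET, EpochSet, Recording

__all__ = [
    "detect_artifact_samples", "bandpass_filter", "resample_to_64",
    "segment_epochs", "reject_channels_and_epochs", "derive_bipolar",
    "preprocess_recording",
]

#: amplitude artifact threshold (uV); samples strictly exceeding it are masked
AMPLITUDE_LIMIT_UV = 500.0
#: minimum duration of a constant-valued run to count as a flat artifact (s)
FLAT_MIN_S = 1.0
#: band-pass design: passband 0.5-35 Hz via Chebyshev II stopband edges/atten
BP_STOP_EDGES_HZ = (0.25, 40.0)
BP_STOP_ATTEN_DB = 40.0
BP_ORDER = 5

#: default rejection thresholds
CHANNEL_REJECT_FRACTION = 0.25
EPOCH_REJECT_FRACTION = 0.50

#: bipolar derivations used for the montage comparison
DEFAULT_BIPOLAR_PAIRS = (("F3", "P3"), ("F4", "P4"), ("P3", "P4"))


def detect_artifact_samples(signal: np.ndarray, fs: float) -> np.ndarray:
    """Boolean artifact mask for a single channel.

    True where |x| > 500 uV (strict), where the sample lies inside a
    constant-valued run of at least 1 s, or where the sample is NaN.
    """
    x = np.asarray(signal, dtype=float)
    mask = np.zeros(x.shape, dtype=bool)
    nan = ~np.isfinite(x)
    if nan.any():
        warnings.warn("non-finite samples masked as artifact", stacklevel=2)
        mask |= nan
    with np.errstate(invalid="ignore"):
        mask |= np.abs(x) > AMPLITUDE_LIMIT_UV

    min_run = int(round(FLAT_MIN_S * fs))
    if x.size >= min_run and min_run >= 1:
        # run-length encode equal consecutive values
        same = np.concatenate([[False], np.equal(x[1:], x[:-1])])
        # boundaries of runs of identical values
        run_id = np.cumsum(~same)
        counts = np.bincount(run_id)
        flat = counts[run_id] >= min_run
        mask |= flat
    return mask


def bandpass_filter(signal: np.ndarray, fs: float) -> np.ndarray:
    """0.5-35 Hz band-pass (5th-order Chebyshev type II, forward-backward).

    The design is specified by stopband edges 0.25 and 40 Hz with 40 dB
    attenuation; applied with ``sosfiltfilt`` for zero phase.
    """
    if fs < 100:
        raise ValueError("sampling rate must be >= 100 Hz for the 35 Hz passband edge")
    sos = sps.cheby2(BP_ORDER, BP_STOP_ATTEN_DB, BP_STOP_EDGES_HZ,
                     btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(signal, dtype=float), axis=-1)


def resample_to_64(signal: np.ndarray, fs_native: float) -> np.ndarray:
    """Resample to 64 Hz with an anti-aliasing polyphase filter.

    Output length is ``round(n_in * 64 / fs_native)``.
    """
    if fs_native not in (200.0, 250.0, 256.0, 200, 250, 256):
        warnings.warn(f"unusual native rate {fs_native} Hz", stacklevel=2)
    x = np.asarray(signal, dtype=float)
    frac = Fraction(FS_TARGET / fs_native).limit_denominator(10_000)
    y = sps.resample_poly(x, frac.numerator, frac.denominator, axis=-1)
    n_out = int(round(x.shape[-1] * FS_TARGET / fs_native))
    if y.shape[-1] > n_out:
        y = y[..., :n_out]
    elif y.shape[-1] < n_out:
        pad = np.zeros(y.shape[:-1] + (n_out - y.shape[-1],))
        y = np.concatenate([y, pad], axis=-1)
    return y


def _mask_to_64(mask: np.ndarray, fs_native: float, n_out: int) -> np.ndarray:
    """Carry a native-rate boolean mask to 64 Hz by nearest-sample mapping."""
    idx = np.round(np.arange(n_out) * fs_native / FS_TARGET).astype(int)
    idx = np.clip(idx, 0, mask.shape[-1] - 1)
    return mask[..., idx]


def segment_epochs(data_64: np.ndarray, mask_64: np.ndarray,
                   channel_labels: list[str], subject_id: str = "S0",
                   montage: str = "referential") -> EpochSet:
    """Cut a (channels x samples) 64 Hz array into 5-minute epochs.

    The trailing remainder (< 300 s) is dropped; a recording shorter than one
    epoch yields an empty set with a warning.
    """
    n = data_64.shape[-1]
    n_epochs = n // EPOCH_SAMPLES
    if n_epochs == 0:
        warnings.warn("recording shorter than one 5-min epoch; empty EpochSet",
                      stacklevel=2)
    n_ch = data_64.shape[0]
    used = n_epochs * EPOCH_SAMPLES
    epochs = data_64[:, :used].reshape(n_ch, n_epochs, EPOCH_SAMPLES).transpose(1, 0, 2)
    masks = mask_64[:, :used].reshape(n_ch, n_epochs, EPOCH_SAMPLES).transpose(1, 0, 2)
    return EpochSet(epochs=epochs.copy(), artifact_mask=masks.copy(),
                    channel_labels=list(channel_labels), subject_id=subject_id,
                    montage=montage)


def reject_channels_and_epochs(epochset: EpochSet,
                               channel_fraction: float = CHANNEL_REJECT_FRACTION,
                               epoch_fraction: float = EPOCH_REJECT_FRACTION) -> EpochSet:
    """Populate rejection flags (in place) and return the epoch set.

    A channel is rejected in an epoch when at least ``channel_fraction`` of
    its samples are artifactual; an epoch is rejected when at least
    ``epoch_fraction`` of the channels are rejected.  A ``channel_fraction``
    of 0 rejects any channel containing at least one artifactual sample.
    """
    frac = epochset.artifact_mask.mean(axis=2)  # epoch x channel
    if channel_fraction <= 0:
        epochset.channel_rejected = frac > 0
    else:
        epochset.channel_rejected = frac >= channel_fraction
    rej_frac = epochset.channel_rejected.mean(axis=1)
    epochset.epoch_rejected = rej_frac >= epoch_fraction
    return epochset


def derive_bipolar(recording: Recording,
                   pairs: tuple[tuple[str, str], ...] = DEFAULT_BIPOLAR_PAIRS) -> Recording:
    """Bipolar derivations (e.g. F3-P3) from a referential recording.

    Each output channel is the sample-wise difference of its two referential
    channels; artifact masks are OR-combined.
    """
    data = []
    masks = [] if recording.artifact_mask is not None else None
    labels = []
    for a, b in pairs:
        ia, ib = recording.channel_index(a), recording.channel_index(b)
        data.append(recording.data[ia] - recording.data[ib])
        if masks is not None:
            masks.append(recording.artifact_mask[ia] | recording.artifact_mask[ib])
        labels.append(f"{a}-{b}")
    return Recording(data=np.asarray(data), fs=recording.fs, channel_labels=labels,
                     montage="bipolar",
                     artifact_mask=None if masks is None else np.asarray(masks),
                     subject_id=recording.subject_id)


def preprocess_recording(recording: Recording,
                         channel_fraction: float = CHANNEL_REJECT_FRACTION,
                         epoch_fraction: float = EPOCH_REJECT_FRACTION) -> EpochSet:
    """Full chain: artifact scan -> filter -> resample -> epoch -> rejection."""
    fs = recording.fs
    mask_native = np.stack([detect_artifact_samples(ch, fs) for ch in recording.data])
    clean = np.nan_to_num(recording.data, nan=0.0, posinf=0.0, neginf=0.0)
    filtered = bandpass_filter(clean, fs)
    data64 = resample_to_64(filtered, fs)
    mask64 = _mask_to_64(mask_native, fs, data64.shape[-1])
    es = segment_epochs(data64, mask64, recording.channel_labels,
                        subject_id=recording.subject_id, montage=recording.montage)
    return reject_channels_and_epochs(es, channel_fraction, epoch_fraction)
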