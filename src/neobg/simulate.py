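"""Synthetic neonatal EEG generator.

Produces labelled multi-channel recordings whose background classes realize
the clinical seven-grade scoring system used for neonatal EEG after birth
asphyxia:

====== =========================================================
score  pattern
====== =========================================================
0      continuous activity (default envelope 25-50 uV)
1      trace alternant, IBI voltage >= 25 uV, IBI duration <= 6 s
2      trace alternant, IBI voltage >= 25 uV, IBI duration > 6 s
3      trace discontinu, IBI voltage < 25 uV
4      depressed/undifferentiated, persistent 5-15 uV
5      burst suppression, IBI voltage < 5 uV
6      very low voltage, < 5 uV
====== =========================================================

The carrier is band-limited 1/f-like coloured noise; discontinuous classes
multiply the carrier by a burst gate with gamma-distributed burst/IBI
durations and raised-cosine edges.  All channels share the burst gate (the
background is a global brain state) but carry independent noise.

Amplitude convention: envelope values are *peak-to-peak* targets in uV.  The
carrier is scaled to an RMS of env/5 and hard-clipped at +/- env/2, so class
amplitude bounds (e.g. "< 5 uV") hold strictly while the realized
peak-to-peak amplitude tracks the requested envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from .core import EPOCH_SECONDS, Recording, child_seed

__all__ = [
    "BackgroundClassParams",
    "SimConfig",
    "DEFAULT_CLASS_PARAMS",
    "simulate_epoch",
    "simulate_recording",
    "inject_artifacts",
]

#: scores whose signal alternates bursts and interburst intervals
DISCONTINUOUS_SCORES = (1, 2, 3, 5)
#: scores defined by their amplitude envelope alone
AMPLITUDE_SCORES = (0, 4, 6)

#: raised-cosine edge of the burst gate (s)
GATE_EDGE_S = 0.25
#: shape of the gamma distributions for burst / IBI durations
DURATION_GAMMA_SHAPE = 8.0
#: crossfade between background-state segments (s); must stay <= 30 s
CROSSFADE_S = 10.0


@dataclass(frozen=True)
class BackgroundClassParams:
    """Generative parameters of one background class.

    Amplitudes are peak-to-peak in uV; durations are means in seconds.
    ``continuous_amp_range_uv`` is used by the amplitude-defined classes
    (0, 4, 6); the burst/IBI fields by the discontinuous classes (1, 2, 3, 5).
    """

    score: int
    burst_amp_uv: float = 100.0
    ibi_amp_uv: float = 0.0
    ibi_dur_s: float = 5.0
    burst_dur_s: float = 5.0
    continuous_amp_range_uv: tuple[float, float] = (25.0, 50.0)
    spectral_exponent: float = 1.2

    def __post_init__(self) -> None:
        if self.score not in range(7):
            raise ValueError(f"score must be in 0..6, got {self.score}")
        if self.score in DISCONTINUOUS_SCORES:
            if self.burst_dur_s <= 0 or self.ibi_dur_s <= 0:
                raise ValueError("burst/IBI durations must be positive")
            if self.ibi_amp_uv < 0:
                raise ValueError("IBI amplitude must be nonnegative")
        lo, hi = self.continuous_amp_range_uv
        if not (0 <= lo <= hi):
            raise ValueError("continuous_amp_range_uv must satisfy 0 <= low <= high")
        self._validate_class_rules()

    def _validate_class_rules(self) -> None:
        """Check the class-defining inequalities of the clinical scoring table."""
        s = self.score
        if s == 1 and not (self.ibi_amp_uv >= 25 and self.ibi_dur_s <= 6):
            raise ValueError("score 1 requires IBI voltage >= 25 uV and IBI duration <= 6 s")
        if s == 2 and not (self.ibi_amp_uv >= 25 and self.ibi_dur_s > 6):
            raise ValueError("score 2 requires IBI voltage >= 25 uV and IBI duration > 6 s")
        if s == 3 and not (self.ibi_amp_uv < 25):
            raise ValueError("score 3 requires IBI voltage < 25 uV")
        if s == 5 and not (self.ibi_amp_uv < 5):
            raise ValueError("score 5 requires IBI voltage < 5 uV")
        if s == 4:
            lo, hi = self.continuous_amp_range_uv
            if not (5 <= lo and hi <= 15):
                raise ValueError("score 4 requires an amplitude envelope within [5, 15] uV")
        if s == 6:
            _, hi = self.continuous_amp_range_uv
            if not hi < 5:
                raise ValueError("score 6 requires an amplitude envelope < 5 uV")


#: default, well-separated parameters for each class; the continuous (score 0)
#: envelope is a configurable convention -- the clinical table gives no number.
DEFAULT_CLASS_PARAMS: dict[int, BackgroundClassParams] = {
    0: BackgroundClassParams(score=0, continuous_amp_range_uv=(25.0, 50.0)),
    1: BackgroundClassParams(score=1, burst_amp_uv=100.0, ibi_amp_uv=35.0,
                             ibi_dur_s=4.0, burst_dur_s=6.0),
    2: BackgroundClassParams(score=2, burst_amp_uv=100.0, ibi_amp_uv=35.0,
                             ibi_dur_s=9.0, burst_dur_s=6.0),
    3: BackgroundClassParams(score=3, burst_amp_uv=75.0, ibi_amp_uv=12.0,
                             ibi_dur_s=8.0, burst_dur_s=4.0),
    4: BackgroundClassParams(score=4, continuous_amp_range_uv=(6.0, 14.0)),
    5: BackgroundClassParams(score=5, burst_amp_uv=60.0, ibi_amp_uv=2.0,
                             ibi_dur_s=10.0, burst_dur_s=2.0),
    6: BackgroundClassParams(score=6, continuous_amp_range_uv=(1.5, 4.0)),
}


@dataclass
class SimConfig:
    """Configuration of a simulated multi-subject style recording.

    ``trajectory`` is a sequence of ``(score, duration_min)`` pairs; durations
    must be positive multiples of 5 minutes so that every 5-minute epoch has a
    single predominant class.  ``artifact_rate`` is events per hour.
    """

    trajectory: list[tuple[int, float]]
    n_channels: int = 4
    fs_native: float = 256.0
    artifact_rate: float = 0.0
    seed: int = 0
    channel_labels: list[str] | None = None
    class_params: dict[int, BackgroundClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PARAMS))
    subject_id: str = "S0"

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be positive")
        if self.fs_native not in (200.0, 250.0, 256.0):
            warnings.warn(
                f"fs_native={self.fs_native} is outside the usual clinical set "
                "{200, 250, 256} Hz", stacklevel=2)
        if not self.trajectory:
            raise ValueError("trajectory must contain at least one segment")
        for score, dur in self.trajectory:
            if score not in range(7):
                raise ValueError(f"unknown score {score} in trajectory")
            if dur <= 0 or abs(dur / 5.0 - round(dur / 5.0)) > 1e-9:
                raise ValueError("segment durations must be positive multiples of 5 min")
        if self.channel_labels is None:
            defaults = ["F3", "F4", "P3", "P4", "C3", "C4", "O1", "O2",
                        "Fp1", "Fp2", "T3", "T4", "T5", "T6", "F7", "F8"]
            if self.n_channels <= len(defaults):
                self.channel_labels = defaults[: self.n_channels]
            else:
                self.channel_labels = defaults + [
                    f"X{i}" for i in range(self.n_channels - len(defaults))]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("channel_labels length must equal n_channels")


# ---------------------------------------------------------------------------
# carrier and gate construction
# ---------------------------------------------------------------------------

def colored_noise(n: int, fs: float, exponent: float, rng: np.random.Generator,
                  band: tuple[float, float] = (0.5, 30.0)) -> np.ndarray:
    """Band-limited 1/f**exponent noise with unit RMS."""
    n_fft = int(n)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    amp = np.zeros_like(freqs)
    inband = (freqs >= band[0]) & (freqs <= band[1])
    amp[inband] = freqs[inband] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * amp, n=n_fft)
    rms = np.sqrt(np.mean(x ** 2))
    return x / rms if rms > 0 else x


def _burst_gate(duration_s: float, fs: float, ibi_dur_s: float, burst_dur_s: float,
                rng: np.random.Generator) -> np.ndarray:
    """Burst gate in [0, 1]: alternating IBI (0) and burst (1) plateaus with
    raised-cosine edges; durations drawn from gamma distributions with the
    configured means."""
    n = int(round(duration_s * fs))
    gate = np.zeros(n)
    shape = DURATION_GAMMA_SHAPE
    t = 0
    # random initial phase: start inside a burst or an IBI
    in_burst = bool(rng.random() < burst_dur_s / (burst_dur_s + ibi_dur_s))
    while t < n:
        mean = burst_dur_s if in_burst else ibi_dur_s
        dur = rng.gamma(shape, mean / shape)
        dur = max(dur, 2 * GATE_EDGE_S)  # keep edges from overlapping
        seg = int(round(dur * fs))
        if in_burst:
            gate[t: t + seg] = 1.0
        t += seg
        in_burst = not in_burst
    edge = int(round(GATE_EDGE_S * fs))
    if edge > 1:
        win = np.hanning(2 * edge + 1)
        win /= win.sum()
        gate = np.convolve(gate, win, mode="same")
    return np.clip(gate, 0.0, 1.0)


def _slow_modulation(duration_s: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Slow (~0.02-0.1 Hz) modulation in [0, 1] for continuous classes."""
    n = int(round(duration_s * fs))
    f_mod = rng.uniform(0.02, 0.1)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / fs
    return 0.5 + 0.5 * np.sin(2 * np.pi * f_mod * t + phase)


def _envelope(params: BackgroundClassParams, duration_s: float, fs: float,
              rng: np.random.Generator) -> np.ndarray:
    """Shared peak-to-peak target envelope (uV) over time."""
    if params.score in DISCONTINUOUS_SCORES:
        gate = _burst_gate(duration_s, fs, params.ibi_dur_s, params.burst_dur_s, rng)
        return params.ibi_amp_uv + (params.burst_amp_uv - params.ibi_amp_uv) * gate
    lo, hi = params.continuous_amp_range_uv
    mod = _slow_modulation(duration_s, fs, rng)
    return lo + (hi - lo) * mod


def simulate_epoch(params: BackgroundClassParams, n_channels: int, fs: float,
                   duration_s: float, seed: int) -> np.ndarray:
    """Simulate one multi-channel segment of a single background class.

    Returns an (n_channels, fs*duration_s) array in uV.  Channels share the
    burst gate / envelope (global background state) but have independent
    carrier noise.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    env = _envelope(params, duration_s, fs, rng)  # shared across channels
    out = np.empty((n_channels, n))
    for c in range(n_channels):
        carrier = colored_noise(n, fs, params.spectral_exponent, rng)
        x = carrier * (env / 5.0)
        np.clip(x, -env / 2.0, env / 2.0, out=x)
        out[c] = x
    return out


def simulate_recording(config: SimConfig) -> tuple[Recording, np.ndarray]:
    """Simulate a continuous recording following ``config.trajectory``.

    Segments are joined with a raised-cosine crossfade (10 s, well under the
    30 s cap).  Returns the recording and the ground-truth score per 5-minute
    epoch (the predominant class of that epoch).
    """
    fs = config.fs_native
    n_fade = int(round(CROSSFADE_S * fs))
    n_seg = len(config.trajectory)
    pieces: list[np.ndarray] = []
    truth: list[int] = []
    for i, (score, dur_min) in enumerate(config.trajectory):
        params = config.class_params[score]
        if params.score != score:
            raise ValueError(f"class_params[{score}] has score {params.score}")
        # internal segments carry a crossfade tail so the overlap-add below
        # preserves the total duration exactly
        extra = CROSSFADE_S if i < n_seg - 1 else 0.0
        seg = simulate_epoch(params, config.n_channels, fs,
                             dur_min * 60.0 + extra,
                             child_seed(config.seed, "segment", i))
        pieces.append(seg)
        truth.extend([score] * int(round(dur_min / 5.0)))

    data = pieces[0]
    ramp = 0.5 - 0.5 * np.cos(np.linspace(0, np.pi, n_fade))  # 0 -> 1
    for seg in pieces[1:]:
        blended = data[:, -n_fade:] * (1 - ramp) + seg[:, :n_fade] * ramp
        data = np.concatenate([data[:, :-n_fade], blended, seg[:, n_fade:]],
                              axis=1)

    rec = Recording(data=data, fs=fs, channel_labels=list(config.channel_labels),
                    montage="referential", subject_id=config.subject_id)
    truth_arr = np.asarray(truth, dtype=int)
    n_epochs = int(rec.duration_s // EPOCH_SECONDS)
    return rec, truth_arr[:n_epochs]


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

def inject_artifacts(recording: Recording, rate: float,
                     kinds: tuple[str, ...] = ("high_amplitude", "flat"),
                     seed: int = 0) -> tuple[Recording, list[dict]]:
    """Inject NICU-style artifacts at ``rate`` events/hour.

    ``high_amplitude`` events exceed +/- 500 uV; ``flat`` events hold the
    channel constant for at least 1 s.  Returns a copy of the recording and a
    log of ``{"channel", "onset_s", "duration_s", "kind"}`` entries.
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    for k in kinds:
        if k not in ("high_amplitude", "flat"):
            raise ValueError(f"unknown artifact kind {k!r}")
    data = recording.data.copy()
    log: list[dict] = []
    if rate == 0 or not kinds:
        return replace_data(recording, data), log
    rng = np.random.default_rng(seed)
    hours = recording.duration_s / 3600.0
    n_events = rng.poisson(rate * hours)
    fs = recording.fs
    for _ in range(n_events):
        kind = kinds[rng.integers(len(kinds))]
        ch = int(rng.integers(recording.n_channels))
        if kind == "high_amplitude":
            dur = float(rng.uniform(0.5, 2.0))
        else:
            dur = float(rng.uniform(2.0, 10.0))
        onset = float(rng.uniform(0, max(recording.duration_s - dur, 0)))
        i0 = int(round(onset * fs))
        i1 = min(i0 + int(round(dur * fs)), data.shape[1])
        if kind == "high_amplitude":
            amp = float(rng.uniform(620.0, 900.0)) * (1 if rng.random() < 0.5 else -1)
            tt = np.arange(i1 - i0)
            pulse = amp * np.sin(np.pi * tt / max(len(tt) - 1, 1)) ** 2
            data[ch, i0:i1] += pulse
        else:
            data[ch, i0:i1] = data[ch, i0]
        log.append({"channel": recording.channel_labels[ch], "onset_s": onset,
                    "duration_s": dur, "kind": kind})
    return replace_data(recording, data), log


def make_cohort(n_subjects: int = 10, hours: float = 3.0, seed: int = 0,
                n_channels: int = 4, fs_native: float = 256.0,
                artifact_rate: float = 0.0) -> list[SimConfig]:
    """Configurations for a multi-subject cohort with varied trajectories.

    Each subject follows a trajectory of 30-minute background states drawn
    (seeded) from the seven classes, so every class is well represented
    across the cohort.
    """
    seg_min = 30.0
    n_seg = max(1, int(round(hours * 60.0 / seg_min)))
    configs = []
    for i in range(n_subjects):
        rng = np.random.default_rng(child_seed(seed, "cohort", i))
        scores: list[int] = []
        while len(scores) < n_seg:
            scores.extend(rng.permutation(7).tolist())
        traj = [(int(s), seg_min) for s in scores[:n_seg]]
        configs.append(SimConfig(trajectory=traj, n_channels=n_channels,
                                 fs_native=fs_native, artifact_rate=artifact_rate,
                                 seed=child_seed(seed, "subject", i),
                                 subject_id=f"S{i:02d}"))
    return configs


def simulate_raters(truth: np.ndarray, seed: int, confusion_prob: float = 0.10,
                    reject_prob: float = 0.02) -> tuple[np.ndarray, np.ndarray]:
    """Two independent noisy expert annotations of a ground-truth series.

    Each rater confuses an epoch with a neighbouring grade with probability
    ``confusion_prob`` and rejects it with probability ``reject_prob`` —
    emulating the neighbouring-score disagreement seen between human experts.
    """
    from .core import REJECT

    rng = np.random.default_rng(seed)
    raters = []
    for _ in range(2):
        scores = np.asarray(truth, dtype=int).copy()
        flip = rng.random(len(scores)) < confusion_prob
        delta = rng.choice([-1, 1], size=len(scores))
        scores[flip] = np.clip(scores[flip] + delta[flip], 0, 6)
        rej = rng.random(len(scores)) < reject_prob
        scores[rej] = REJECT
        raters.append(scores)
    return raters[0], raters[1]


def replace_data(recording: Recording, data: np.ndarray) -> Recording:
    """Copy of a recording with new sample data."""
    return Recording(data=data, fs=recording.fs,
                     channel_labels=list(recording.channel_labels),
                     montage=recording.montage,
                     artifact_mask=None if recording.artifact_mask is None
                     else recording.artifact_mask.copy(),
                     subject_id=recording.subject_id)
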