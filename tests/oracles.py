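"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written in the most literal way possible
(loops, first-principles formulas) and stays independent of the package
internals it checks.
"""

from __future__ import annotations

import math

import numpy as np

REJECT = -1


def kappa_bruteforce(a, b) -> float:
    """Cohen's kappa from first principles."""
    a = list(a)
    b = list(b)
    pairs = [(x, y) for x, y in zip(a, b) if x != REJECT and y != REJECT]
    n = len(pairs)
    classes = sorted({x for p in pairs for x in p})
    p_o = sum(1 for x, y in pairs if x == y) / n
    p_e = 0.0
    for c in classes:
        pa = sum(1 for x, _ in pairs if x == c) / n
        pb = sum(1 for _, y in pairs if y == c) / n
        p_e += pa * pb
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o >= 1.0 - 1e-15 else 0.0
    return (p_o - p_e) / (1 - p_e)


def f1_scores_bruteforce(pred, ref):
    """(macro_f1, weighted_f1) from per-class precision/recall loops."""
    pred = list(pred)
    ref = list(ref)
    classes = sorted(set(pred) | set(ref))
    f1s, weights = [], []
    n = len(ref)
    for c in classes:
        tp = sum(1 for p, r in zip(pred, ref) if p == c and r == c)
        fp = sum(1 for p, r in zip(pred, ref) if p == c and r != c)
        fn = sum(1 for p, r in zip(pred, ref) if p != c and r == c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        f1s.append(f1)
        weights.append(sum(1 for r in ref if r == c) / n)
    macro = sum(f1s) / len(f1s)
    weighted = sum(f * w for f, w in zip(f1s, weights))
    return macro, weighted


def running_median_bruteforce(scores, window):
    """Centred running median with REJECT exclusion, lower-middle tie rule."""
    half = window // 2
    out = list(scores)
    for i, s in enumerate(scores):
        if s == REJECT:
            continue
        vals = sorted(v for v in scores[max(0, i - half): i + half + 1]
                      if v != REJECT)
        out[i] = vals[(len(vals) - 1) // 2]
    return out


def sample_entropy_bruteforce(x, m=2, r=None, r_factor=0.15):
    """Literal SampEn: loops over template pairs i < j."""
    x = np.asarray(x, dtype=float)
    if r is None:
        r = r_factor * x.std()
    n = len(x)
    N = n - m
    B = A = 0
    for i in range(N - 1):
        for j in range(i + 1, N):
            if max(abs(x[i + t] - x[j + t]) for t in range(m)) <= r:
                B += 1
                if max(abs(x[i + t] - x[j + t]) for t in range(m + 1)) <= r:
                    A += 1
    if B == 0 or A == 0:
        return float("nan")
    return -math.log(A / B)


def welch_band_power_bruteforce(x, band, fs=64.0, nperseg=512):
    """Hann-window Welch PSD by explicit segment loops + band integration."""
    x = np.asarray(x, dtype=float)
    nperseg = min(nperseg, len(x))
    step = nperseg // 2
    win = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(nperseg) / (nperseg - 1))
    scale = 1.0 / (fs * (win ** 2).sum())
    psds = []
    start = 0
    while start + nperseg <= len(x):
        seg = x[start: start + nperseg]
        seg = seg - seg.mean()
        spec = np.fft.rfft(seg * win)
        p = (np.abs(spec) ** 2) * scale
        p[1:-1] *= 2  # one-sided
        psds.append(p)
        start += step
    pxx = np.mean(psds, axis=0)
    f = np.fft.rfftfreq(nperseg, 1 / fs)
    sel = (f >= band[0]) & (f < band[1])
    return float(np.sum(pxx[sel]) * (f[1] - f[0]))


def median_aggregate_bruteforce(values):
    """Median across channels, NaNs ignored; NaN when nothing remains."""
    vals = [v for v in values if not math.isnan(v)]
    if not vals:
        return float("nan")
    vals.sort()
    k = len(vals)
    return vals[k // 2] if k % 2 else 0.5 * (vals[k // 2 - 1] + vals[k // 2])


# ---------------------------------------------------------------------------
# rule-based background-class oracle (thresholds from the clinical table)
# ---------------------------------------------------------------------------

def p2p_windows(x, fs, window_s=0.5, step_s=0.25):
    w = int(round(window_s * fs))
    step = int(round(step_s * fs))
    return np.array([np.ptp(x[i: i + w])
                     for i in range(0, len(x) - w + 1, step)])


def classify_epoch_oracle(x, fs=64.0):
    """Rule-based grade from the class-defining thresholds (25/5 uV, 6 s).

    Works on a clean single-class epoch of one channel.  The interburst
    voltage is the raw-signal peak-to-peak over IBI run interiors (burst
    ramps trimmed), matching the clinical reading of "IBI voltage".
    """
    env = p2p_windows(x, fs)
    fs_env = 4.0
    step = int(round(fs / fs_env))
    w = int(round(0.5 * fs))
    p95, p10, med = (np.percentile(env, q) for q in (95, 10, 50))
    if p95 < 5:
        return 6
    if p95 >= 25 and p95 - p10 > 30:
        # discontinuous: split bursts from IBIs midway between the extremes
        thr = 0.5 * (p10 + p95)
        below = env < thr
        runs = []
        start = None
        for i, b in enumerate(list(below) + [False]):
            if b and start is None:
                start = i
            elif not b and start is not None:
                if (i - start) / fs_env >= 1.0:
                    runs.append((start, i))
                start = None
        if not runs:
            return 0
        volts = []
        for a, b in runs:
            if b - a >= 10:  # interior exists once ramps are trimmed
                lo, hi = (a + 3) * step, (b - 4) * step + w
                volts.append(np.ptp(x[lo:hi]))
        if not volts:  # only short IBIs: fall back to the envelope quartile
            volts = [np.percentile(env[a:b], 25) for a, b in runs]
        ibi_volt = np.median(volts)
        mean_dur = np.mean([(b - a) / fs_env for a, b in runs])
        if ibi_volt >= 25:
            return 1 if mean_dur <= 6 else 2
        if ibi_volt < 5:
            return 5
        return 3
    return 4 if med <= 16 else 0
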