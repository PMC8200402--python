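"""Signal measures underlying the feature registry.

All functions take 64 Hz signals in uV.  Degenerate inputs (constant or
all-zero signals) return NaN for entropy-type measures and documented
fallbacks elsewhere.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps

FS = 64.0

#: Welch periodogram: 8 s Hann windows, 50% overlap -> 0.125 Hz resolution
PSD_NPERSEG = 512
#: samples of the epoch used for entropy estimates (28.125 s at 64 Hz)
ENTROPY_SEGMENT = 1800
#: coarse-graining scales of the multiscale entropy curve
MSE_SCALES = tuple(range(1, 21))


# ---------------------------------------------------------------------------
# spectral
# ---------------------------------------------------------------------------

def periodogram_welch(x: np.ndarray, fs: float = FS):
    """Averaged windowed periodogram (PSD in uV^2/Hz)."""
    nperseg = min(PSD_NPERSEG, len(x))
    f, pxx = sps.welch(x, fs=fs, window="hann", nperseg=nperseg,
                       noverlap=nperseg // 2)
    return f, pxx


def band_power(x: np.ndarray, band: tuple[float, float], fs: float = FS,
               psd: tuple[np.ndarray, np.ndarray] | None = None) -> float:
    """Integrated spectral power (uV^2) in the half-open band [lo, hi)."""
    f, pxx = psd if psd is not None else periodogram_welch(x, fs)
    sel = (f >= band[0]) & (f < band[1])
    if not sel.any():
        return 0.0
    df = f[1] - f[0]
    return float(np.sum(pxx[sel]) * df)


def spectral_edge(f: np.ndarray, pxx: np.ndarray, fraction: float,
                  band: tuple[float, float] = (0.5, 30.0)) -> float:
    """Frequency below which ``fraction`` of the band's power lies."""
    sel = (f >= band[0]) & (f < band[1])
    p = pxx[sel]
    fr = f[sel]
    total = p.sum()
    if total <= 0:
        return float("nan")
    cum = np.cumsum(p) / total
    idx = int(np.searchsorted(cum, fraction))
    return float(fr[min(idx, len(fr) - 1)])


def spectral_entropy(f: np.ndarray, pxx: np.ndarray,
                     band: tuple[float, float] = (0.5, 30.0)) -> float:
    """Normalized Shannon entropy of the PSD within the band (0..1)."""
    sel = (f >= band[0]) & (f < band[1])
    p = pxx[sel]
    total = p.sum()
    if total <= 0 or sel.sum() < 2:
        return float("nan")
    p = p / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / np.log(sel.sum()))


def spectral_flatness(f: np.ndarray, pxx: np.ndarray,
                      band: tuple[float, float] = (0.5, 30.0)) -> float:
    sel = (f >= band[0]) & (f < band[1])
    p = pxx[sel]
    if p.size == 0 or np.any(p <= 0):
        return float("nan")
    return float(np.exp(np.mean(np.log(p))) / np.mean(p))


def spectral_slope(f: np.ndarray, pxx: np.ndarray,
                   band: tuple[float, float] = (2.0, 16.0)) -> float:
    """Slope of log10 PSD vs log10 frequency (the 1/f exponent is -slope)."""
    sel = (f >= band[0]) & (f < band[1]) & (pxx > 0)
    if sel.sum() < 3:
        return float("nan")
    return float(np.polyfit(np.log10(f[sel]), np.log10(pxx[sel]), 1)[0])


# ---------------------------------------------------------------------------
# amplitude / envelope
# ---------------------------------------------------------------------------

def smoothed_envelope(x: np.ndarray, fs: float = FS, cutoff: float = 1.0) -> np.ndarray:
    """Magnitude of the analytic signal, low-pass smoothed at ``cutoff`` Hz."""
    env = np.abs(sps.hilbert(x))
    sos = sps.butter(4, cutoff, btype="low", fs=fs, output="sos")
    sm = sps.sosfiltfilt(sos, env)
    return np.maximum(sm, 0.0)


def amplitude_modulation_stats(x: np.ndarray, fs: float = FS,
                               envelope: np.ndarray | None = None) -> tuple[float, float]:
    """(mean, SD) of the amplitude modulation (smoothed analytic envelope, uV)."""
    env = smoothed_envelope(x, fs) if envelope is None else envelope
    return float(env.mean()), float(env.std())


def reeg(x: np.ndarray, fs: float = FS, window_s: float = 2.0) -> np.ndarray:
    """Range-EEG: peak-to-peak amplitude in non-overlapping 2 s windows."""
    w = int(round(window_s * fs))
    n = len(x) // w
    if n == 0:
        return np.array([np.ptp(x)])
    seg = x[: n * w].reshape(n, w)
    return seg.max(axis=1) - seg.min(axis=1)


def hjorth_parameters(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth activity (uV^2), mobility, complexity."""
    activity = float(np.var(x))
    if activity == 0:
        return 0.0, float("nan"), float("nan")
    d1 = np.diff(x)
    d2 = np.diff(d1)
    m1 = np.sqrt(np.var(d1) / activity)
    v1 = np.var(d1)
    mobility = float(m1)
    complexity = float(np.sqrt(np.var(d2) / v1) / m1) if v1 > 0 else float("nan")
    return activity, mobility, complexity


def zero_crossing_rate(x: np.ndarray, fs: float = FS) -> float:
    """Zero crossings per second."""
    s = np.signbit(x)
    return float(np.count_nonzero(s[1:] != s[:-1]) / (len(x) / fs))


def line_length(x: np.ndarray) -> float:
    return float(np.abs(np.diff(x)).sum() / len(x))


def nonlinear_energy(x: np.ndarray) -> float:
    """Mean Teager-Kaiser energy."""
    if len(x) < 3:
        return 0.0
    return float(np.mean(x[1:-1] ** 2 - x[2:] * x[:-2]))


# ---------------------------------------------------------------------------
# discontinuity
# ---------------------------------------------------------------------------

#: short-window peak-to-peak envelope used by the discontinuity features
P2P_WINDOW_S = 0.5
P2P_STEP_S = 0.25


def p2p_envelope(x: np.ndarray, fs: float = FS, window_s: float = P2P_WINDOW_S,
                 step_s: float = P2P_STEP_S) -> tuple[np.ndarray, float]:
    """Peak-to-peak amplitude in sliding windows.

    Returns ``(env, fs_env)`` where ``env[k]`` is the p2p amplitude of the
    window starting at ``k * step_s`` and ``fs_env = 1 / step_s``.
    """
    w = int(round(window_s * fs))
    step = int(round(step_s * fs))
    n = max((len(x) - w) // step + 1, 1)
    if len(x) < w:
        return np.array([np.ptp(x)]), 1.0 / step_s
    idx = np.arange(n)[:, None] * step + np.arange(w)[None, :]
    seg = x[idx]
    return seg.max(axis=1) - seg.min(axis=1), 1.0 / step_s


def suppression_ratio(env_p2p: np.ndarray, threshold_uv: float) -> float:
    """Fraction of time the peak-to-peak envelope stays below ``threshold_uv``."""
    return float(np.mean(env_p2p < threshold_uv))


def segment_runs(below: np.ndarray, fs: float, min_s: float) -> list[tuple[int, int]]:
    """(start, stop) index pairs of True-runs lasting at least ``min_s``."""
    if not below.any():
        return []
    padded = np.concatenate([[False], below, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    min_n = int(round(min_s * fs))
    return [(a, b) for a, b in zip(starts, stops) if b - a >= min_n]


def ibi_statistics(env_p2p: np.ndarray, fs: float = 1.0 / P2P_STEP_S,
                   threshold_uv: float = 25.0, min_s: float = 1.0) -> dict:
    """Interburst-interval statistics from the peak-to-peak envelope.

    IBIs are runs where the envelope stays below ``threshold_uv`` for at
    least ``min_s``; bursts are the complementary runs.  The voltage of one
    IBI is the lower-quartile envelope over the run (robust to burst ramps at
    the run edges); ``ibi_voltage_p95_uv`` is the 95th percentile of that
    across IBIs.  All durations in s.
    """
    minutes = len(env_p2p) / fs / 60.0
    runs = segment_runs(env_p2p < threshold_uv, fs, min_s)
    burst_runs = segment_runs(env_p2p >= threshold_uv, fs, 0.5)
    durs = np.array([(b - a) / fs for a, b in runs])
    per_ibi_volt = [float(np.percentile(env_p2p[a:b], 25)) for a, b in runs]
    ibi_volt = float(np.percentile(per_ibi_volt, 95)) if runs else 0.0
    burst_durs = np.array([(b - a) / fs for a, b in burst_runs])
    burst_amp = (float(np.percentile(np.concatenate(
        [env_p2p[a:b] for a, b in burst_runs]), 95)) if burst_runs else 0.0)
    return {
        "ibi_count_per_min": len(runs) / minutes if minutes > 0 else 0.0,
        "ibi_mean_dur_s": float(durs.mean()) if durs.size else 0.0,
        "ibi_max_dur_s": float(durs.max()) if durs.size else 0.0,
        "ibi_sd_dur_s": float(durs.std()) if durs.size else 0.0,
        "ibi_voltage_p95_uv": ibi_volt,
        "burst_count_per_min": len(burst_runs) / minutes if minutes > 0 else 0.0,
        "burst_mean_dur_s": float(burst_durs.mean()) if burst_durs.size else 0.0,
        "burst_amp_p95_uv": burst_amp,
    }


# ---------------------------------------------------------------------------
# complexity
# ---------------------------------------------------------------------------

def _embed(x: np.ndarray, m: int) -> np.ndarray:
    """Delay-1 embedding matrix of shape (len(x)-m+1, m)."""
    n = len(x) - m + 1
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n]


try:  # jitted kernels make the entropy bank tractable on 5-min epochs
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _sampen_counts_jit(x, m, r):  # pragma: no cover - exercised via wrapper
        n = x.shape[0]
        N = n - m
        A = 0
        B = 0
        for i in range(N - 1):
            for j in range(i + 1, N):
                d = 0.0
                for t in range(m):
                    tmp = abs(x[i + t] - x[j + t])
                    if tmp > d:
                        d = tmp
                if d <= r:
                    B += 1
                    tmp = abs(x[i + m] - x[j + m])
                    if tmp > d:
                        d = tmp
                    if d <= r:
                        A += 1
        return A, B

    @njit(cache=True, fastmath=False)
    def _apen_phis_jit(x, m, r):  # pragma: no cover - exercised via wrapper
        n = x.shape[0]
        phis = np.empty(2)
        for step in range(2):
            mm = m + step
            N = n - mm + 1
            acc = 0.0
            for i in range(N):
                cnt = 0
                for j in range(N):
                    d = 0.0
                    for t in range(mm):
                        tmp = abs(x[i + t] - x[j + t])
                        if tmp > d:
                            d = tmp
                    if d <= r:
                        cnt += 1
                acc += np.log(cnt / N)
            phis[step] = acc / N
        return phis

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def _count_matches(templates: np.ndarray, r: float) -> int:
    """Number of ordered pairs i<j with Chebyshev distance <= r (blocked)."""
    n = len(templates)
    total = 0
    block = 256
    for i0 in range(0, n - 1, block):
        i1 = min(i0 + block, n - 1)
        chunk = templates[i0:i1]  # (b, m)
        # compare chunk rows i against all rows j > i
        d = np.abs(chunk[:, None, :] - templates[None, i0 + 1:, :]).max(axis=2)
        rows = np.arange(i0, i1)[:, None]
        cols = np.arange(i0 + 1, n)[None, :]
        total += int(np.count_nonzero((d <= r) & (cols > rows)))
    return total


def sample_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                   r_factor: float = 0.15) -> float:
    """Sample entropy SampEn(m, r): -ln(A/B) over template pairs (i < j).

    ``r`` defaults to ``r_factor * SD(x)``.  Returns NaN for constant signals
    or when no template pairs match.
    """
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0 or len(x) < m + 2:
        return float("nan")
    if r is None:
        r = r_factor * sd
    if _HAVE_NUMBA:
        a, b = _sampen_counts_jit(np.ascontiguousarray(x), m, float(r))
    else:
        # B: matches of length m among the first len(x)-m templates (standard
        # convention: same number of m and m+1 templates)
        tm = _embed(x, m)[: len(x) - m]
        tm1 = _embed(x, m + 1)
        b = _count_matches(tm, r)
        a = _count_matches(tm1, r)
    if b == 0 or a == 0:
        return float("nan")
    return float(-np.log(a / b))


def approximate_entropy(x: np.ndarray, m: int = 2, r: float | None = None,
                        r_factor: float = 0.15) -> float:
    """ApEn(m, r) with self-matches included (Pincus convention)."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0 or len(x) < m + 2:
        return float("nan")
    if r is None:
        r = r_factor * sd
    if _HAVE_NUMBA:
        phis = _apen_phis_jit(np.ascontiguousarray(x), m, float(r))
        return float(phis[0] - phis[1])

    def phi(mm: int) -> float:
        t = _embed(x, mm)
        n = len(t)
        counts = np.empty(n)
        block = 256
        for i0 in range(0, n, block):
            d = np.abs(t[i0:i0 + block, None, :] - t[None, :, :]).max(axis=2)
            counts[i0:i0 + block] = np.count_nonzero(d <= r, axis=1)
        return float(np.mean(np.log(counts / n)))

    return phi(m) - phi(m + 1)


def coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    n = len(x) // scale
    return x[: n * scale].reshape(n, scale).mean(axis=1)


def multiscale_entropy_curve(x: np.ndarray, scales=MSE_SCALES, m: int = 2,
                             r_factor: float = 0.15) -> np.ndarray:
    """Sample entropy at each coarse-graining scale; r fixed from SD(x)."""
    x = np.asarray(x, dtype=float)
    r = r_factor * x.std()
    return np.array([sample_entropy(coarse_grain(x, s), m=m, r=r) for s in scales])


def multiscale_entropy_slope(x: np.ndarray, scales=MSE_SCALES, m: int = 2,
                             r_factor: float = 0.15,
                             curve: np.ndarray | None = None) -> float:
    """Least-squares slope of the multiscale entropy curve vs scale."""
    cur = multiscale_entropy_curve(x, scales, m, r_factor) if curve is None else curve
    sc = np.asarray(scales, dtype=float)
    ok = np.isfinite(cur)
    if ok.sum() < 3:
        return float("nan")
    return float(np.polyfit(sc[ok], cur[ok], 1)[0])


def permutation_entropy(x: np.ndarray, order: int = 3) -> float:
    """Normalized permutation entropy (0..1), delay 1."""
    if len(x) < order + 1 or np.std(x) == 0:
        return float("nan")
    emb = _embed(x, order)
    ranks = np.argsort(np.argsort(emb, axis=1), axis=1)
    base = (order ** np.arange(order)).astype(float)
    codes = ranks @ base
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    import math
    return float(-(p * np.log(p)).sum() / math.log(math.factorial(order)))


def higuchi_fd(x: np.ndarray, kmax: int = 8) -> float:
    """Higuchi fractal dimension."""
    n = len(x)
    if np.std(x) == 0 or n < kmax * 3:
        return float("nan")
    lk = []
    ks = np.arange(1, kmax + 1)
    for k in ks:
        lengths = []
        for mstart in range(k):
            idx = np.arange(mstart, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (len(idx) - 1) / k
            lengths.append(dist * norm / k)
        lk.append(np.mean(lengths))
    coeffs = np.polyfit(np.log(1.0 / ks), np.log(lk), 1)
    return float(coeffs[0])


def katz_fd(x: np.ndarray) -> float:
    d1 = np.abs(np.diff(x))
    L = d1.sum()
    if L == 0:
        return float("nan")
    d = np.abs(x - x[0]).max()
    n = len(x) - 1
    if d == 0:
        return float("nan")
    import math
    return float(math.log10(n) / (math.log10(d / L) + math.log10(n)))


def dfa_alpha(x: np.ndarray,
              window_sizes: np.ndarray | None = None) -> float:
    """Detrended-fluctuation-analysis scaling exponent."""
    x = np.asarray(x, dtype=float)
    if np.std(x) == 0:
        return float("nan")
    y = np.cumsum(x - x.mean())
    n = len(y)
    if window_sizes is None:
        window_sizes = np.unique(np.floor(
            np.logspace(np.log10(8), np.log10(n // 4), 12)).astype(int))
    flucts = []
    for w in window_sizes:
        k = n // w
        seg = y[: k * w].reshape(k, w)
        t = np.arange(w)
        tm = t - t.mean()
        beta = (seg @ tm) / (tm @ tm)
        alpha_c = seg.mean(axis=1)
        detr = seg - (alpha_c[:, None] + beta[:, None] * tm[None, :])
        flucts.append(np.sqrt(np.mean(detr ** 2)))
    coeffs = np.polyfit(np.log(window_sizes), np.log(flucts), 1)
    return float(coeffs[0])


def lempel_ziv_complexity(x: np.ndarray) -> float:
    """Normalized Lempel-Ziv complexity of the median-binarized signal."""
    if np.std(x) == 0:
        return float("nan")
    s = (x > np.median(x)).astype(np.uint8).tobytes()
    n = len(s)
    # dictionary-style parsing: count distinct phrases
    substrings: set[bytes] = set()
    word = b""
    c = 0
    for ch in s:
        word += bytes([ch])
        if word not in substrings:
            substrings.add(word)
            c += 1
            word = b""
    import math
    return float(c * math.log2(n) / n) if n > 1 else float("nan")


def svd_entropy(x: np.ndarray, order: int = 10, delay: int = 1) -> float:
    """Normalized entropy of the singular-value spectrum of the embedding."""
    if np.std(x) == 0:
        return float("nan")
    n = len(x) - (order - 1) * delay
    if n < order:
        return float("nan")
    emb = np.array([x[i * delay: i * delay + n] for i in range(order)])
    sv = np.linalg.svd(emb, compute_uv=False)
    sv = sv / sv.sum()
    sv = sv[sv > 0]
    return float(-(sv * np.log(sv)).sum() / np.log(order))


def fisher_information(x: np.ndarray, order: int = 10, delay: int = 1) -> float:
    """Fisher information of the normalized singular-value spectrum."""
    if np.std(x) == 0:
        return float("nan")
    n = len(x) - (order - 1) * delay
    if n < order:
        return float("nan")
    emb = np.array([x[i * delay: i * delay + n] for i in range(order)])
    sv = np.linalg.svd(emb, compute_uv=False)
    sv = sv / sv.sum()
    return float(np.sum(np.diff(sv) ** 2 / sv[:-1]))


def ar_relative_residual(x: np.ndarray, order: int = 9) -> float:
    """Relative residual variance of a Yule-Walker AR fit (dimensionless)."""
    x = np.asarray(x, dtype=float)
    v = np.var(x)
    if v == 0 or len(x) <= order + 1:
        return float("nan")
    xc = x - x.mean()
    acf = np.array([xc[: len(xc) - k] @ xc[k:] for k in range(order + 1)]) / len(xc)
    from scipy.linalg import solve_toeplitz
    try:
        phi = solve_toeplitz(acf[:-1], acf[1:])
    except np.linalg.LinAlgError:
        return float("nan")
    resid_var = acf[0] - phi @ acf[1:]
    return float(max(resid_var, 0.0) / acf[0])


# ---------------------------------------------------------------------------
# synchrony (channel pairs)
# ---------------------------------------------------------------------------

def activation_synchrony_index(a: np.ndarray, b: np.ndarray, fs: float = FS,
                               env_a: np.ndarray | None = None,
                               env_b: np.ndarray | None = None) -> float:
    """Co-occurrence of high-amplitude activations between two channels.

    Each channel's smoothed envelope is binarized at its own 75th percentile;
    the index is the phi coefficient (Pearson correlation of the binary
    activation indicators).  Symmetric; 1 for identical channels; 0 fallback
    when either channel has a degenerate (constant) envelope.
    """
    if len(a) != len(b):
        raise ValueError("channels must have the same length")
    ea = smoothed_envelope(a, fs) if env_a is None else env_a
    eb = smoothed_envelope(b, fs) if env_b is None else env_b
    ga = ea > np.percentile(ea, 75)
    gb = eb > np.percentile(eb, 75)
    if ga.std() == 0 or gb.std() == 0:
        return 0.0
    return float(np.corrcoef(ga.astype(float), gb.astype(float))[0, 1])


def envelope_correlation(a: np.ndarray, b: np.ndarray, fs: float = FS,
                         env_a: np.ndarray | None = None,
                         env_b: np.ndarray | None = None) -> float:
    ea = smoothed_envelope(a, fs) if env_a is None else env_a
    eb = smoothed_envelope(b, fs) if env_b is None else env_b
    if ea.std() == 0 or eb.std() == 0:
        return 0.0
    return float(np.corrcoef(ea, eb)[0, 1])


def band_coherence(a: np.ndarray, b: np.ndarray, band: tuple[float, float],
                   fs: float = FS) -> float:
    """Mean magnitude-squared coherence within the band."""
    nperseg = min(PSD_NPERSEG, len(a))
    f, cxy = sps.coherence(a, b, fs=fs, nperseg=nperseg, noverlap=nperseg // 2)
    sel = (f >= band[0]) & (f < band[1])
    if not sel.any():
        return float("nan")
    return float(cxy[sel].mean())


def max_crosscorrelation(a: np.ndarray, b: np.ndarray, fs: float = FS,
                         max_lag_s: float = 0.5) -> float:
    """Maximum absolute normalized cross-correlation within +/- max_lag_s."""
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    full = sps.fftconvolve(a, b[::-1], mode="full")
    center = len(b) - 1
    lag = int(round(max_lag_s * fs))
    window = full[center - lag: center + lag + 1]
    return float(np.abs(window).max() / denom)
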