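"""The 98-feature registry.

Features are grouped in six categories — amplitude, spectral, modulation,
discontinuity, complexity and synchrony — filling the standard neonatal qEEG
canon.  Five anchor features used throughout the field are present under
stable ids: ``am_sd``, ``asi``, ``am_mean``, ``mse_slope`` and ``bp_9_11``.

Each entry declares how it responds to a signal gain ``g``:

* ``linear`` — value scales with g (amplitudes, envelopes),
* ``quadratic`` — value scales with g**2 (powers, variances),
* ``invariant`` — dimensionless (entropies, relative powers, synchrony),
* ``other`` — depends on fixed uV thresholds (suppression/IBI statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats as spstats

from . import measures as M

__all__ = ["RegistryEntry", "FeatureRegistry", "FEATURE_REGISTRY", "NAMED_TOP5"]

#: ids of the five anchor features reported as most informative
NAMED_TOP5 = ("am_sd", "asi", "am_mean", "mse_slope", "bp_9_11")

CATEGORIES = ("amplitude", "spectral", "modulation", "discontinuity",
              "complexity", "synchrony")


@dataclass(frozen=True)
class RegistryEntry:
    feature_id: str
    name: str
    category: str
    scaling: str  # linear | quadratic | invariant | other
    func: Callable  # ctx -> float, or (ctx_a, ctx_b) -> float for synchrony
    params: dict = field(default_factory=dict)

    @property
    def pairwise(self) -> bool:
        return self.category == "synchrony"


class FeatureRegistry:
    """Ordered collection of exactly 98 feature definitions."""

    def __init__(self, entries: list[RegistryEntry]):
        ids = [e.feature_id for e in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids")
        for e in entries:
            if e.category not in CATEGORIES:
                raise ValueError(f"unknown category {e.category}")
        self.entries = list(entries)
        self._by_id = {e.feature_id: e for e in entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, feature_id: str) -> RegistryEntry:
        return self._by_id[feature_id]

    @property
    def ids(self) -> list[str]:
        return [e.feature_id for e in self.entries]

    def by_category(self, category: str) -> list[RegistryEntry]:
        return [e for e in self.entries if e.category == category]


def _build() -> FeatureRegistry:
    E: list[RegistryEntry] = []

    def add(fid, name, cat, scaling, func, **params):
        E.append(RegistryEntry(fid, name, cat, scaling, func, params))

    # ----------------------------------------------------------------- amplitude
    add("amp_mean_abs", "mean absolute amplitude (uV)", "amplitude", "linear",
        lambda c: float(np.mean(np.abs(c.x))))
    add("amp_sd", "amplitude standard deviation (uV)", "amplitude", "linear",
        lambda c: float(np.std(c.x)))
    add("amp_rms", "root-mean-square amplitude (uV)", "amplitude", "linear",
        lambda c: float(np.sqrt(np.mean(c.x ** 2))))
    add("amp_ptp", "peak-to-peak amplitude (uV)", "amplitude", "linear",
        lambda c: float(np.ptp(c.x)))
    add("amp_skew", "amplitude skewness", "amplitude", "invariant",
        lambda c: float(spstats.skew(c.x)))
    add("amp_kurtosis", "amplitude excess kurtosis", "amplitude", "invariant",
        lambda c: float(spstats.kurtosis(c.x)))
    for p in (5, 25, 50, 75, 95):
        add(f"reeg_p{p:02d}", f"rEEG {p}th percentile (uV)", "amplitude", "linear",
            (lambda pp: lambda c: float(np.percentile(c.reeg, pp)))(p), percentile=p)
    add("reeg_mean", "rEEG mean (uV)", "amplitude", "linear",
        lambda c: float(np.mean(c.reeg)))
    add("reeg_sd", "rEEG standard deviation (uV)", "amplitude", "linear",
        lambda c: float(np.std(c.reeg)))
    add("reeg_asymmetry", "rEEG asymmetry", "amplitude", "invariant",
        lambda c: _reeg_asym(c))
    add("hjorth_activity", "Hjorth activity (uV^2)", "amplitude", "quadratic",
        lambda c: c.hjorth[0])
    add("hjorth_mobility", "Hjorth mobility", "amplitude", "invariant",
        lambda c: c.hjorth[1])
    add("hjorth_complexity", "Hjorth complexity", "amplitude", "invariant",
        lambda c: c.hjorth[2])
    add("line_length", "mean line length (uV/sample)", "amplitude", "linear",
        lambda c: M.line_length(c.x))
    add("nonlinear_energy", "mean Teager-Kaiser energy (uV^2)", "amplitude",
        "quadratic", lambda c: M.nonlinear_energy(c.x))
    add("zero_crossing_rate", "zero crossings per second", "amplitude",
        "invariant", lambda c: M.zero_crossing_rate(c.x))

    # ------------------------------------------------------------------ spectral
    coarse = {"0.5_3": (0.5, 3.0), "3_8": (3.0, 8.0), "8_15": (8.0, 15.0),
              "15_30": (15.0, 30.0), "9_11": (9.0, 11.0)}
    fine = {"0.5_1": (0.5, 1.0), "1_2": (1.0, 2.0), "2_3": (2.0, 3.0),
            "4_6": (4.0, 6.0), "6_8": (6.0, 8.0), "11_13": (11.0, 13.0)}
    for key, band in {**coarse, **fine}.items():
        add(f"bp_{key}", f"absolute power {band[0]}-{band[1]} Hz (uV^2)",
            "spectral", "quadratic",
            (lambda b: lambda c: M.band_power(c.x, b, psd=c.psd))(band), band=band)
    for key, band in {**coarse, **fine}.items():
        add(f"relbp_{key}", f"relative power {band[0]}-{band[1]} Hz",
            "spectral", "invariant",
            (lambda b: lambda c: _rel_power(c, b))(band), band=band)
    add("bp_total", "total power 0.5-30 Hz (uV^2)", "spectral", "quadratic",
        lambda c: c.total_power)
    for key, (b1, b2) in {"ratio_delta_theta": ((0.5, 3.0), (3.0, 8.0)),
                          "ratio_theta_alpha": ((3.0, 8.0), (8.0, 15.0)),
                          "ratio_alpha_beta": ((8.0, 15.0), (15.0, 30.0))}.items():
        add(key, f"power ratio {b1}/{b2}", "spectral", "invariant",
            (lambda x1, x2: lambda c: _power_ratio(c, x1, x2))(b1, b2))
    for frac in (0.80, 0.90, 0.95):
        add(f"sef{int(frac * 100)}", f"spectral edge frequency {int(frac*100)}% (Hz)",
            "spectral", "invariant",
            (lambda fr: lambda c: M.spectral_edge(*c.psd, fr))(frac), fraction=frac)
    add("peak_freq", "peak frequency 0.5-30 Hz (Hz)", "spectral", "invariant",
        lambda c: _peak_freq(c))
    add("median_freq", "median frequency (Hz)", "spectral", "invariant",
        lambda c: M.spectral_edge(*c.psd, 0.50))
    add("spectral_entropy", "normalized spectral entropy", "spectral",
        "invariant", lambda c: M.spectral_entropy(*c.psd))
    add("spectral_flatness", "spectral flatness 0.5-30 Hz", "spectral",
        "invariant", lambda c: M.spectral_flatness(*c.psd))
    add("spectral_slope", "log-log PSD slope 2-16 Hz", "spectral", "invariant",
        lambda c: M.spectral_slope(*c.psd))

    # ---------------------------------------------------------------- modulation
    add("am_mean", "amplitude-modulation mean (uV)", "modulation", "linear",
        lambda c: float(np.mean(c.env)))
    add("am_sd", "amplitude-modulation standard deviation (uV)", "modulation",
        "linear", lambda c: float(np.std(c.env)))
    add("am_cv", "amplitude-modulation coefficient of variation", "modulation",
        "invariant", lambda c: _safe_div(float(np.std(c.env)), float(np.mean(c.env))))
    add("am_skew", "amplitude-modulation skewness", "modulation", "invariant",
        lambda c: float(spstats.skew(c.env)))
    add("am_kurtosis", "amplitude-modulation excess kurtosis", "modulation",
        "invariant", lambda c: float(spstats.kurtosis(c.env)))
    add("am_median", "amplitude-modulation median (uV)", "modulation", "linear",
        lambda c: float(np.median(c.env)))
    add("am_p05", "amplitude-modulation 5th percentile (uV)", "modulation",
        "linear", lambda c: float(np.percentile(c.env, 5)))
    add("am_p95", "amplitude-modulation 95th percentile (uV)", "modulation",
        "linear", lambda c: float(np.percentile(c.env, 95)))
    add("am_depth", "modulation depth (p95-p05)/p50", "modulation", "invariant",
        lambda c: _safe_div(float(np.percentile(c.env, 95) - np.percentile(c.env, 5)),
                            float(np.median(c.env))))
    add("am_fluctuation_rate", "envelope mean-crossing rate (1/s)", "modulation",
        "invariant", lambda c: M.zero_crossing_rate(c.env - c.env.mean()))

    # ------------------------------------------------------------- discontinuity
    for thr in (5, 10, 15, 25):
        add(f"suppression_ratio_{thr}", f"fraction of time below {thr} uV",
            "discontinuity", "other",
            (lambda t: lambda c: M.suppression_ratio(c.env_p2p, t))(thr),
            threshold_uv=thr)
    for key in ("ibi_count_per_min", "ibi_mean_dur_s", "ibi_max_dur_s",
                "ibi_sd_dur_s", "ibi_voltage_p95_uv", "burst_count_per_min",
                "burst_mean_dur_s", "burst_amp_p95_uv"):
        add(key, key.replace("_", " "), "discontinuity", "other",
            (lambda k: lambda c: c.ibi_stats[k])(key), threshold_uv=25)

    # ---------------------------------------------------------------- complexity
    add("sample_entropy", "sample entropy (m=2, r=0.15 SD)", "complexity",
        "invariant", lambda c: M.sample_entropy(c.ent_segment))
    add("approximate_entropy", "approximate entropy (m=2, r=0.15 SD)",
        "complexity", "invariant", lambda c: M.approximate_entropy(c.ent_segment))
    add("mse_slope", "multiscale entropy curve slope", "complexity", "invariant",
        lambda c: M.multiscale_entropy_slope(c.ent_segment, curve=c.mse_curve))
    add("mse_mean", "multiscale entropy curve mean", "complexity", "invariant",
        lambda c: float(np.nanmean(c.mse_curve)) if np.isfinite(c.mse_curve).any()
        else float("nan"))
    for s in (5, 10, 20):
        add(f"mse_scale{s}", f"sample entropy at scale {s}", "complexity",
            "invariant",
            (lambda ss: lambda c: float(c.mse_curve[M.MSE_SCALES.index(ss)]))(s),
            scale=s)
    for order in (3, 5):
        add(f"perm_entropy_{order}", f"permutation entropy (order {order})",
            "complexity", "invariant",
            (lambda o: lambda c: M.permutation_entropy(c.ent_segment, o))(order),
            order=order)
    add("higuchi_fd", "Higuchi fractal dimension", "complexity", "invariant",
        lambda c: M.higuchi_fd(c.ent_segment))
    add("katz_fd", "Katz fractal dimension", "complexity", "invariant",
        lambda c: M.katz_fd(c.ent_segment))
    add("dfa_alpha", "DFA scaling exponent", "complexity", "invariant",
        lambda c: M.dfa_alpha(c.ent_segment))
    add("lzc", "Lempel-Ziv complexity (median binarized)", "complexity",
        "invariant", lambda c: M.lempel_ziv_complexity(c.ent_segment))
    add("svd_entropy", "SVD embedding entropy", "complexity", "invariant",
        lambda c: M.svd_entropy(c.ent_segment))
    add("fisher_info", "Fisher information of SVD spectrum", "complexity",
        "invariant", lambda c: M.fisher_information(c.ent_segment))
    add("ar_residual_rel", "relative AR(9) residual variance", "complexity",
        "invariant", lambda c: M.ar_relative_residual(c.x))

    # ----------------------------------------------------------------- synchrony
    add("asi", "activation synchrony index", "synchrony", "invariant",
        lambda a, b: M.activation_synchrony_index(a.x, b.x, env_a=a.env, env_b=b.env))
    add("env_correlation", "inter-channel envelope correlation", "synchrony",
        "invariant",
        lambda a, b: M.envelope_correlation(a.x, b.x, env_a=a.env, env_b=b.env))
    for key, band in {"coh_0.5_3": (0.5, 3.0), "coh_3_8": (3.0, 8.0),
                      "coh_8_15": (8.0, 15.0)}.items():
        add(key, f"mean coherence {band[0]}-{band[1]} Hz", "synchrony",
            "invariant", (lambda bb: lambda a, b: M.band_coherence(a.x, b.x, bb))(band),
            band=band)
    add("max_xcorr", "max cross-correlation (|lag| <= 0.5 s)", "synchrony",
        "invariant", lambda a, b: M.max_crosscorrelation(a.x, b.x))

    reg = FeatureRegistry(E)
    assert len(reg) == 98, f"registry has {len(reg)} features, expected 98"
    return reg


def _safe_div(a: float, b: float) -> float:
    return a / b if b not in (0.0, -0.0) and np.isfinite(b) else float("nan")


def _reeg_asym(c) -> float:
    p5, p50, p95 = (np.percentile(c.reeg, q) for q in (5, 50, 95))
    span = p95 - p5
    return float((p95 - 2 * p50 + p5) / span) if span > 0 else 0.0


def _rel_power(c, band) -> float:
    return _safe_div(M.band_power(c.x, band, psd=c.psd), c.total_power)


def _power_ratio(c, b1, b2) -> float:
    return _safe_div(M.band_power(c.x, b1, psd=c.psd),
                     M.band_power(c.x, b2, psd=c.psd))


def _peak_freq(c) -> float:
    f, pxx = c.psd
    sel = (f >= 0.5) & (f < 30.0)
    if not sel.any() or pxx[sel].max() <= 0:
        return float("nan")
    return float(f[sel][int(np.argmax(pxx[sel]))])


FEATURE_REGISTRY = _build()
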