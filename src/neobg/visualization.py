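"""Clinical displays: per-score probability heatmap and Background Trend.

The Background Trend (BT) collapses the per-epoch class posterior into a
single score-scale value — the probability-weighted average of the class
values — smoothed with a three-epoch moving average.  Its uncertainty band
is the probability-weighted standard deviation of the class values (zero
exactly when the posterior is one-hot).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import REJECT

__all__ = ["ProbSeries", "BTrend", "bt_from_probs", "heatmap_matrix",
           "render_report"]

#: default moving-average window of the BT display (epochs)
BT_WINDOW = 3


@dataclass
class ProbSeries:
    """Per-epoch class-posterior matrix with the score value of each class."""

    probs: np.ndarray               # epochs x K
    class_values: np.ndarray        # numeric score per class, severity order
    epoch_minutes: float = 5.0
    reject: np.ndarray | None = None  # epochs flagged ungradable

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.class_values = np.asarray(self.class_values, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(self.class_values):
            raise ValueError("probs must be epochs x K with K class values")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1) > 1e-6):
            raise ValueError("probability rows must sum to 1 (tol 1e-6)")

    @property
    def n_epochs(self) -> int:
        return self.probs.shape[0]


@dataclass
class BTrend:
    bt: np.ndarray
    uncertainty: np.ndarray
    bt_raw: np.ndarray
    window: int = BT_WINDOW


def bt_from_probs(series: ProbSeries, window: int = BT_WINDOW) -> BTrend:
    """Background Trend from a posterior series.

    ``bt_raw[t] = sum_c value(c) p[t, c]``; ``bt`` is its centred moving
    average (window shrunk at the edges); ``uncertainty[t]`` is the
    probability-weighted SD of the class values around ``bt_raw[t]``.
    """
    if series.n_epochs == 0:
        raise ValueError("empty probability series")
    v = series.class_values
    p = series.probs
    bt_raw = p @ v
    var = (p * (v[None, :] - bt_raw[:, None]) ** 2).sum(axis=1)
    unc = np.sqrt(np.maximum(var, 0.0))
    half = window // 2
    n = len(bt_raw)
    bt = np.empty(n)
    for t in range(n):
        lo, hi = max(0, t - half), min(n, t + half + 1)
        bt[t] = bt_raw[lo:hi].mean()
    return BTrend(bt=bt, uncertainty=unc, bt_raw=bt_raw, window=window)


def heatmap_matrix(series: ProbSeries, normalize: bool = True
                   ) -> tuple[np.ndarray, dict]:
    """K x T heatmap matrix plus its colour-mapping specification.

    Rows are ordered by increasing severity (class value); columns are
    epochs.  With ``normalize`` each column is renormalized to sum to one.
    REJECT epochs are flagged in the colour spec so the renderer can paint
    them in a distinct neutral colour.
    """
    order = np.argsort(series.class_values)
    mat = series.probs.T[order]
    if normalize:
        mat = mat / np.maximum(mat.sum(axis=0, keepdims=True), 1e-12)
    spec = {
        "cmap": "hot",
        "row_values": series.class_values[order],
        "vmin": 0.0,
        "vmax": 1.0,
        "reject_color": "0.6",
        "reject_epochs": (np.flatnonzero(series.reject)
                          if series.reject is not None else np.array([], int)),
    }
    return mat, spec


def render_report(series: ProbSeries, out_prefix: str,
                  reference: dict[str, np.ndarray] | None = None,
                  formats: tuple[str, ...] = ("svg",)) -> list[str]:
    """Two-panel clinical figure: heatmap above, BT with uncertainty below.

    ``reference`` maps overlay names (e.g. "E1", "E2") to per-epoch score
    series on the class-value scale; REJECT entries are not drawn.  Output is
    deterministic for identical input.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plt.rcParams["svg.hashsalt"] = "neobg"

    trend = bt_from_probs(series)
    mat, spec = heatmap_matrix(series)
    hours = np.arange(series.n_epochs) * series.epoch_minutes / 60.0

    fig, (ax1, ax2) = plt.subplots(
        2, 1, figsize=(10, 5), sharex=True,
        gridspec_kw={"height_ratios": [1, 1.2]})
    extent = (0, hours[-1] + series.epoch_minutes / 60.0,
              spec["row_values"][0] - 0.5, spec["row_values"][-1] + 0.5)
    ax1.imshow(mat, aspect="auto", origin="lower", cmap=spec["cmap"],
               vmin=spec["vmin"], vmax=spec["vmax"], extent=extent,
               interpolation="nearest")
    for e in spec["reject_epochs"]:
        ax1.axvspan(hours[e], hours[e] + series.epoch_minutes / 60.0,
                    color=spec["reject_color"])
    ax1.set_ylabel("score")
    ax1.set_title("background score probability")

    ax2.fill_between(hours, trend.bt - trend.uncertainty,
                     trend.bt + trend.uncertainty, color="0.8",
                     label="uncertainty")
    ax2.plot(hours, trend.bt, "k-", lw=1.2, label="BT")
    if reference:
        colors = {"E1": "tab:blue", "E2": "tab:green"}
        for name, scores in reference.items():
            if len(scores) != series.n_epochs:
                raise ValueError(f"overlay {name!r} length mismatch")
            s = np.asarray(scores, dtype=float)
            s[np.asarray(scores) == REJECT] = np.nan
            ax2.plot(hours, s, color=colors.get(name, "tab:orange"),
                     lw=0.8, label=name)
    ax2.set_xlabel("time (h)")
    ax2.set_ylabel("background trend")
    ax2.set_ylim(series.class_values.min() - 0.7, series.class_values.max() + 0.7)
    ax2.legend(loc="upper right", fontsize=8)
    fig.tight_layout()

    paths = []
    for fmt in formats:
        path = f"{out_prefix}.{fmt}"
        fig.savefig(path, format=fmt, metadata=_deterministic_metadata(fmt))
        paths.append(path)
    plt.close(fig)
    return paths


def _deterministic_metadata(fmt: str) -> dict:
    if fmt == "svg":
        return {"Date": None}
    if fmt == "pdf":
        return {"CreationDate": None}
    return {}
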