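"""Optional diagnostic plots for the sweep results (matplotlib, lazy import)."""

from __future__ import annotations

import pandas as pd


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_frequency_sweep(sweep: pd.DataFrame, path=None):
    """p value vs sampling interval, one panel per index, one curve per method."""
    plt = _plt()
    indices = list(sweep["index"].unique())
    fig, axes = plt.subplots(2, (len(indices) + 1) // 2, figsize=(4 * ((len(indices) + 1) // 2), 6),
                             sharex=True, sharey=True)
    for ax, index in zip(axes.ravel(), indices):
        sub = sweep[sweep["index"] == index]
        for method, marker in (("instantaneous", "D"), ("averaging", "o")):
            cell = sub[sub.method == method].sort_values("interval_s")
            ax.plot(cell.interval_s, cell.p_value, marker=marker, label=method, ms=4)
        ax.axhline(0.05, color="tab:blue", lw=1)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_title(index)
        ax.set_xlabel("sampling interval (s)")
        ax.set_ylabel("p value")
    axes.ravel()[0].legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
    return fig


def plot_duration_sweep(sweep: pd.DataFrame, path=None):
    """Semilogarithmic p value vs monitoring duration, one curve per statistic."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    for stat, sub in sweep.groupby("statistic"):
        sub = sub.sort_values("duration_h")
        ax.semilogy(sub.duration_h, sub.p_value, marker="o", ms=3, label=stat)
    ax.axhline(0.05, color="k", ls="--", lw=1)
    ax.set_xlabel("monitoring duration (h)")
    ax.set_ylabel("p value")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
    return fig
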