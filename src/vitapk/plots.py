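"""Matplotlib renderings of the standard model diagnostics."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from scipy import stats  # noqa: E402

__all__ = [
    "plot_obs_vs_pred",
    "plot_residuals",
    "plot_prediction_band",
    "plot_dose_response",
]


def plot_obs_vs_pred(obs_vs_pred, path=None):
    """Observations against individual predictions on log-log axes."""
    fig, ax = plt.subplots(figsize=(5, 5))
    x = obs_vs_pred["IPRED"].to_numpy()
    y = obs_vs_pred["DV"].to_numpy()
    ax.loglog(x, y, ".", alpha=0.5, color="tab:blue")
    lim = [min(x.min(), y.min()) * 0.8, max(x.max(), y.max()) * 1.2]
    ax.plot(lim, lim, "k-", lw=1)
    ax.set_xlabel("individual prediction (ng/ml)")
    ax.set_ylabel("observation (ng/ml)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_residuals(values, path=None, label="NPDE"):
    """Histogram and normal QQ plot of a residual-type diagnostic."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    axes[0].hist(values, bins=30, density=True, color="tab:blue", alpha=0.7)
    grid = np.linspace(-4, 4, 200)
    axes[0].plot(grid, stats.norm.pdf(grid), "k-", lw=1)
    axes[0].set_xlabel(label)
    stats.probplot(values, dist="norm", plot=axes[1])
    axes[1].set_title("")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_prediction_band(band, observations=None, path=None):
    """Quantile band for one subject-occasion with observations overlaid."""
    fig, ax = plt.subplots(figsize=(6, 4))
    t = band["TIME"].to_numpy()
    qcols = sorted(c for c in band.columns if c.startswith("q"))
    lo, hi = qcols[0], qcols[-1]
    ax.fill_between(t, band[lo], band[hi], color="tab:blue", alpha=0.25,
                    label=f"{lo[1:]}-{hi[1:]}% band")
    ax.plot(t, band["median"], color="tab:orange", label="median")
    if observations is not None:
        ax.plot(observations[0], observations[1], "k.", label="observed")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("concentration (ng/ml)")
    ax.legend()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_dose_response(table, path=None):
    """Time above each target vs dose, per route."""
    fig, ax = plt.subplots(figsize=(6, 4))
    tcols = [c for c in table.columns if c.startswith("t_above_")]
    for route, grp in table.groupby("route"):
        for col in tcols:
            ax.semilogx(grp["dose_mg_kg"], grp[col],
                        label=f"{route} {col.replace('t_above_', '')}")
    ax.set_xlabel("dose (mg/kg)")
    ax.set_ylabel("time above target (h)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
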