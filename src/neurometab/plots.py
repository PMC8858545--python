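"""Figure helpers: volcano plot, scatter with confidence band, ROC curve."""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from scipy import stats

__all__ = ["volcano_plot", "scatter_with_band", "roc_plot"]

_TIER_COLORS = {"none": "0.6", "q95": "tab:pink", "q975": "tab:cyan"}


def volcano_plot(screen_df: pd.DataFrame, path=None, title: str = ""):
    """Correlation-screen volcano: r vs -log10 permutation p, tier-colored."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for tier, sub in screen_df.groupby("tier"):
        ax.scatter(sub["r"], -np.log10(sub["p_perm"]),
                   c=_TIER_COLORS.get(tier, "k"), label=tier, s=25)
    for _, row in screen_df[screen_df["tier"] != "none"].iterrows():
        ax.annotate(row["feature"], (row["r"], -np.log10(row["p_perm"])), fontsize=7)
    ax.axhline(-np.log10(0.05), ls=":", c="0.4")
    ax.axhline(-np.log10(0.025), ls=":", c="0.7")
    ax.set_xlabel("Pearson r")
    ax.set_ylabel(r"$-\log_{10} P_r$")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def scatter_with_band(x, y, path=None, xlabel="", ylabel="", level: float = 0.95):
    """Scatter with least-squares line and pointwise confidence band."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    res = stats.linregress(x, y)
    grid = np.linspace(x.min(), x.max(), 200)
    yhat = res.intercept + res.slope * grid
    n = len(x)
    resid = y - (res.intercept + res.slope * x)
    s = np.sqrt(np.sum(resid**2) / (n - 2))
    half = (
        stats.t.ppf(0.5 + level / 2, n - 2)
        * s
        * np.sqrt(1 / n + (grid - x.mean()) ** 2 / np.sum((x - x.mean()) ** 2))
    )
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=25)
    ax.plot(grid, yhat, "k-")
    ax.plot(grid, yhat - half, "k:")
    ax.plot(grid, yhat + half, "k:")
    r = stats.pearsonr(x, y).statistic
    ax.set_title(f"$r^2$ = {r**2:.2f}")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig


def roc_plot(roc_results, path=None):
    """Overlayed binormal ROC curves with AUC legend entries."""
    fig, ax = plt.subplots(figsize=(4.2, 4))
    for rr in roc_results:
        ax.plot(rr.curve[:, 0], rr.curve[:, 1],
                label=f"{rr.feature} (AUC {rr.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    if path:
        fig.savefig(path)
        plt.close(fig)
    return fig
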