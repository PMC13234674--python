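"""Figure helpers: KDE marginals, attribution summaries, learning curves and
the MPSP heatmap.  All functions save to a path and return it."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .uncertainty import AttributionSummary, HeatmapGrid

__all__ = ["plot_kde_marginals", "plot_attribution_summary",
           "plot_learning_curve", "plot_heatmap"]


def plot_kde_marginals(curves: dict[str, pd.DataFrame], path: str | Path) -> Path:
    n = len(curves)
    ncols = min(3, max(1, n))
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(4 * ncols, 3 * nrows),
                             squeeze=False)
    for ax, (name, curve) in zip(axes.flat, curves.items()):
        ax.plot(curve["value"], curve["density"], color="tab:blue")
        ax.fill_between(curve["value"], curve["density"], alpha=0.2)
        ax.set_title(name, fontsize=9)
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_attribution_summary(summary: AttributionSummary, path: str | Path,
                             max_features: int = 12) -> Path:
    """Beeswarm-style summary: one horizontal strip of per-sample Shapley
    values per feature, colored by the feature's value."""
    ranking = summary.ranking().head(max_features)
    fig, ax = plt.subplots(figsize=(7, 0.45 * len(ranking) + 1.5))
    rng = np.random.default_rng(0)
    for row, name in enumerate(reversed(ranking.index)):
        phi = summary.attributions[name].to_numpy()
        vals = summary.feature_values[name].to_numpy(dtype=float)
        span = np.ptp(vals)
        color = (vals - vals.min()) / span if span > 0 else np.full_like(vals, 0.5)
        jitter = rng.normal(0.0, 0.06, len(phi))
        ax.scatter(phi, row + jitter, c=color, cmap="coolwarm", s=12,
                   edgecolors="none")
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(range(len(ranking)))
    ax.set_yticklabels(list(reversed(ranking.index)), fontsize=8)
    ax.set_xlabel(f"attribution to {summary.target} (USD/kg)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_learning_curve(curve: pd.DataFrame, path: str | Path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    for kind, color in [("train", "tab:blue"), ("validation", "tab:orange")]:
        ax.plot(curve["n_train"], curve[f"{kind}_r2"], "o-", color=color,
                label=kind)
        ax.fill_between(curve["n_train"],
                        curve[f"{kind}_r2"] - curve[f"{kind}_r2_std"],
                        curve[f"{kind}_r2"] + curve[f"{kind}_r2_std"],
                        color=color, alpha=0.15)
    ax.set_xlabel("training examples")
    ax.set_ylabel("$R^2$")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_heatmap(grid: HeatmapGrid, path: str | Path,
                 marr: float | None = None) -> Path:
    fig, ax = plt.subplots(figsize=(7, 5))
    mesh = ax.pcolormesh(grid.irr_axis, grid.upc_axis, grid.mpsp,
                         cmap="jet", shading="auto")
    fig.colorbar(mesh, ax=ax, label="MPSP (USD/kg)")
    if marr is not None:
        ax.axvline(marr, color="black", ls="--", lw=1,
                   label=f"MARR = {marr:.0%}")
        ax.legend(loc="upper left")
    ax.set_xlabel("IRR (after taxes)")
    ax.set_ylabel("UPC (USD/kg)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
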