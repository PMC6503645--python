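"""Map and study figures (matplotlib, headless-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .destination_sets import RegionLabel
from .spatial_stats import RasterField, StudyResult


def plot_field(field: RasterField, env=None):
    """Three-panel map: triage sub-regions, BHR vs nearest PSC, BHR vs
    nearest CSC (the latter two over the higher-order region only)."""
    fig, axes = plt.subplots(1, 3, figsize=(15, 5), constrained_layout=True)

    ax = axes[0]
    colors = {1: "#d9d9d9", 2: "#74a9cf", 3: "#d7301f"}
    for val, name in ((1, "CSC catchment"), (2, "simple triage"), (3, "higher order")):
        m = field.label == val
        ax.scatter(field.x[m], field.y[m], s=1, c=colors[val], label=name, rasterized=True)
    ax.legend(markerscale=8, loc="upper right", fontsize=8)
    ax.set_title("triage sub-regions")

    for ax, vals, title in (
        (axes[1], field.bhr_psc_max, "max BHR vs nearest PSC"),
        (axes[2], field.bhr_csc_max, "max BHR vs nearest CSC"),
    ):
        m = ~np.isnan(vals)
        ax.scatter(field.x[~m], field.y[~m], s=1, c="#eeeeee", rasterized=True)
        if m.any():
            sc = ax.scatter(field.x[m], field.y[m], s=1, c=vals[m], cmap="viridis", rasterized=True)
            fig.colorbar(sc, ax=ax, shrink=0.8)
        ax.set_title(title)

    if env is not None:
        for a in axes:
            for c in env.centers:
                marker = "o" if c.level == "CSC" else "x"
                a.plot(c.location.x, c.location.y, marker, color="k", ms=6)
    for a in axes:
        a.set_aspect("equal")
    return fig


def plot_study(study: StudyResult, stat: str = "triage_fraction"):
    """Boxplots of a per-environment statistic by PSC count, one panel
    per CSC count."""
    df = study.per_environment
    n_cscs = sorted(df["n_csc"].unique())
    fig, axes = plt.subplots(1, len(n_cscs), figsize=(4 * len(n_cscs), 4),
                             sharey=True, constrained_layout=True, squeeze=False)
    for ax, n_csc in zip(axes[0], n_cscs):
        sub = df[df["n_csc"] == n_csc]
        groups = sorted(sub["n_psc"].unique())
        data = [sub.loc[sub["n_psc"] == p, stat].dropna() for p in groups]
        ax.boxplot(data, tick_labels=[str(p) for p in groups])
        ax.set_title(f"{n_csc} CSC")
        ax.set_xlabel("PSCs")
    axes[0][0].set_ylabel(stat)
    return fig
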