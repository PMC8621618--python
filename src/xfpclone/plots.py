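"""Optional figures for cohort reports (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .metrics import COMPOSITION_ORDER


def size_vs_dispersion(summaries: pd.DataFrame, path=None):
    """Scatter of clone size against rostro-caudal dispersion."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    for comp, grp in summaries.groupby("composition"):
        ax.scatter(grp["size"], grp["rc_dispersion"], label=comp, alpha=0.7, s=18)
    ax.set_xlabel("clone size (cells)")
    ax.set_ylabel("R-C dispersion (µm)")
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def per_class_strip(summaries: pd.DataFrame, metric: str = "rc_dispersion", path=None):
    """Per-composition-class strip plot of a clone metric."""
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    classes = [c for c in COMPOSITION_ORDER if c in summaries["composition"].values]
    for i, comp in enumerate(classes):
        vals = summaries.loc[summaries["composition"] == comp, metric]
        ax.plot([i] * len(vals), vals, "o", alpha=0.6, ms=4)
    ax.set_xticks(range(len(classes)), classes, rotation=45, ha="right", fontsize=7)
    ax.set_ylabel(metric)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
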