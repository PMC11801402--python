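"""Optional figure side-outputs (all quantitative results live in the CSVs)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_kde_overlay(
    densities: dict[str, pd.DataFrame], title: str, path: str | Path
) -> None:
    """Overlay per-group KDE frequency curves, flow-cytometry style."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, frame in densities.items():
        ax.plot(frame["intensity_8bit"], frame["density"], label=label)
        peak_idx = frame["density"].idxmax()
        ax.axvline(
            frame["intensity_8bit"][peak_idx], linestyle="--", linewidth=0.8,
            color=ax.lines[-1].get_color(),
        )
    ax.set_xlabel("intensity (8-bit scale)")
    ax.set_ylabel("probability density")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rel_changes(rel_changes: pd.DataFrame, title: str, path: str | Path) -> None:
    """Bar chart of relative changes per histogram characteristic."""
    fig, ax = plt.subplots(figsize=(6, 4))
    pivot = rel_changes.pivot_table(
        index="metric", columns="modality", values="rel_change_pct", sort=False
    )
    pivot.plot.bar(ax=ax)
    ax.axhline(0, color="k", linewidth=0.8)
    ax.set_ylabel("relative change vs control (%)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
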