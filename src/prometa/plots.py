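"""Static regional association plots (LocusZoom-style, stacked panels)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .enrich import AnnotationTrack
from .ld import LDPanel

_LD_BINS = [(0.8, "#d62728"), (0.6, "#ff7f0e"), (0.4, "#2ca02c"),
            (0.2, "#17becf"), (0.0, "#7f7f7f")]


def _scatter_panel(ax, window: pd.DataFrame, lead: str,
                   panel: LDPanel | None, label: str) -> None:
    pos = window["POS"].to_numpy(float) / 1e6
    logp = -np.log10(np.clip(window["P"].to_numpy(float), 1e-300, 1.0))
    if panel is not None and panel.has(lead):
        r2 = panel.r2_with(lead)
        r2v = window["MARKER"].map(lambda m: r2.get(m, np.nan)).to_numpy(float)
    else:
        r2v = np.full(len(window), np.nan)
    for lo, color in _LD_BINS:
        mask = (r2v >= lo) if lo > 0 else (np.isnan(r2v) | (r2v < 0.2))
        if lo > 0:
            mask &= r2v < (lo + 0.2 if lo < 0.8 else 1.01)
        ax.scatter(pos[mask], logp[mask], s=14, c=color, edgecolors="none")
    is_lead = (window["MARKER"] == lead).to_numpy()
    if is_lead.any():
        ax.scatter(pos[is_lead], logp[is_lead], s=90, marker="D",
                   c="#9467bd", edgecolors="black", zorder=5, label="lead")
        ax.legend(loc="upper right", fontsize=8)
    ax.set_ylabel(f"{label}\n-log10 p")


def locus_plot(
    window: pd.DataFrame,
    lead: str,
    panel: LDPanel | None = None,
    extra_traits: dict[str, pd.DataFrame] | None = None,
    annotations: AnnotationTrack | None = None,
    path: str | Path = "locus.png",
    title: str | None = None,
) -> Path:
    """Stacked regional plot: -log10 p vs position, colored by LD with lead.

    ``extra_traits`` adds one panel per companion trait or eQTL gene over the
    same x-axis; ``annotations`` adds interval bars below.
    """
    if window.empty:
        raise ValueError("window is empty")
    extra_traits = extra_traits or {}
    n_panels = 1 + len(extra_traits) + (1 if annotations is not None else 0)
    heights = [3] * (1 + len(extra_traits)) + ([0.6] if annotations is not None else [])
    fig, axes = plt.subplots(
        n_panels, 1, sharex=True, figsize=(8, 1 + 2.2 * n_panels),
        gridspec_kw={"height_ratios": heights}, squeeze=False,
    )
    axes = axes.ravel()
    _scatter_panel(axes[0], window, lead, panel, "index trait")
    for ax, (name, df) in zip(axes[1:], extra_traits.items()):
        _scatter_panel(ax, df, lead, panel, name)
    if annotations is not None:
        ax = axes[-1]
        for chrom, (starts, ends) in annotations._per_chrom.items():
            for s, e in zip(starts, ends):
                ax.axvspan(s / 1e6, e / 1e6, color="#8c564b", alpha=0.6)
        ax.set_yticks([])
        ax.set_ylabel("tracks", rotation=0, ha="right", va="center")
    axes[-1].set_xlabel(f"chr{window['CHR'].iloc[0]} position (Mb)")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
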