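"""Plot helpers: germination curves with the desired-germination line and
growth-model scatter-plus-curve figures."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .germination import GerminationSeries
from .growth_model import SigmoidParams, sigmoid_predict


def plot_germination_curves(
    series_list: list[GerminationSeries],
    out_path: str | Path,
    threshold_pct: float = 90.0,
) -> Path:
    """Cumulative germination over days, one curve per cultivar, with a
    dashed grey line at the desired germination threshold; curves that stay
    below the line indicate poor germination."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for s in series_list:
        ax.plot(s.days, s.germination_pct, marker="o", label=s.cultivar or "series")
    ax.axhline(threshold_pct, color="grey", linestyle="--", label=f"desired {threshold_pct:g}%")
    ax.set_xlabel("days after sowing")
    ax.set_ylabel("germination (%)")
    ax.set_ylim(0, 105)
    ax.legend(fontsize=8)
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path


def plot_growth_fit(
    x, y, params: SigmoidParams, out_path: str | Path, labels=None
) -> Path:
    """Scatter of (canopy size, dry weight) with the fitted sigmoid overlaid."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(6, 4))
    if labels is not None:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            sel = labels == lab
            ax.scatter(x[sel], y[sel], s=12, label=str(lab))
        ax.legend(fontsize=8)
    else:
        ax.scatter(x, y, s=12)
    grid = np.linspace(x.min(), x.max(), 200)
    ax.plot(grid, sigmoid_predict(params, grid), color="black")
    ax.set_xlabel("projected canopy size (cm²)")
    ax.set_ylabel("shoot dry weight (g)")
    out_path = Path(out_path)
    fig.savefig(out_path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return out_path
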