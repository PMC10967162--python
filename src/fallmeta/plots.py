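"""Figure output: forest plot of pooled coefficients, hanging rootograms."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .meta import MetaResult, StudyEstimate
from .validation import RootogramData

__all__ = ["forest_plot", "rootogram_plot"]


def forest_plot(studies: dict[str, list[StudyEstimate]],
                pooled: dict[str, MetaResult],
                path: str | None = None,
                log_scale_names: set[str] | None = None):
    """Forest plot of per-study and pooled estimates, one block per
    coefficient.  Log-scale coefficients (rates, rate ratios) are shown
    exponentiated on a log axis; others (theta) on the linear scale.
    """
    if log_scale_names is None:
        log_scale_names = {name for name in studies if name != "theta"}

    rows = []  # (label, point, lo, hi, is_pooled)
    for name, ests in studies.items():
        tr = np.exp if name in log_scale_names else (lambda x: x)
        for e in ests:
            rows.append((f"{name}: {e.study}", tr(e.y), tr(e.y - 1.96 * e.se), tr(e.y + 1.96 * e.se), False))
        if name in pooled:
            r = pooled[name]
            rows.append((f"{name}: pooled", tr(r.mu), tr(r.ci95[0]), tr(r.ci95[1]), True))
        rows.append(None)  # spacer

    fig, ax = plt.subplots(figsize=(7, 0.32 * len(rows) + 1.2))
    ypos = len(rows)
    for row in rows:
        ypos -= 1
        if row is None:
            continue
        label, pt, lo, hi, is_pooled = row
        color = "firebrick" if is_pooled else "black"
        marker = "D" if is_pooled else "s"
        ax.plot([lo, hi], [ypos, ypos], color=color, lw=1.2)
        ax.plot([pt], [ypos], marker, color=color, ms=5)
        ax.text(-0.02, ypos, label, ha="right", va="center",
                transform=ax.get_yaxis_transform(), fontsize=8)
    ax.axvline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xscale("log")
    ax.set_yticks([])
    ax.set_xlabel("rate / rate ratio (95% CI)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def rootogram_plot(data: RootogramData, title: str = "", path: str | None = None):
    """Hanging rootogram: sqrt(observed) bars suspended from the
    sqrt(expected) curve; bars ending below the x-axis flag
    underestimated frequencies, floating bars overestimated ones."""
    fig, ax = plt.subplots(figsize=(7, 4))
    x = data.counts
    ax.bar(x, height=np.sqrt(data.observed_freq), bottom=data.bar_bottom,
           width=0.9, color="lightgrey", edgecolor="grey")
    ax.plot(x, np.sqrt(data.expected_freq), "o-", color="firebrick", ms=3, lw=1.2)
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xticks(x[:: max(1, len(x) // 12)])
    ax.set_xticklabels([data.labels[i] for i in range(0, len(x), max(1, len(x) // 12))])
    ax.set_xlabel("number of falls")
    ax.set_ylabel("sqrt(frequency)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
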