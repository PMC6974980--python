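"""Stacked-bar visualisation of read-category percentages."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .classify import CATEGORIES, EfficiencyReport

_COLORS = {
    "WT": "#9e9e9e",
    "Correct_HDR": "#2e7d32",
    "Incorrect_HDR": "#ef6c00",
    "Others": "#455a64",
}


def plot_category_bars(reports: Sequence[EfficiencyReport], path) -> None:
    """One stacked bar of category percentages per condition; saved to ``path``."""
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(reports), 4))
    xs = range(len(reports))
    bottom = [0.0] * len(reports)
    for cat in CATEGORIES:
        heights = [r.percentages[cat] for r in reports]
        ax.bar(xs, heights, bottom=bottom, label=cat, color=_COLORS[cat], width=0.6)
        bottom = [b + h for b, h in zip(bottom, heights)]
    ax.set_xticks(list(xs))
    ax.set_xticklabels([r.condition for r in reports], rotation=30, ha="right")
    ax.set_ylabel("% of assembled reads")
    ax.set_ylim(0, 100)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
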