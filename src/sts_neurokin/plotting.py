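"""Minimal per-variable figure: side-vs-side mean curves with SPM clusters."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .pipeline import N_NODES, GroupComparisonReport

__all__ = ["plot_comparison"]


def plot_comparison(
    report: GroupComparisonReport,
    condition: str,
    variable: str,
    path: str | Path,
) -> Path:
    """Group mean ± SE per side over the cycle, with significant clusters barred."""
    node_cols = [f"v{i}" for i in range(N_NODES)]
    sub = report.curves[(report.curves["condition"] == condition)
                        & (report.curves["variable"] == variable)]
    comp = report.comparison(condition, variable)

    fig, ax = plt.subplots(figsize=(6, 3.2))
    x = np.arange(N_NODES)
    colors = {"MI": "#e08a3c", "LI": "#2a6f4e"}
    for side, label in (("MI", "more impaired"), ("LI", "less impaired")):
        rows = sub[sub["side"] == side]
        per_subject = rows.groupby("subject")[node_cols].mean().to_numpy()
        if per_subject.size == 0:
            continue
        mean = per_subject.mean(axis=0)
        se = per_subject.std(axis=0, ddof=1) / np.sqrt(per_subject.shape[0])
        ax.plot(x, mean, color=colors[side], label=label)
        ax.fill_between(x, mean - se, mean + se, color=colors[side], alpha=0.25)
    if comp.result is not None:
        y0 = ax.get_ylim()[1]
        for cl in comp.result.clusters:
            if cl.p_value <= 0.05:
                ax.hlines(y0, cl.node_start, cl.node_end, lw=3, color="black")
                ax.annotate(f"p={cl.p_value:.3f}",
                            ((cl.node_start + cl.node_end) / 2, y0),
                            textcoords="offset points", xytext=(0, 4),
                            ha="center", fontsize=7)
    ax.set_xlabel("STS cycle (%)")
    ax.set_ylabel(variable)
    ax.set_title(f"{variable} — {condition} (n={comp.n})")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
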