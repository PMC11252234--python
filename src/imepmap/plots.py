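"""Simple diagnostic figures: CoG scatter and posterior histograms."""

from __future__ import annotations

import numpy as np

TASK_COLORS = {"iBB": "peru", "bBB": "gold", "iBB-cAE": "firebrick"}


def plot_cog_scatter(long_df, hotspot=None, axes=("x", "y"), ax=None):
    """Scatter individual CoGs per task in one coordinate plane.

    ``long_df`` is the long table from :func:`imepmap.mapping.group_cog_table`;
    ``hotspot`` an optional reference location drawn as cross-hair lines.
    """
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    a0, a1 = axes
    for task, sub in long_df.groupby("task", sort=False):
        color = TASK_COLORS.get(task)
        ax.scatter(sub[a0], sub[a1], s=18, alpha=0.6, label=task, color=color)
        ax.scatter(sub[a0].mean(), sub[a1].mean(), s=120, marker="+",
                   color=color or "k", linewidths=2)
    if hotspot is not None:
        hotspot = np.asarray(hotspot, float)
        idx = {"x": 0, "y": 1, "z": 2}
        ax.axvline(hotspot[idx[a0]], color="k", lw=0.8)
        ax.axhline(hotspot[idx[a1]], color="k", lw=0.8)
    ax.set_xlabel(f"{a0} (mm)")
    ax.set_ylabel(f"{a1} (mm)")
    ax.legend(frameon=False, fontsize=8)
    return ax
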