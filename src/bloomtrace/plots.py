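"""Plot helpers: ensemble envelope panels and zoned nutrient whisker plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .stats import GroupSummary

__all__ = ["plot_group_summary", "plot_climatology"]

_GROUP_STYLE = {"bloom": ("c", "bloom"), "no_bloom": ("k", "no bloom")}


def plot_group_summary(summaries: list[GroupSummary], axes=None):
    """Mean +/- sd envelopes vs. days before the event, one panel per variable."""
    if axes is None:
        _, axes = plt.subplots(len(summaries), 1, figsize=(7, 2.5 * len(summaries)),
                               sharex=True, squeeze=False)
        axes = axes[:, 0]
    for ax, s in zip(axes, summaries):
        t = s.times_rel_days
        for mean, sd, (color, label) in (
            (s.mean_bloom, s.sd_bloom, _GROUP_STYLE["bloom"]),
            (s.mean_nonbloom, s.sd_nonbloom, _GROUP_STYLE["no_bloom"]),
        ):
            ax.plot(t, mean, color=color, label=label)
            ax.fill_between(t, mean - sd, mean + sd, color=color, alpha=0.2)
        ax.set_ylabel(s.variable)
        ax.legend(loc="best", fontsize="small")
    axes[-1].set_xlabel("days relative to bloom event")
    return axes


def plot_climatology(stats: pd.DataFrame, variable: str, ax=None):
    """Side-by-side coastal/offshore whisker boxes per climatological month."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3))
    months = sorted(stats["month"].unique())
    colors = {"coastal": "peru", "offshore": "steelblue"}
    for zi, zone in enumerate(("coastal", "offshore")):
        sub = stats[(stats["variable"] == variable) & (stats["zone"] == zone)]
        for mi, month in enumerate(months):
            row = sub[sub["month"] == month]
            if row.empty or row["n_used"].iloc[0] == 0:
                continue
            r = row.iloc[0]
            x = mi + (-0.18 if zi == 0 else 0.18)
            ax.vlines(x, r["whisker_lo"], r["whisker_hi"], color=colors[zone])
            ax.add_patch(plt.Rectangle((x - 0.12, r["q25"]), 0.24,
                                       r["q75"] - r["q25"],
                                       facecolor=colors[zone], alpha=0.5))
            ax.hlines(r["median"], x - 0.12, x + 0.12, color="red")
    ax.set_xticks(np.arange(len(months)))
    ax.set_xticklabels(months)
    ax.set_xlabel("month")
    ax.set_ylabel(f"{variable} (umol/L)")
    return ax
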