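"""Plain diagnostic plots: cell means with bootstrap CIs, power curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)  # headless-safe default
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .simulate import COMPONENTS


def plot_components(results, fig=None):
    """Point estimates of the four fitness components per design cell.

    One panel per component; x-groups are site-soil combinations, with
    the two ecotypes side by side. A plain means plot (no styling beyond
    labels); bootstrap CIs for s are reported in the estimates table
    rather than drawn here.
    """
    summaries = results.cell_summaries
    if fig is None:
        fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
    else:
        axes = np.array(fig.subplots(2, 2, sharex=True))
    cells = summaries[["site", "soil"]].drop_duplicates().reset_index(drop=True)
    labels = [f"{r.site}\n{r.soil} soil" for r in cells.itertuples(index=False)]
    x = np.arange(len(cells))
    ecotypes = sorted(summaries["ecotype"].unique())
    offsets = np.linspace(-0.15, 0.15, len(ecotypes))
    for ax, comp in zip(axes.ravel(), COMPONENTS):
        for off, eco in zip(offsets, ecotypes):
            y = []
            for r in cells.itertuples(index=False):
                row = summaries[
                    (summaries["site"] == r.site)
                    & (summaries["soil"] == r.soil)
                    & (summaries["ecotype"] == eco)
                ]
                y.append(float(row[comp].iloc[0]) if len(row) else np.nan)
            ax.plot(x + off, y, "o", label=eco)
        ax.set_title(comp.replace("_", " "))
        ax.set_xticks(x, labels)
    axes.ravel()[0].legend(title="ecotype", fontsize=8)
    fig.suptitle("Fitness components by site, soil and ecotype")
    fig.tight_layout()
    return fig


def plot_power(power_df: pd.DataFrame, fig=None):
    """Rejection rate against true delta_s, one line per sample size."""
    if fig is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        ax = fig.subplots()
    for n, g in power_df.groupby("n"):
        g = g.sort_values("delta_s")
        ax.errorbar(
            g["delta_s"], g["rejection_rate"], yerr=2 * g["mc_se"],
            marker="o", capsize=3, label=f"n = {n}/cell",
        )
    ax.set_xlabel("true between-soil difference in selection (delta_s)")
    ax.set_ylabel("rejection rate")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    fig.tight_layout()
    return fig
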