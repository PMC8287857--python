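"""Condition-profile plots of the summary variables.

One panel per summary variable (bias, threshold, log10 lapse) against
absolute surround orientation, one line per condition with SEM error
bars — the standard way this literature displays center-surround bias
profiles.
"""

from __future__ import annotations

import pandas as pd

from .stats import ABS_SURROUNDS

_VARIABLES = [("bias", "bias (deg)"), ("threshold", "threshold (deg)"),
              ("log10_lapse", "log10 lapse rate")]


def plot_condition_profiles(summaries: pd.DataFrame, path=None):
    """Plot group mean +/- SEM of each summary variable per condition.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.6))
    for ax, (var, label) in zip(axes, _VARIABLES):
        for cond, grp in summaries.groupby("condition", sort=True):
            agg = grp.groupby("abs_surround")[var].agg(["mean", "sem"])
            agg = agg.reindex(list(ABS_SURROUNDS))
            ax.errorbar(
                agg.index, agg["mean"], yerr=agg["sem"], marker="o",
                capsize=3, label=cond,
            )
        ax.set_xlabel("|surround| (deg)")
        ax.set_ylabel(label)
        ax.set_xticks(list(ABS_SURROUNDS))
        if var == "bias":
            ax.axhline(0.0, color="0.7", lw=0.8, zorder=0)
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
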