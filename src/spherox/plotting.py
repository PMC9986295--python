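"""Quick-look plots of per-cavity oxygen curves."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["plot_cavity_curves"]

_ROI_COLORS = {"spheroid": "tab:red", "wall": "tab:gray",
               "chamfer": "tab:blue"}


def plot_cavity_curves(
    series: pd.DataFrame,
    path,
    value: str = "oxygen_norm",
    max_cavities: int = 16,
) -> None:
    """One panel per cavity: oxygen vs time for the three ROIs.

    Phase boundaries are drawn when the series carries a ``phase`` column.
    """
    if value not in series.columns:
        raise KeyError(f"series has no column {value!r}")
    cavities = sorted(set(zip(series["row"], series["col"])))[:max_cavities]
    n = len(cavities)
    ncols = min(4, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.4 * nrows),
        sharex=True, sharey=True, squeeze=False,
    )
    for ax, (r, c) in zip(axes.ravel(), cavities):
        sub = series[(series["row"] == r) & (series["col"] == c)]
        for roi, grp in sub.groupby("roi"):
            grp = grp.sort_values("time_min")
            ax.plot(grp["time_min"], grp[value], lw=1,
                    color=_ROI_COLORS.get(roi), label=roi)
        if "phase" in sub.columns:
            starts = sub.groupby("phase")["time_min"].min().sort_values()
            for t in starts.iloc[1:]:
                ax.axvline(t, color="0.8", lw=0.5, zorder=0)
        ax.set_title(f"cavity ({r}, {c})", fontsize=8)
    for ax in axes.ravel()[n:]:
        ax.set_visible(False)
    axes[0, 0].legend(fontsize=7)
    for ax in axes[-1]:
        ax.set_xlabel("time (min)")
    for row in axes:
        row[0].set_ylabel("O$_2$ (%a.s.)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
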