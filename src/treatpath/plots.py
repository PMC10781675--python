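"""Optional figures: stacked occupancy curves and deprivation-gap panels."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .msm import DAYS_PER_MONTH, OccupancyResult

STATE_LABELS = {"p11": "alive, untreated", "p12": "alive, treated", "p13": "dead"}
STATE_COLORS = {"p11": "#4477aa", "p12": "#228833", "p13": "#cc3311"}


def plot_occupancy(result: OccupancyResult, ax=None, title: str | None = None):
    """Stacked state-occupancy probabilities over months since diagnosis."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    months = result.times / DAYS_PER_MONTH
    ax.stackplot(
        months, result.p11, result.p12, result.p13,
        labels=[STATE_LABELS[s] for s in ("p11", "p12", "p13")],
        colors=[STATE_COLORS[s] for s in ("p11", "p12", "p13")],
        alpha=0.85,
    )
    ax.set_xlim(0, months[-1])
    ax.set_ylim(0, 1)
    ax.set_xlabel("months since diagnosis")
    ax.set_ylabel("probability")
    if title:
        ax.set_title(title)
    ax.legend(loc="center right", fontsize=8)
    return ax


def plot_contrast(contrast_table, ax=None, title: str | None = None):
    """Most-vs-least deprived differences with percentile bands per state."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for state, grp in contrast_table.groupby("quantity"):
        months = grp["time"].to_numpy() / DAYS_PER_MONTH
        color = STATE_COLORS.get(state, "grey")
        ax.plot(months, grp["difference"], color=color, label=STATE_LABELS.get(state, state))
        ax.fill_between(months, grp["lower"], grp["upper"], color=color, alpha=0.2)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("months since diagnosis")
    ax.set_ylabel("difference in probability")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax


def save_stratum_figures(res, outdir, quintiles=(1, 5)):
    """Write occupancy and contrast panels for one analysed stratum."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(1, len(quintiles) + 1, figsize=(4.5 * (len(quintiles) + 1), 3.2))
    for ax, q in zip(axes, quintiles):
        plot_occupancy(res.occupancy[q], ax=ax, title=f"quintile {q}")
    plot_contrast(res.contrast_occupancy, ax=axes[-1], title="most vs least deprived")
    fig.tight_layout()
    fig.savefig(out / f"{res.name}_occupancy.png", dpi=120)
    plt.close(fig)
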