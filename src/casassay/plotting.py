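"""Plots: sequence logo of the significant-PAM set and fit overlays."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .depletion import LogoMatrix
from .kinetics import ExponentialFitResults, _predict

_LOGO_COLORS = {"A": "#2ca02c", "G": "#2ca02c", "C": "#1f77b4", "T": "#1f77b4"}


def plot_logo(logo: LogoMatrix, path: str | Path | None = None, ax=None):
    """Draw the logo: letter heights are base frequency times information
    content, positions ordered as labelled (-5 ... -8, 5'->3')."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.0 + 0.8 * len(logo.frequencies), 2.5))
    for x, (label, row) in enumerate(logo.frequencies.iterrows()):
        ic = logo.bits[label]
        y = 0.0
        for base in sorted("ACGT", key=lambda b: row[b]):
            h = row[base] * ic
            if h <= 0:
                continue
            ax.text(x, y + h / 2, base, ha="center", va="center",
                    fontsize=10 + 18 * h, color=_LOGO_COLORS[base],
                    fontweight="bold", family="monospace")
            y += h
    ax.set_xticks(range(len(logo.frequencies)))
    ax.set_xticklabels(logo.frequencies.index)
    ax.set_xlim(-0.6, len(logo.frequencies) - 0.4)
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xlabel("PAM position")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_fit(results: ExponentialFitResults, path: str | Path | None = None, ax=None):
    """Observed points with the fitted exponential overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    course = results.model.course
    for rep, grp in course.observations.groupby("replicate"):
        ax.plot(grp["time"], grp["value"], "o", ms=4, alpha=0.6, label=str(rep))
    t = np.linspace(0, course.observations["time"].max(), 200)
    for f in results.fits:
        if f.nd or f.k_obs is None:
            continue
        ax.plot(t, _predict(t, f.k_obs, f.ymax, f.y0 or 0.0), "-", lw=1.5)
    unit = {"minute": "min", "second": "s"}[course.time_unit]
    ax.set_xlabel(f"time ({unit})")
    ax.set_ylabel(course.assay.replace("_", " "))
    ax.set_title(course.condition, fontsize=9)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
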