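"""Quick-look figures for traces and ribosome-density tables."""

from __future__ import annotations

import numpy as np

from .polysome import PeakAnnotation, ProfileTrace


def plot_trace(trace: ProfileTrace, annotation: PeakAnnotation | None = None,
               ax=None):
    """Absorbance trace with the 80S peak and polysome boundary marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    ax.plot(trace.positions, trace.absorbance, lw=1, color="black")
    if annotation is not None:
        ax.axvline(annotation.pos_80s, color="tab:blue", ls=":", label="80S")
        ax.axvline(annotation.polysome_boundary, color="tab:red", ls="--",
                   label="polysome boundary")
        ax.legend(frameon=False, fontsize=8)
    ax.set_xlabel("elution position")
    ax.set_ylabel("A254")
    ax.set_title(trace.label)
    return ax


def plot_rd_scatter(rd_table, ax=None):
    """Per-gene control vs treated RD on log axes with the diagonal."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    passing = rd_table[rd_table["passes_filter"]]
    ax.scatter(passing["rd_control"], passing["rd_treated"], s=8, alpha=0.5,
               color="tab:gray", edgecolors="none")
    lo = float(min(passing["rd_control"].min(), passing["rd_treated"].min()))
    hi = float(max(passing["rd_control"].max(), passing["rd_treated"].max()))
    ax.plot([lo, hi], [lo, hi], color="black", lw=0.8)
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("RD (control)")
    ax.set_ylabel("RD (treated)")
    return ax
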