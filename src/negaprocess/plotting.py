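"""Height-distribution graphics for negative-control baselines."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def render_distribution_plot(
    heights_by_dye: Mapping[str, Sequence[float]],
    plot_x_max: float,
    path: str | Path | None = None,
    bins: int = 60,
):
    """Overlaid height histograms (density) per dye, x-axis capped at ``plot_x_max``.

    Data beyond the cap is clipped out before rendering.  With no signals
    at all, an annotated placeholder figure is produced instead of a
    crash.  Returns the matplotlib figure.
    """
    fig, ax = plt.subplots(figsize=(7, 4.5))
    edges = np.linspace(0.0, plot_x_max, bins + 1)
    n_traces = 0
    for dye, heights in heights_by_dye.items():
        h = np.asarray(heights, dtype=float)
        h = h[(h >= 0) & (h <= plot_x_max)]
        if h.size == 0:
            continue
        ax.hist(h, bins=edges, density=True, alpha=0.35, label=dye)
        n_traces += 1
    if n_traces == 0:
        ax.annotate(
            "no negative signals",
            xy=(0.5, 0.5),
            xycoords="axes fraction",
            ha="center",
            fontsize=12,
        )
    else:
        ax.legend(title="dye")
    ax.set_xlim(0.0, plot_x_max)
    ax.set_xlabel("peak height (RFU)")
    ax.set_ylabel("density")
    ax.set_title("Negative-signal height distribution")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
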