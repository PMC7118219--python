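"""CV-analysis plot: normalized 1/CV^2 versus normalized mean.

The reference lines carry the interpretation: the horizontal line y = 1
marks purely postsynaptic expression (no change in release probability),
the unity diagonal demarcates presynaptic from postsynaptic expression,
and the vertical line x = 1 separates LTD (left) from LTP (right).
"""

from __future__ import annotations

from typing import Iterable, Optional, Union
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .quantal import CVPoint

__all__ = ["cv_plot"]


def cv_plot(
    points: Iterable[CVPoint],
    mean_point: Optional[CVPoint] = None,
    path: Optional[Union[str, Path]] = None,
    xlim: tuple = (0.0, 2.0),
    ylim: tuple = (0.0, 2.0),
):
    """Draw the CV-analysis plot and optionally save it (SVG/PNG by suffix).

    Returns the matplotlib figure.
    """
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    lo = min(xlim[0], ylim[0])
    hi = max(xlim[1], ylim[1])
    ax.axhline(1.0, color="k", lw=1.0, label="postsynaptic (y = 1)")
    ax.plot([lo, hi], [lo, hi], "k--", lw=1.0, label="diagonal (pre/post demarcation)")
    ax.axvline(1.0, color="k", ls=":", lw=0.8)
    xs = [p.mu_norm for p in points]
    ys = [p.inv_cv2_norm for p in points]
    ax.scatter(xs, ys, s=18, c="0.6", edgecolors="none", label="experiments")
    if mean_point is not None:
        ax.scatter(
            [mean_point.mu_norm],
            [mean_point.inv_cv2_norm],
            s=60,
            c="tab:red",
            marker="v",
            label="ensemble mean",
        )
    ax.set_xlim(*xlim)
    ax.set_ylim(*ylim)
    ax.set_xlabel(r"$\mu_{norm}$ (normalized mean)")
    ax.set_ylabel(r"$1/CV^2_{norm}$")
    ax.legend(fontsize=7, loc="upper left")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
    return fig
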