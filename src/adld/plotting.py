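"""Rendering of alignment diagrams.

Similar fragments are drawn as blue diagonal line segments and free
points as red star markers, on a square 1-based coordinate grid labelled
by the two sequence ids (longer sequence on the x axis).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends first
import matplotlib.pyplot as plt

from .core import Adld

__all__ = ["plot_adld", "save_adld_plot"]


def plot_adld(adld: Adld, ax: "plt.Axes | None" = None) -> "plt.Axes":
    """Draw the diagram onto ``ax`` (a new figure if omitted)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    for f in adld.fragments:
        ax.plot([f.start[0], f.end[0]], [f.start[1], f.end[1]],
                color="tab:blue", linewidth=1.5, solid_capstyle="round")
    if adld.free_points:
        xs, ys = zip(*adld.free_points)
        ax.plot(xs, ys, "r*", markersize=7, linestyle="none")
    lim = adld.n1 + 1
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_aspect("equal")
    ax.set_xlabel(adld.pair_ids[0])
    ax.set_ylabel(adld.pair_ids[1])
    p = adld.params
    ax.set_title(
        f"ADLD (ε={p.epsilon:g}, δ={p.delta}, ξ={p.xi}, w={adld.width})"
    )
    return ax


def save_adld_plot(adld: Adld, path: str | Path, dpi: int = 150) -> None:
    """Render the diagram to an image file."""
    ax = plot_adld(adld)
    fig = ax.figure
    fig.tight_layout()
    fig.savefig(path, dpi=dpi)
    plt.close(fig)
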