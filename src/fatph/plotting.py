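"""Diagram scatter and barcode rendering (matplotlib, Agg-friendly)."""

from __future__ import annotations

import numpy as np

from .persistence import PersistenceDiagram

__all__ = ["pool_diagrams", "plot_diagram", "plot_barcode", "close"]

_COLORS = {0: "tab:blue", 1: "tab:red"}


def pool_diagrams(diagrams) -> PersistenceDiagram:
    """Union of several diagrams' intervals (group-level view)."""
    if not diagrams:
        return PersistenceDiagram(np.empty(0, int), np.empty(0), np.empty(0))
    return PersistenceDiagram(
        np.concatenate([d.dims for d in diagrams]),
        np.concatenate([d.births for d in diagrams]),
        np.concatenate([d.deaths for d in diagrams]),
        source_label="pooled",
    )


def _finite_cap(diagram: PersistenceDiagram) -> float:
    finite = diagram.deaths[np.isfinite(diagram.deaths)]
    top = max(
        float(finite.max()) if len(finite) else 0.0,
        float(diagram.births.max()) if len(diagram) else 0.0,
    )
    return top * 1.05 + 1.0


def plot_diagram(diagram: PersistenceDiagram, title: str = ""):
    """Birth–death scatter with the diagonal reference line; essential
    classes are drawn at a cap above the largest finite value."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    cap = _finite_cap(diagram)
    for k in (0, 1):
        b, d = diagram.intervals(k)
        if len(b) == 0:
            continue
        d = np.where(np.isinf(d), cap, d)
        ax.scatter(b, d, s=12, alpha=0.6, color=_COLORS[k], label=f"dim {k}")
    ax.plot([0, cap], [0, cap], "k--", lw=0.8)
    ax.axhline(cap, color="gray", lw=0.5, ls=":")
    ax.set_xlabel("birth")
    ax.set_ylabel("death")
    if title:
        ax.set_title(title)
    ax.legend(loc="lower right")
    fig.tight_layout()
    return fig


def plot_barcode(diagram: PersistenceDiagram, title: str = "", max_bars: int = 200):
    """Interval rendering of the diagram; longest bars first per dimension."""
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    cap = _finite_cap(diagram)
    y = 0
    for k in (0, 1):
        b, d = diagram.intervals(k)
        d = np.where(np.isinf(d), cap, d)
        order = np.argsort(-(d - b))[:max_bars]
        for i in order:
            ax.hlines(y, b[i], d[i], color=_COLORS[k], lw=1.2)
            y += 1
    ax.set_xlabel("filtration value")
    ax.set_yticks([])
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig


def close(fig) -> None:
    import matplotlib.pyplot as plt

    plt.close(fig)
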