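"""Optional plotting helpers (requires matplotlib, extra ``plots``).

The ternary heatmap projects simplex points (a, b, c) onto the plane via
the standard equilateral-triangle map x = b + c/2, y = c*sqrt(3)/2 and
color-codes each grid composition by its probability.
"""

from __future__ import annotations

import numpy as np

from .mixtures import TernaryGrid


def plot_ternary(grid: TernaryGrid, ax=None, cmap: str = "viridis"):
    """Scatter-style ternary heatmap of mixture probabilities.

    Returns the matplotlib axes; raises ImportError with a hint when
    matplotlib is not installed.
    """
    try:
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "plotting requires matplotlib: pip install 'confshift[plots]'"
        ) from exc

    pts = grid.points
    x = pts["b"] + pts["c"] / 2.0
    y = pts["c"] * np.sqrt(3.0) / 2.0
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5.5))
    sc = ax.scatter(x, y, c=pts["probability"], cmap=cmap, s=180, marker="h",
                    edgecolors="none")
    ax.plot([0, 1, 0.5, 0], [0, 0, np.sqrt(3) / 2, 0], color="0.3", lw=1)
    ax.text(-0.02, -0.04, grid.axis_labels[0], ha="right")
    ax.text(1.02, -0.04, grid.axis_labels[1], ha="left")
    ax.text(0.5, np.sqrt(3) / 2 + 0.03, grid.axis_labels[2], ha="center")
    ax.set_aspect("equal")
    ax.axis("off")
    plt.colorbar(sc, ax=ax, label="probability", shrink=0.8)
    return ax
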