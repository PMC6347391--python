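"""Belief-simplex figures: cohort classification plots and recovery arrows."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .dst import BodyOfEvidence, simplex_coords

_SQRT3_2 = np.sqrt(3.0) / 2.0


def _triple_coords(m_oa: float, m_np: float, m_u: float) -> tuple[float, float]:
    return simplex_coords(BodyOfEvidence(m_oa, m_np, m_u))


def draw_simplex_frame(ax: plt.Axes) -> None:
    """Triangle outline, the B(OA)=B(NP) decision boundary (dashed) and the
    B(OA)=0.5 / B(NP)=0.5 interior boundaries (solid)."""
    tri = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, _SQRT3_2], [0.0, 0.0]])
    ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1)
    # decision boundary m_oa = m_np: from (0.5, 0.5, 0) to (0, 0, 1)
    ax.plot(
        *zip(_triple_coords(0.5, 0.5, 0.0), _triple_coords(0.0, 0.0, 1.0)),
        ls="--",
        color="grey",
        lw=1,
    )
    # loci B(OA) = 0.5 and B(NP) = 0.5
    ax.plot(
        *zip(_triple_coords(0.5, 0.5, 0.0), _triple_coords(0.5, 0.0, 0.5)),
        color="grey",
        lw=0.8,
    )
    ax.plot(
        *zip(_triple_coords(0.5, 0.5, 0.0), _triple_coords(0.0, 0.5, 0.5)),
        color="grey",
        lw=0.8,
    )
    ax.annotate("B(NP)=1", (0, 0), ha="right", va="top", fontsize=9)
    ax.annotate("B(OA)=1", (1, 0), ha="left", va="top", fontsize=9)
    ax.annotate("U=1", (0.5, _SQRT3_2), ha="center", va="bottom", fontsize=9)
    ax.set_aspect("equal")
    ax.axis("off")


def simplex_plot(beliefs: pd.DataFrame, path: str | Path | None = None) -> plt.Figure:
    """Scatter a per-subject belief table (columns x, y, true) on the simplex."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    draw_simplex_frame(ax)
    markers = {"OA": ("x", "tab:red"), "NP": ("o", "tab:blue")}
    for group, (marker, color) in markers.items():
        sub = beliefs[beliefs["true"] == group]
        if len(sub):
            ax.scatter(
                sub["x"], sub["y"], marker=marker, color=color,
                facecolors="none" if marker == "o" else color, label=group,
            )
    ax.legend(loc="upper right", frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def recovery_arrows(
    pre_beliefs: pd.DataFrame,
    post_beliefs: pd.DataFrame,
    path: str | Path | None = None,
) -> plt.Figure:
    """Arrows from each subject's pre-operative to post-operative belief point."""
    fig, ax = plt.subplots(figsize=(5, 4.5))
    draw_simplex_frame(ax)
    post = post_beliefs.reindex(pre_beliefs.index)
    for subj in pre_beliefs.index:
        x0, y0 = pre_beliefs.loc[subj, ["x", "y"]]
        x1, y1 = post.loc[subj, ["x", "y"]]
        ax.annotate(
            "",
            xy=(x1, y1),
            xytext=(x0, y0),
            arrowprops=dict(arrowstyle="->", color="purple", lw=0.9),
        )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
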