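"""Diagnostic figures: per-locus score scatter and the map-wide b profile."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_cluster_scatter(scores, clusters=None, path=None, title: str = ""):
    """Samples in the (v, b) score plane, colored by cluster.

    Homozygotes sit on the axes, heterozygotes near the diagonal, and
    low-coverage samples near the origin.
    """
    fig, ax = plt.subplots(figsize=(5, 5))
    labels = clusters.labels if clusters is not None else {}
    cmap = plt.get_cmap("tab10")
    for sid, sc in scores.items():
        ci = labels.get(sid)
        color = cmap(ci % 10) if ci is not None else "0.6"
        ax.plot(sc.v_score, sc.b_score, "o", ms=4, color=color, alpha=0.8)
    ax.set_xlabel("B. variegata score")
    ax.set_ylabel("B. bombina score")
    ax.set_title(title)
    lim = max(ax.get_xlim()[1], ax.get_ylim()[1])
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_b_profile(records: Sequence, path=None):
    """Sex-homozygote bias b along the linkage map, one panel per LG, with
    the autosomal null b = 0.5 marked."""
    recs = [r for r in records if r.linkage_group is not None]
    lgs = sorted({r.linkage_group for r in recs})
    if not lgs:
        raise ValueError("no mapped records to plot")
    fig, axes = plt.subplots(
        1, len(lgs), figsize=(1.6 * len(lgs) + 1, 3), sharey=True, squeeze=False
    )
    for ax, lg in zip(axes[0], lgs):
        sub = sorted(
            (r for r in recs if r.linkage_group == lg), key=lambda r: r.position_cM
        )
        ax.plot([r.position_cM for r in sub], [r.b for r in sub], "o-", ms=3)
        ax.axhline(0.5, color="tab:blue", lw=1, alpha=0.6)
        ax.set_title(f"LG{lg}", fontsize=9)
        ax.set_ylim(-0.02, 1.0)
    axes[0][0].set_ylabel("b")
    fig.supxlabel("position (cM)")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
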