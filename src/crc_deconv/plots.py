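"""Figure-style plots: copy-number heatmaps, compositions, feature violins."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.colors import ListedColormap

from .classify import RARE_LABELS
from .cnv import SegmentSet

#: gain = red, loss = blue, neutral = white
_CNV_CMAP = ListedColormap(["#2166ac", "#ffffff", "#b2182b"])
_STATE_CODE = {"loss": 0, "neutral": 1, "gain": 2}

_LABEL_COLORS = {"EPI.CTC": "#d95f02", "pEMT.CTC": "#7570b3", "CEC": "#1b9e77"}


def cnv_heatmap(
    segment_sets: list[SegmentSet],
    clonality: pd.DataFrame | None = None,
    path=None,
    ax=None,
):
    """Cells x bins heatmap of called states, rows ordered by clonal group."""
    if not segment_sets:
        raise ValueError("no segment sets to plot")
    order = list(range(len(segment_sets)))
    if clonality is not None:
        groups = dict(zip(clonality["cell_id"], clonality["clonal_group"]))
        order.sort(
            key=lambda i: (groups.get(segment_sets[i].cell_id) or "~", segment_sets[i].cell_id)
        )
    mat = np.array(
        [
            [_STATE_CODE[s] for s in segment_sets[i].state_per_bin()]
            for i in order
        ]
    )
    if ax is None:
        _, ax = plt.subplots(figsize=(10, max(2, 0.25 * len(order))))
    ax.imshow(mat, aspect="auto", cmap=_CNV_CMAP, vmin=0, vmax=2, interpolation="nearest")
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels([segment_sets[i].cell_id for i in order], fontsize=6)
    ax.set_xlabel("genomic bin")
    ax.set_title("copy-number states (gain = red, loss = blue)")
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def composition_bars(longitudinal: pd.DataFrame, path=None, ax=None):
    """Stacked rare-cell composition per draw over time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    bottoms = np.zeros(len(longitudinal))
    x = longitudinal["timepoint_weeks"].to_numpy(float)
    for label in RARE_LABELS:
        frac = longitudinal[f"frac_{label}"].fillna(0).to_numpy(float)
        ax.bar(x, frac, width=2.5, bottom=bottoms, label=label, color=_LABEL_COLORS[label])
        bottoms += frac
    for xi, status in zip(x, longitudinal["disease_status"]):
        ax.annotate(status, (xi, 1.02), ha="center", fontsize=8)
    ax.set_xlabel("weeks")
    ax.set_ylabel("fraction of classified rare cells")
    ax.set_xticks(np.arange(0, max(x) + 4, 4))
    ax.legend(fontsize=7)
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def feature_violins(
    values_by_group: dict[str, np.ndarray], feature_name: str, path=None, ax=None
):
    """Violin + jitter view of one feature across cell groups."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    names = list(values_by_group)
    data = [np.asarray(values_by_group[g], dtype=float) for g in names]
    ax.violinplot(data, showmedians=True)
    rng = np.random.default_rng(0)
    for i, vals in enumerate(data, start=1):
        ax.plot(i + rng.uniform(-0.08, 0.08, len(vals)), vals, "k.", ms=3, alpha=0.5)
    ax.set_xticks(range(1, len(names) + 1))
    ax.set_xticklabels(names, fontsize=8)
    ax.set_ylabel(feature_name)
    if path:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
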