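"""Plotting helpers for fitted results: dendrogram, KM curves, ROC."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
from scipy.cluster.hierarchy import dendrogram as _dendrogram  # noqa: E402

SUBTYPE_COLORS = {"A": "#b2182b", "B": "#2166ac"}


def plot_dendrogram(linkage_matrix, labels=None, ax=None, **kwargs):
    """Dendrogram of the Ward tree (rows of a linkage matrix)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 4))
    _dendrogram(linkage_matrix, labels=labels, no_labels=labels is None,
                color_threshold=0, above_threshold_color="0.3", ax=ax,
                **kwargs)
    ax.set_ylabel("merge height")
    return ax


def plot_km(curves: dict, ax=None, horizon=None):
    """Step survival curves per subtype from a ``curves`` mapping
    (subtype -> KMCurve), as produced by the stratified analysis."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    for subtype, curve in curves.items():
        t = np.r_[0.0, curve.times]
        s = np.r_[1.0, curve.survival]
        ax.step(t, s, where="post", label=f"subtype {subtype}",
                color=SUBTYPE_COLORS.get(subtype))
    if horizon is not None:
        ax.axvline(horizon, ls=":", color="0.6")
    ax.set_xlabel("years")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def plot_roc(roc_results: dict, ax=None):
    """Overlay ROC curves from a mapping model-name -> ROCResult."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for name, res in roc_results.items():
        ax.plot(res.fpr, res.tpr, label=f"{name} (AUC {res.auc:.2f})")
    ax.plot([0, 1], [0, 1], ls="--", color="0.6")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend()
    return ax
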