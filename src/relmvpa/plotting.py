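"""Figure helpers: decoding timecourses, generalization heatmaps, RDMs, MDS."""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .rsa import RDM

__all__ = ["plot_timecourse", "plot_matrix", "plot_rdm", "plot_mds"]

_CATEGORY_COLORS = {1: "tab:blue", 2: "tab:orange", 3: "tab:green"}
_RELEVANCE_MARKERS = {"current": "o", "prospective": "^", "irrelevant": "s"}


def plot_timecourse(
    accuracies: Mapping[str, np.ndarray],
    chance: float = 1.0 / 3.0,
    sem: Optional[Mapping[str, np.ndarray]] = None,
    sig_mask: Optional[Mapping[str, np.ndarray]] = None,
    ax=None,
):
    """Per-TR accuracy lines per scheme with chance line, shaded within-subject
    SEM bands and uncorrected-significance markers."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for k, (label, acc) in enumerate(accuracies.items()):
        trs = np.arange(1, len(acc) + 1)
        (line,) = ax.plot(trs, acc, label=label)
        if sem and label in sem:
            ax.fill_between(trs, acc - sem[label], acc + sem[label],
                            alpha=0.25, color=line.get_color())
        if sig_mask and label in sig_mask:
            y = chance - 0.02 - 0.012 * k
            m = np.asarray(sig_mask[label], dtype=bool)
            ax.plot(trs[m], np.full(m.sum(), y), ".", color=line.get_color())
    ax.axhline(chance, color="k", ls="--", lw=0.8)
    ax.set_xlabel("TR")
    ax.set_ylabel("classification accuracy")
    ax.legend(frameon=False)
    return ax


def plot_matrix(matrix: np.ndarray, chance: float = 1.0 / 3.0,
                mask: Optional[np.ndarray] = None, ax=None):
    """Train-TR x test-TR accuracy heatmap, optionally outlining a cluster mask."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    m = np.asarray(matrix)
    lim = np.nanmax(np.abs(m - chance))
    im = ax.imshow(m, origin="lower", cmap="RdBu_r",
                   vmin=chance - lim, vmax=chance + lim)
    if mask is not None:
        ax.contour(np.asarray(mask, dtype=float), levels=[0.5], colors="k",
                   linewidths=1.0)
    ax.set_xlabel("test TR")
    ax.set_ylabel("train TR")
    plt.colorbar(im, ax=ax, label="accuracy")
    return ax


def plot_rdm(rdm: RDM, ax=None):
    """RDM heatmap with relevance/category block separators."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.imshow(rdm.d, cmap="RdBu_r")
    conds = [lab[0] for lab in rdm.labels]
    for i in range(1, rdm.side):
        if conds[i] != conds[i - 1]:
            ax.axhline(i - 0.5, color="k", lw=1.2)
            ax.axvline(i - 0.5, color="k", lw=1.2)
    ax.set_title(rdm.scope)
    plt.colorbar(im, ax=ax, label="dissimilarity")
    return ax


def plot_mds(coords: np.ndarray, labels: Sequence, ax=None):
    """2-D MDS scatter with category colours and relevance markers."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for (cond, cat, _ex), (x, y) in zip(labels, coords[:, :2]):
        ax.scatter(
            x, y,
            color=_CATEGORY_COLORS.get(cat, "gray"),
            marker=_RELEVANCE_MARKERS.get(cond, "x"),
            s=45, edgecolor="k", linewidth=0.4,
        )
    ax.set_xlabel("dimension 1")
    ax.set_ylabel("dimension 2")
    ax.set_aspect("equal")
    return ax
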