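"""Optional diagnostic plots (requires matplotlib, install extra ``plot``)."""

from __future__ import annotations

import numpy as np

from .classify import KfdaModel
from .selection import SelectionTrace

__all__ = ["plot_selection_curve", "plot_svm_scores", "plot_kfda_scores"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_selection_curve(trace: SelectionTrace, ax=None):
    """Mean pairwise LOOCV accuracy against the number of retained features."""
    ax = _axes(ax)
    counts = [n for n, _ in trace.criterion_curve]
    accs = [c for _, c in trace.criterion_curve]
    ax.plot(counts, accs, "o-")
    ax.set_xlabel("number of GLCM features")
    ax.set_ylabel("maximum average pairwise accuracy")
    ax.invert_xaxis()
    return ax


def plot_svm_scores(scores, labels, positive_label: str, ax=None):
    """Per-sample signed SVM decision values; sign = predicted group."""
    ax = _axes(ax)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    for lab, marker in zip(np.unique(labels), "ox^sv*"):
        mask = labels == lab
        ax.plot(np.flatnonzero(mask), scores[mask], marker, linestyle="", label=str(lab))
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("sample index")
    ax.set_ylabel(f"SVM score (+ = {positive_label})")
    ax.legend()
    return ax


def plot_kfda_scores(model: KfdaModel, ax=None):
    """3-D scatter of the first three discriminant scores per class."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    scores = model.train_scores
    if scores.shape[1] < 3:
        scores = np.pad(scores, ((0, 0), (0, 3 - scores.shape[1])))
    labels = np.asarray(model.train_labels)
    for lab in model.class_labels:
        mask = labels == lab
        ax.scatter(scores[mask, 0], scores[mask, 1], scores[mask, 2], label=str(lab))
    ax.set_xlabel("$s_1$")
    ax.set_ylabel("$s_2$")
    ax.set_zlabel("$s_3$")
    ax.legend()
    return ax
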