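"""Plotting helpers: feature scatter, synchronization matrix, detection timeline."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_feature_scatter", "plot_sync_matrix", "plot_detection_timeline"]


def _get_ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_feature_scatter(frame, ax=None):
    """Scatter windows in the (gamma-bar, normalized amplitude) plane."""
    ax = _get_ax(ax)
    ictal = frame["label"].to_numpy(dtype=bool)
    ax.scatter(
        frame.loc[~ictal, "gamma"], frame.loc[~ictal, "amp_norm"],
        s=4, alpha=0.3, label="interictal", color="tab:blue",
    )
    ax.scatter(
        frame.loc[ictal, "gamma"], frame.loc[ictal, "amp_norm"],
        s=6, alpha=0.6, label="ictal", color="tab:red",
    )
    ax.set_xlabel(r"global synchronization $\bar\gamma$")
    ax.set_ylabel("normalized amplitude $A_m(n)$")
    ax.legend(frameon=False)
    return ax


def plot_sync_matrix(matrix, ax=None):
    """Heatmap of a pairwise synchronization matrix."""
    ax = _get_ax(ax)
    im = ax.imshow(matrix.values, vmin=0, vmax=1, cmap="viridis")
    ticks = np.arange(len(matrix.labels))
    ax.set_xticks(ticks, matrix.labels, rotation=90, fontsize=7)
    ax.set_yticks(ticks, matrix.labels, fontsize=7)
    ax.figure.colorbar(im, ax=ax, label=r"$\gamma(k,l)$")
    return ax


def plot_detection_timeline(window_starts, decisions, seizure_intervals, ax=None):
    """Step plot of the detection function with annotated seizures shaded."""
    ax = _get_ax(ax)
    starts = np.asarray(window_starts, dtype=float)
    d = np.asarray(decisions, dtype=float)
    ax.step(starts, d, where="post", lw=1, color="k", label="detector")
    for a, b in seizure_intervals:
        ax.axvspan(a, b, color="tab:red", alpha=0.2)
    ax.set_ylim(-0.05, 1.2)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("ictal decision")
    return ax
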