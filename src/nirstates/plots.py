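"""Figure helpers: state connectivity matrices and transition heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dynamic_fc import StateResults


def plot_state_matrices(states: StateResults, path=None):
    """One correlation-matrix panel per connectivity state, low to high."""
    k = states.n_states
    fig, axes = plt.subplots(1, k, figsize=(3.2 * k, 3.2), squeeze=False)
    for i, ax in enumerate(axes[0]):
        M = states.state_matrix(i)
        im = ax.imshow(M, vmin=-1, vmax=1, cmap="RdBu_r")
        ax.set_title(f"{states.state_names[i]} (mean r={states.centroid_strength[i]:.2f})")
        ax.set_xticks(range(len(states.windows.node_labels)))
        ax.set_xticklabels(states.windows.node_labels, rotation=90, fontsize=7)
        ax.set_yticks(range(len(states.windows.node_labels)))
        ax.set_yticklabels(states.windows.node_labels, fontsize=7)
    fig.colorbar(im, ax=axes[0], shrink=0.8, label="Pearson r")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_transition_matrix(trans: np.ndarray, state_names, path=None):
    """Heatmap of the transition-percentage matrix; entry (x, y) is the
    percentage of transitions from state x to state y."""
    fig, ax = plt.subplots(figsize=(3.5, 3.2))
    im = ax.imshow(trans, cmap="viridis")
    for i in range(trans.shape[0]):
        for j in range(trans.shape[1]):
            ax.text(j, i, f"{trans[i, j]:.1f}", ha="center", va="center",
                    color="w", fontsize=8)
    ax.set_xticks(range(len(state_names)))
    ax.set_xticklabels(state_names)
    ax.set_yticks(range(len(state_names)))
    ax.set_yticklabels(state_names)
    ax.set_xlabel("to state")
    ax.set_ylabel("from state")
    fig.colorbar(im, ax=ax, label="% of transitions")
    if path:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
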