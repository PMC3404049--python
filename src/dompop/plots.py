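"""Plots: the deletion-trajectory bar chart."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .compat import DeletionTrajectory

__all__ = ["plot_trajectory"]


def plot_trajectory(traj: DeletionTrajectory, title: str = "", ax=None):
    """Bar chart of MIC against the number of genotypes deleted so far.

    A gradual, near-linear decline indicates that incompatibility is
    spread over many recombinant genotypes (sexual populations); a sharp
    early drop indicates a few recombinants on top of a tree-like,
    clonally derived genotype pool.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.bar(range(len(traj.mic_after)), traj.mic_after, color="0.35")
    ax.set_xlabel("genotypes deleted")
    ax.set_ylabel("matrix incompatibility count")
    if title:
        ax.set_title(title)
    ax.figure.tight_layout()
    return ax
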