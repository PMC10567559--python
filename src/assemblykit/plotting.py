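"""Minimal trajectory and exploration plots."""

from __future__ import annotations

import numpy as np


def plot_growth(traj, ax=None, levels=None, log=True):
    """Unique-object counts per assembly index over time (one line per a),
    plus A(t) on a twin axis when the trajectory carries it."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    levels = levels if levels is not None else traj.a_levels
    for ai, a in enumerate(traj.a_levels):
        if a not in levels or not np.any(traj.counts[:, ai] > 0):
            continue
        ax.plot(traj.t, traj.counts[:, ai], label=f"a={int(a)}", drawstyle="steps-post")
    if log:
        ax.set_yscale("log")
    ax.set_xlabel("time")
    ax.set_ylabel("unique objects $N_a$")
    ax.legend(fontsize="small")
    if traj.A is not None:
        ax2 = ax.twinx()
        ax2.plot(traj.t, traj.A, color="k", ls="--", label="A(t)")
        ax2.set_ylabel("assembly A")
    return ax


def plot_exploration(per_run, ax=None):
    """Exploration ratio vs maximum assembly index, one point per run,
    coloured by mode."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for mode, df in per_run.groupby("mode"):
        ax.scatter(df["exploration_ratio"], df["max_assembly_index"], label=mode, alpha=0.7)
    ax.set_xlabel("exploration ratio")
    ax.set_ylabel("max assembly index")
    ax.legend()
    return ax
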