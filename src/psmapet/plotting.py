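"""Plots for scenario sweeps and PSA outcome distributions."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_sweep", "plot_delta_distribution"]


def plot_sweep(scenario_frame, x: str, y: str = "d_life_years", ax=None):
    """Line plot of a one-way sweep (one line per strategy)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for strat, sub in scenario_frame.groupby("strategy"):
        if (sub[y] == 0).all():  # reference strategy
            continue
        ax.plot(sub[x], sub[y], marker="o", label=strat)
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xlabel(x)
    ax.set_ylabel(f"{y} per 1000 vs conventional imaging")
    ax.legend()
    return ax


def plot_delta_distribution(psa_results, outcome: str = "life_years", ax=None):
    """Histogram of per-iteration strategy-vs-conventional differences."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    draws = psa_results.draws
    ref = draws[draws["strategy"] == "ctbs"].set_index("iteration")[outcome]
    for strat in draws["strategy"].unique():
        if strat == "ctbs":
            continue
        sub = draws[draws["strategy"] == strat].set_index("iteration")[outcome]
        ax.hist(np.asarray(sub - ref), bins=50, alpha=0.5, label=strat)
    ax.set_xlabel(f"difference in {outcome} per 1000 vs conventional imaging")
    ax.set_ylabel("iterations")
    ax.legend()
    return ax
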