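"""Plotting helpers: LTT curves with detected shifts, diversity curves."""

from __future__ import annotations

import numpy as np

from .fossil import diversity_curve
from .tree import Chronogram, ltt

__all__ = ["plot_ltt", "plot_diversity_curve"]


def plot_ltt(trees, shift_ages=(), labels=None, ax=None, log_scale=True):
    """Lineage-through-time plot, age decreasing left to right.

    ``trees`` is a Chronogram or a sequence of them; ``shift_ages`` are
    drawn as vertical lines (detected rate shifts).
    """
    import matplotlib.pyplot as plt

    if isinstance(trees, Chronogram):
        trees = [trees]
    if ax is None:
        _, ax = plt.subplots()
    for i, tree in enumerate(trees):
        curve = ltt(tree)
        ages = np.repeat(curve.ages, 2)[1:]
        counts = np.repeat(curve.counts, 2)[:-1]
        label = labels[i] if labels else None
        ax.plot(ages, counts, drawstyle="default", label=label)
    for s in shift_ages:
        ax.axvline(s, color="0.4", linestyle="--", linewidth=0.8)
    if log_scale:
        ax.set_yscale("log")
    ax.invert_xaxis()
    ax.set_xlabel("age (Ma)")
    ax.set_ylabel("lineages")
    if labels:
        ax.legend()
    return ax


def plot_diversity_curve(ranges_by_group, old=66.0, step=1.0, marker_age=None,
                         ax=None):
    """Range-through standing diversity through time, per group.

    ``ranges_by_group`` maps a label to a list of fossil ranges (use
    {"total": ranges} for a single curve); ``marker_age`` draws a dashed
    line (e.g. at a faunal-turnover boundary).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, ranges in ranges_by_group.items():
        ages, counts = diversity_curve(ranges, old=old, step=step)
        ax.plot(ages, counts, label=label)
    if marker_age is not None:
        ax.axvline(marker_age, color="k", linestyle="--", linewidth=0.8)
    ax.invert_xaxis()
    ax.set_xlabel("age (Ma)")
    ax.set_ylabel("standing diversity (species)")
    ax.legend()
    return ax
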