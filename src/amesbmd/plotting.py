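"""Plot helpers: radar-style maximum fold changes, forest-style potency
rankings, fitted dose-response curves.

The numeric values are the contract (they come straight from the screening
and ranking modules); styling is deliberately plain.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["plot_max_fold_radar", "plot_ranking", "plot_fit"]


def plot_max_fold_radar(values: dict, thresholds=(2.0, 3.0), ax=None):
    """Polar plot of maximum fold change per category.

    ``values`` maps a label (e.g. ``"water/TA100"``) to its maximum
    treated/control ratio; dashed rings mark the 2- and 3-fold positivity
    thresholds.
    """
    import matplotlib.pyplot as plt

    labels = list(values)
    vals = [values[k] for k in labels]
    angles = np.linspace(0, 2 * math.pi, len(labels), endpoint=False)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.plot(
        np.append(angles, angles[0]), np.append(vals, vals[0]), marker="o"
    )
    for thr, style in zip(thresholds, ("--", ":")):
        ax.plot(
            np.linspace(0, 2 * math.pi, 100),
            [thr] * 100,
            style,
            color="red",
            linewidth=0.8,
        )
    ax.set_xticks(angles)
    ax.set_xticklabels(labels, fontsize=7)
    return ax


def plot_ranking(entries, ax=None):
    """Forest-style plot of ranked CED confidence intervals on a log axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.3 * max(len(list(entries)), 4) + 1))
    entries = sorted(entries, key=lambda e: e.rank or 0, reverse=True)
    for y, e in enumerate(entries):
        hi = e.cedu if math.isfinite(e.cedu) else e.ced * 100
        ax.plot([e.cedl, hi], [y, y], color="C0")
        marker = ">" if not math.isfinite(e.cedu) else "|"
        ax.plot([hi], [y], marker, color="C0")
        ax.plot([e.ced], [y], "o", color="C3", markersize=3)
    ax.set_yticks(range(len(entries)))
    ax.set_yticklabels(
        [f"#{e.rank} " + "/".join(e.design) for e in entries], fontsize=6
    )
    ax.set_xscale("log")
    ax.set_xlabel("CED (ug/plate), two-sided 90% CI")
    return ax


def plot_fit(results, spec=None, ax=None, n_points: int = 200):
    """Observed plate counts with the fitted mean curve(s), log-dose axis."""
    import matplotlib.pyplot as plt

    from . import family

    if ax is None:
        _, ax = plt.subplots()
    data = results.model.data
    positive = data.doses[data.doses > 0]
    lo, hi = positive.min(), positive.max()
    grid = np.geomspace(lo / 5, hi, n_points)
    for g in results.groups:
        mask = np.array([s == g for s in data.subgroup])
        ax.plot(
            np.where(data.doses[mask] > 0, data.doses[mask], lo / 10),
            data.responses[mask],
            "o",
            markersize=3,
            label=f"{g} plates",
        )
        if results.model_id != "m1":
            curve = family.mean_response(results.estimates[g].params, grid)
            ax.plot(grid, curve, label=f"{g} fit ({results.model_id})")
    ax.set_xscale("log")
    ax.set_xlabel("dose (ug/plate)")
    ax.set_ylabel("revertants/plate")
    ax.legend(fontsize=6)
    return ax
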