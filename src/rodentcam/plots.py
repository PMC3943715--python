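"""Optional figures for the report bundle.

CSV outputs are the primary artifacts; these helpers render the standard
summary figures from them when plotting is enabled.  matplotlib is
imported lazily so the numerical pipeline never needs a display stack.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def detection_curve_plot(curves: dict[str, pd.DataFrame], level: float = 0.95,
                         ax=None):
    """Cumulative detection probability by survey night, one line per
    species, with CI bands where available."""
    ax = _axes(ax)
    for i, (name, curve) in enumerate(curves.items()):
        style = ["-", "-."][i % 2]
        ax.plot(curve["night"], curve["P"], style, label=name)
        if {"P_lower", "P_upper"} <= set(curve.columns):
            ax.fill_between(
                curve["night"], curve["P_lower"], curve["P_upper"], alpha=0.2
            )
    ax.axhline(level, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("survey night")
    ax.set_ylabel("cumulative detection probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    return ax


def activity_histogram(activity: pd.DataFrame, species: str, ax=None,
                       bins=None):
    """Number of sites by activity-index value (events per night) for one
    species; sites never recording the species are excluded."""
    ax = _axes(ax)
    vals = activity.loc[
        (activity["species"] == species) & (activity["index"] > 0), "index"
    ]
    if bins is None:
        bins = np.arange(0, np.ceil(vals.max() if len(vals) else 1) + 1)
    ax.hist(vals, bins=bins, edgecolor="black")
    ax.set_xlabel("activity index (events per night)")
    ax.set_ylabel("number of sites")
    ax.set_title(species)
    return ax


def coefficient_plot(averaged: dict[str, pd.DataFrame], ax=None):
    """Model-averaged coefficients (point and 95% CI) per species."""
    ax = _axes(ax)
    markers = ["s", "^", "o", "v"]
    terms = sorted({t for df in averaged.values() for t in df["term"]})
    pos = {t: i for i, t in enumerate(terms)}
    for i, (name, df) in enumerate(averaged.items()):
        x = np.array([pos[t] for t in df["term"]], dtype=float) + 0.12 * i
        ax.errorbar(
            x, df["estimate"],
            yerr=[df["estimate"] - df["lower"], df["upper"] - df["estimate"]],
            fmt=markers[i % len(markers)], capsize=3, label=name, ls="none",
        )
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.set_xticks(range(len(terms)))
    ax.set_xticklabels(terms, rotation=45, ha="right")
    ax.set_ylabel("model-averaged coefficient")
    ax.legend()
    return ax
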