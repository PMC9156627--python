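"""Optional forest-plot rendering (matplotlib).

Two-series layout: filled blue markers for the non-topological subset, open
grey markers for all data, with 95% bootstrap CI whiskers.  Odds-ratio plots
use a log axis with a reference line at OR = 1.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")  # headless by default; callers may switch backends first
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["forest_plot", "or_plot"]

_SERIES_STYLE = {
    "non_topological": dict(color="tab:blue", marker="o", fillstyle="full", label="non-topological"),
    "all_data": dict(color="grey", marker="o", fillstyle="none", label="all data"),
}


def forest_plot(forest: pd.DataFrame, semiology: str, ax=None):
    """Point estimates with CI whiskers for one semiology across regions."""
    sub = forest[forest.semiology == semiology]
    if sub.empty:
        raise KeyError(f"semiology {semiology!r} not in forest table")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    regions = list(dict.fromkeys(sub.region))
    y = np.arange(len(regions))[::-1]
    for offset, (label, style) in zip((-0.12, 0.12), _SERIES_STYLE.items()):
        series = sub[sub.subset_label == label].set_index("region")
        if series.empty:
            continue
        p = series.reindex(regions).p_hat.to_numpy(dtype=float)
        lo = series.reindex(regions).ci_low.to_numpy(dtype=float)
        hi = series.reindex(regions).ci_high.to_numpy(dtype=float)
        ax.errorbar(
            p, y + offset,
            xerr=[p - lo, hi - p],
            linestyle="none", capsize=2, **style,
        )
    ax.set_yticks(y)
    ax.set_yticklabels(regions)
    ax.set_xlabel("p(region | semiology)")
    ax.set_xlim(0, 1)
    ax.set_title(semiology)
    ax.legend(loc="lower right", fontsize=8)
    return ax


def or_plot(ors: pd.DataFrame, semiology: str, ax=None):
    """Odds ratios with CI whiskers on a log scale, reference line at 1."""
    sub = ors[ors.semiology == semiology]
    if sub.empty:
        raise KeyError(f"semiology {semiology!r} not in OR table")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    regions = list(dict.fromkeys(sub.region))
    y = np.arange(len(regions))[::-1]
    for offset, (label, style) in zip((-0.12, 0.12), _SERIES_STYLE.items()):
        series = sub[sub.subset_label == label].set_index("region")
        if series.empty:
            continue
        o = series.reindex(regions).odds_ratio.to_numpy(dtype=float)
        lo = series.reindex(regions).ci_low.to_numpy(dtype=float)
        hi = series.reindex(regions).ci_high.to_numpy(dtype=float)
        ax.errorbar(
            o, y + offset,
            xerr=[o - lo, hi - o],
            linestyle="none", capsize=2, **style,
        )
    ax.axvline(1.0, color="k", linewidth=0.8)
    ax.set_xscale("log")
    ax.set_yticks(y)
    ax.set_yticklabels(regions)
    ax.set_xlabel("odds ratio (log scale)")
    ax.set_title(semiology)
    ax.legend(loc="lower right", fontsize=8)
    return ax
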