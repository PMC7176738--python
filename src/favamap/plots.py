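"""Plotting conveniences: distortion profiles and map collinearity dot plots.

These are thin matplotlib wrappers around the QC report and
:func:`favamap.consensus.compare_maps` output; they return the Axes so
callers can restyle or save them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_distortion_profile(
    qc_report: pd.DataFrame,
    gmap=None,
    p_threshold: float = 0.05,
    ax=None,
):
    """Per-marker -log10 chi-square p along the map (or in marker order).

    ``qc_report`` is the table from :func:`favamap.markerqc.filter_markers`;
    when a :class:`~favamap.io.GeneticMap` is given, markers are placed at
    their map positions per group, otherwise in input order.  The dashed line
    marks the significance threshold.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    report = qc_report.dropna(subset=["chi2_p"]).copy()
    report["neglog_p"] = -np.log10(np.maximum(report["chi2_p"], 1e-300))
    if gmap is not None:
        pos = gmap.positions()
        group_of = dict(zip(gmap.table["marker_id"], gmap.table["group"]))
        report = report[report["marker_id"].isin(pos.index)]
        offset = 0.0
        ticks, labels = [], []
        for group in gmap.groups:
            sub = report[[group_of[m] == group for m in report["marker_id"]]]
            x = pos[sub["marker_id"]].to_numpy() + offset
            ax.plot(x, sub["neglog_p"], ".", ms=3)
            span = float(pos[[m for m, g in group_of.items() if g == group]].max())
            ticks.append(offset + span / 2)
            labels.append(group)
            offset += span + 10.0
        ax.set_xticks(ticks, labels)
        ax.set_xlabel("map position")
    else:
        ax.plot(report["neglog_p"].to_numpy(), ".", ms=3)
        ax.set_xlabel("marker index")
    ax.axhline(-np.log10(p_threshold), ls="--", c="red", lw=1)
    ax.set_ylabel(r"$-\log_{10} p$ ($\chi^2$)")
    return ax


def plot_map_dotplot(dotplot: pd.DataFrame, ax=None, label_a="map A", label_b="map B"):
    """Collinearity dot plot from :func:`favamap.consensus.compare_maps` data.

    Normalized positions of shared markers, one colour per group; collinear
    maps fall on the diagonal.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    for group, sub in dotplot.groupby("group"):
        ax.plot(sub["norm_pos_a"], sub["norm_pos_b"], ".", ms=4, label=str(group))
    ax.set_xlabel(f"{label_a} (normalized position)")
    ax.set_ylabel(f"{label_b} (normalized position)")
    ax.legend(fontsize="small", loc="best")
    return ax
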