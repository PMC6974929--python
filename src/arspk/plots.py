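"""Optional rendered figures for the diagnostics and exposure outputs.

Each function returns a matplotlib Figure built from the tidy result
objects; nothing here recomputes statistics.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .diagnostics import VpcResult  # noqa: E402
from .simulate import ExposureComparison  # noqa: E402

_ANALYTE_LABEL = {"ars": "artesunate", "dha": "dihydroartemisinin"}


def plot_vpc(vpc: VpcResult):
    """Prediction-corrected VPC panels (percentiles above, BLQ fraction
    below) for each analyte."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 6), sharex=True)
    for j, analyte in enumerate(("ars", "dha")):
        ax = axes[0, j]
        s = vpc.stats[vpc.stats["analyte"] == analyte]
        for q, style in ((5, ":"), (50, "-"), (95, ":")):
            sq = s[s["percentile"] == q].sort_values("bin")
            ax.fill_between(sq["bin"], sq["sim_lo"], sq["sim_hi"], alpha=0.25)
            ax.plot(sq["bin"], sq["observed"], style, color="k")
        ax.set_yscale("log")
        ax.set_title(_ANALYTE_LABEL[analyte])
        ax.set_ylabel("pred.-corrected conc. (ng/mL)")
        bx = axes[1, j]
        b = vpc.blq[vpc.blq["analyte"] == analyte].sort_values("bin")
        bx.fill_between(b["bin"], b["sim_lo"], b["sim_hi"], alpha=0.25)
        bx.plot(b["bin"], b["observed"], "-", color="k")
        bx.set_ylim(0, 1)
        bx.set_xlabel("time after dose (h)")
        bx.set_ylabel("fraction below LLOQ")
    fig.tight_layout()
    return fig


def plot_gof(tab):
    """Observed vs predicted and conditional weighted residuals."""
    fig, axes = plt.subplots(2, 2, figsize=(9, 6))
    for ax, pred in ((axes[0, 0], "PRED_LOG"), (axes[0, 1], "IPRED_LOG")):
        ax.plot(tab[pred], tab["DV"], "o", ms=3, alpha=0.5)
        lims = [min(tab[pred].min(), tab["DV"].min()),
                max(tab[pred].max(), tab["DV"].max())]
        ax.plot(lims, lims, "k-", lw=1)
        ax.set_xlabel(f"{'population' if pred == 'PRED_LOG' else 'individual'}"
                      " prediction (log ng/mL)")
        ax.set_ylabel("observed (log ng/mL)")
    for ax, x, lab in ((axes[1, 0], "PRED_LOG", "population prediction"),
                       (axes[1, 1], "TIME", "time after dose (h)")):
        ax.plot(tab[x], tab["CWRES"], "o", ms=3, alpha=0.5)
        ax.axhline(0, color="k", lw=1)
        ax.set_xlabel(lab)
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    return fig


def _box_from_percentiles(ax, rows, labels, band=(0.8, 1.2)):
    for i, row in enumerate(rows):
        p10, p25, p50, p75, p90 = row
        ax.plot([p10, p90], [i, i], "k-", lw=1)
        ax.add_patch(plt.Rectangle((p25, i - 0.2), p75 - p25, 0.4,
                                   facecolor="lightsteelblue",
                                   edgecolor="k"))
        ax.plot([p50, p50], [i - 0.2, i + 0.2], "k-", lw=1.5)
    ax.axvline(1.0, color="k", lw=1)
    for edge in band:
        ax.axvline(edge, color="k", lw=1, ls="--")
    ax.set_yticks(range(len(labels)))
    ax.set_yticklabels(labels)


def plot_exposure(comp: ExposureComparison):
    """Relative pregnancy impact on AUC and CMAX per analyte, as box plots
    (boxes 25th-75th, whiskers 10th-90th percentile), with the +-20%
    clinical-relevance band."""
    fig, ax = plt.subplots(figsize=(7, 4))
    pct = comp.percentiles.loc["pregnant"]
    labels = []
    rows = []
    for analyte in ("ars", "dha"):
        for metric in ("auc", "cmax"):
            labels.append(f"{_ANALYTE_LABEL[analyte]} {metric.upper()}")
            rows.append(pct.loc[(analyte, metric)].to_numpy())
    _box_from_percentiles(ax, rows, labels, comp.reference_band)
    ax.set_xlabel("exposure relative to the non-pregnant group mean")
    fig.tight_layout()
    return fig


def plot_covariate_effects(percentiles, band=(0.8, 1.2)):
    """Full-covariate-model box plot: bootstrap distribution of the relative
    pregnancy effect (1 + theta) on each structural parameter."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    labels = list(percentiles.columns)
    rows = [percentiles[c].to_numpy() for c in labels]
    _box_from_percentiles(ax, rows, labels, band)
    ax.set_xlabel("relative pregnancy effect")
    fig.tight_layout()
    return fig
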