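"""Standard figures for a pipeline run (matplotlib, Agg-safe).

Four figure families: per-locus curve fits over the raw two-color
threshold points; outcomes versus age with the normative median and 95%
prediction band; covariate-adjusted ROC curves per marker and
eccentricity; and pairwise deviation scatters (RIT delay versus FT/CT
deviation)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .model import evaluate_curve
from .normative import predict_interval

__all__ = [
    "plot_locus_fit",
    "plot_outcomes_vs_age",
    "plot_aroc_curves",
    "plot_deviation_pairs",
]


def plot_locus_fit(points, params, ax=None, title=""):
    """Raw cyan/red threshold points with the fitted biphasic curve."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    for color, c in (("cyan505", "tab:blue"), ("red627", "tab:red")):
        sub = points[points["color"] == color]
        ax.plot(sub["t_min"], sub["threshold"], ".", color=c, ms=4, label=color)
    tt = np.linspace(0.01, max(points["t_min"].max(), 1.0), 400)
    ax.plot(tt, evaluate_curve(params, tt), "-", color="deepskyblue", lw=1.5)
    ax.axvline(params.CRB, ls="--", color="gray", lw=0.8)
    ax.set_xlabel("time after bleach (min)")
    ax.set_ylabel("threshold (logUnits)")
    ax.set_title(title, fontsize=9)
    ax.invert_yaxis()
    return ax


def plot_outcomes_vs_age(outcomes, models, path: str | Path):
    """Outcome vs. age per eccentricity with normative 95% prediction bands."""
    eccs = sorted(outcomes["eccentricity_deg"].unique())
    names = [n for n in ("CT", "FT", "RIT") if n in models]
    fig, axes = plt.subplots(
        len(names), len(eccs), figsize=(3.2 * len(eccs), 2.6 * len(names)), squeeze=False
    )
    ages = np.linspace(outcomes["age"].min(), outcomes["age"].max(), 50)
    for i, name in enumerate(names):
        for j, ecc in enumerate(eccs):
            ax = axes[i][j]
            sub = outcomes[outcomes["eccentricity_deg"] == ecc]
            for grp, marker, c in (("healthy", "o", "gray"), ("AMD", "^", "tab:orange")):
                g = sub[sub["group"] == grp]
                ax.plot(g["age"], g[name], marker, color=c, ms=4, ls="", label=grp)
            band = np.array([predict_interval(models[name], a, ecc) for a in ages])
            ax.plot(ages, band[:, 1], "-", color="k", lw=1)
            ax.plot(ages, band[:, 0], "--", color="k", lw=0.8)
            ax.plot(ages, band[:, 2], "--", color="k", lw=0.8)
            ax.set_title(f"{name} at {ecc:g} deg", fontsize=9)
            if i == len(names) - 1:
                ax.set_xlabel("age (y)")
    axes[0][0].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_aroc_curves(aroc_results, path: str | Path):
    """Covariate-adjusted ROC curves, one panel per marker x eccentricity."""
    markers = sorted({r.marker_name for r in aroc_results})
    eccs = sorted({r.eccentricity_deg for r in aroc_results})
    fig, axes = plt.subplots(
        len(markers), len(eccs), figsize=(2.8 * len(eccs), 2.8 * len(markers)), squeeze=False
    )
    for r in aroc_results:
        i = markers.index(r.marker_name)
        j = eccs.index(r.eccentricity_deg)
        ax = axes[i][j]
        ax.plot(r.fpf_grid, r.tpf, "-", color="tab:blue")
        ax.plot([0, 1], [0, 1], ":", color="gray", lw=0.8)
        ax.set_title(
            f"{r.marker_name} {r.eccentricity_deg:g} deg  AAUC={r.aauc:.2f}",
            fontsize=8,
        )
        ax.set_xlabel("FPF")
        ax.set_ylabel("TPF")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_deviation_pairs(deviations, path: str | Path):
    """RIT delay vs FT deviation, RIT delay vs CT deviation, FT vs CT."""
    wide = deviations.pivot_table(
        index=["subject_id", "eccentricity_deg", "group"],
        columns="outcome_name",
        values="deviation",
    ).reset_index()
    pairs = [("RIT", "FT"), ("RIT", "CT"), ("FT", "CT")]
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
    for ax, (x, y) in zip(axes, pairs):
        if x not in wide.columns or y not in wide.columns:
            continue
        for grp, marker, c in (("healthy", "o", "gray"), ("AMD", "^", "tab:orange")):
            g = wide[wide["group"] == grp]
            ax.plot(g[x], g[y], marker, color=c, ms=4, ls="")
        ax.set_xlabel(f"{x} {'delay (min)' if x == 'RIT' else 'deviation (logUnits)'}")
        ax.set_ylabel(f"{y} deviation (logUnits)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
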