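"""Diagnostic plots: extended p-CI plots, curve overlays and polygonograms.

Plots are secondary outputs; every plotted quantity is also written as CSV by
the pipeline so downstream analysis never depends on rendered figures.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .interaction import CI_ANTAGONISM_THRESHOLD, CI_SYNERGISM_THRESHOLD, CIResult
from .mixture import PredictedCurve
from .models import BiphasicModel, DoseResponseDataset, evaluate

__all__ = ["plot_extended_ci", "plot_curve_overlay", "plot_polygonogram"]

_CATEGORY_STYLE = {
    "additive": {"color": "0.45", "linestyle": "-"},
    "synergism": {"color": "tab:green", "linestyle": "-"},
    "antagonism": {"color": "tab:red", "linestyle": "--"},
    "absent": {"color": "0.85", "linestyle": ":"},
}


def plot_extended_ci(results: Sequence[CIResult], path: str | Path, title: str = "") -> None:
    """Extended p-CI plot: CI_D, CI_E and CI_w against fractional effect p,
    with the additivity line CI = 1 and the 0.5-2 management band."""
    p = np.array([r.p for r in results])
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.axhspan(CI_SYNERGISM_THRESHOLD, CI_ANTAGONISM_THRESHOLD, color="0.92", zorder=0, label="management band")
    ax.axhline(1.0, color="k", lw=0.8, label="additivity (CI = 1)")
    ax.plot(p, [r.ci_d for r in results], label=r"CI$_D$", color="tab:blue")
    ax.plot(p, [r.ci_e for r in results], label=r"CI$_E$", color="tab:orange")
    ax.plot(p, [r.ci_w for r in results], label=r"CI$_w$", color="tab:purple", lw=2)
    ax.set_yscale("log")
    ax.set_xlabel("fractional effect p")
    ax.set_ylabel("combination index")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_curve_overlay(
    predicted: PredictedCurve,
    path: str | Path,
    *,
    observed: DoseResponseDataset | None = None,
    mixture_model: BiphasicModel | None = None,
    title: str = "",
) -> None:
    """Predicted additive curve vs observed mixture data (and its fit)."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(predicted.dose, predicted.effect, label="additive prediction", color="tab:blue")
    if mixture_model is not None:
        ax.plot(predicted.dose, evaluate(mixture_model, predicted.dose), label="mixture fit", color="tab:red")
    if observed is not None:
        ax.scatter(observed.dose, observed.response, s=12, color="0.3", alpha=0.6, label="observed")
    ax.set_xscale("log")
    ax.set_xlabel("total dose")
    ax.set_ylabel("response (induction factor)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_polygonogram(summary: pd.DataFrame, path: str | Path) -> None:
    """Polygonogram: components on a circle, one panel per p level, edges
    styled by interaction category (CI_w-based)."""
    p_levels = sorted(summary["p"].unique())
    names = sorted(set(summary["component_a"]) | set(summary["component_b"]))
    angle = {n: 2 * np.pi * i / len(names) for i, n in enumerate(names)}
    pos = {n: (np.cos(a), np.sin(a)) for n, a in angle.items()}

    fig, axes = plt.subplots(1, len(p_levels), figsize=(4 * len(p_levels), 4))
    axes = np.atleast_1d(axes)
    for ax, p in zip(axes, p_levels):
        sub = summary[summary["p"] == p]
        for _, row in sub.iterrows():
            a, b = row["component_a"], row["component_b"]
            style = _CATEGORY_STYLE.get(row["category"], _CATEGORY_STYLE["absent"])
            (x1, y1), (x2, y2) = pos[a], pos[b]
            ax.plot([x1, x2], [y1, y2], lw=2, **style)
        for n, (x, y) in pos.items():
            ax.scatter([x], [y], s=300, color="white", edgecolor="k", zorder=3)
            ax.text(x, y, n, ha="center", va="center", fontsize=8, zorder=4)
        ax.set_title(f"p = {p:g}")
        ax.set_aspect("equal")
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
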