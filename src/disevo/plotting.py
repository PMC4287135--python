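"""Optional matplotlib renderings of the pipeline's tables (CLI ``--plot``)."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd


def _axes():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_chcdf(table: pd.DataFrame, path) -> None:
    """CH-CDF scatter (dCDF on x, dCH on y) with quadrant axes."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(5, 5))
    for grp, sub in table.groupby(table["group"].where(table["group"] != "", "all")):
        ax.scatter(sub["dCDF"], sub["dCH"], s=18, label=str(grp))
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("CDF distance (dCDF)")
    ax.set_ylabel("CH distance (dCH)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_rates(table: pd.DataFrame, path) -> None:
    """Grouped bars: substitution rate per domain, one group of bars per pair."""
    plt = _axes()
    sub = table[~table["missing"]]
    domains = list(dict.fromkeys(sub["domain"]))
    pairs = list(dict.fromkeys(zip(sub["group1"], sub["group2"])))
    width = 0.8 / max(len(pairs), 1)
    fig, ax = plt.subplots(figsize=(1.2 + 0.8 * len(domains), 4))
    x = np.arange(len(domains))
    for k, (g1, g2) in enumerate(pairs):
        rates = [
            sub[(sub["domain"] == d) & (sub["group1"] == g1) & (sub["group2"] == g2)][
                "rate"
            ].mean()
            for d in domains
        ]
        ax.bar(x + k * width, rates, width=width, label=f"{g1} vs {g2}")
    ax.set_xticks(x + width * (len(pairs) - 1) / 2)
    ax.set_xticklabels(domains, rotation=45, ha="right")
    ax.set_ylabel("substitution rate")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_gapped(curves: Sequence, path) -> None:
    """Stacked gapped disorder curves with horizontal bars at gap segments."""
    plt = _axes()
    fig, axes = plt.subplots(len(curves), 1, sharex=True, figsize=(8, 1.8 * len(curves)))
    if len(curves) == 1:
        axes = [axes]
    for ax, curve in zip(axes, curves):
        ax.plot(curve.values, lw=0.8, color="k")
        for start, end in curve.gap_segments:
            ax.plot([start, end], [0.5, 0.5], color="magenta", lw=3)
        ax.axhline(0.5, color="gray", lw=0.5, ls="--")
        ax.set_ylim(-0.05, 1.05)
        ax.set_ylabel(curve.protein_id, fontsize=7)
    axes[-1].set_xlabel("alignment column")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_cgn(table: pd.DataFrame, path) -> None:
    """Per-species CGN bar chart with the 0.5 conservation guide line."""
    plt = _axes()
    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * len(table), 3.5))
    ax.bar(table["species"], table["score"], color="gray")
    ax.axhline(0.5, color="k", lw=0.8, ls="--")
    ax.set_ylabel("CGN score")
    ax.set_ylim(0, 1)
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
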