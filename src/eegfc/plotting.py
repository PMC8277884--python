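"""Figures over the tabular pipeline outputs.

All plots are pure functions of the result tables/matrices -- nothing is
recomputed here.  Line plots apply the display cutoffs (coherence < 0.5
and PLI < 0.05 hidden) that keep dense all-to-all graphs readable; they
are display conventions only and never touch the analysis matrices.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix
from .montage import standard_montage

#: Edges weaker than this are hidden in line plots, per estimator.
DISPLAY_CUTOFF = {"coherence": 0.5, "pli": 0.05}


def _save(fig, path: Path, formats=("svg", "png")) -> list[Path]:
    path.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for ext in formats:
        p = path.with_suffix(f".{ext}")
        fig.savefig(p, bbox_inches="tight", dpi=150)
        written.append(p)
    plt.close(fig)
    return written


def plot_adjacency_heatmap(m: ConnectivityMatrix, path: str | Path) -> list[Path]:
    """Channel x channel heatmap of one connectivity matrix."""
    labels = list(m.channel_labels) or [str(i) for i in range(m.n_channels)]
    fig, ax = plt.subplots(figsize=(5.2, 4.6))
    im = ax.imshow(m.values, vmin=0, vmax=max(1e-9, m.values.max()), cmap="viridis")
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(labels)), labels, fontsize=6)
    ax.set_title(f"{m.method} {m.band.name} ({m.condition})", fontsize=10)
    fig.colorbar(im, ax=ax, shrink=0.8)
    return _save(fig, Path(path))


def plot_montage_lines(
    m: ConnectivityMatrix,
    path: str | Path,
    cutoff: float | None = None,
    highlight_edges: pd.DataFrame | None = None,
) -> list[Path]:
    """Head-circle layout with connectivity lines above the display cutoff;
    optional overlay (e.g. top-10 increased edges) drawn in red."""
    montage = standard_montage()
    pos = montage.position_array()
    if cutoff is None:
        cutoff = DISPLAY_CUTOFF.get(m.method, 0.0)
    fig, ax = plt.subplots(figsize=(4.6, 4.6))
    circle = plt.Circle((0, 0), 1.15, fill=False, lw=1.2, color="k")
    ax.add_patch(circle)
    ax.plot([0, -0.12, 0.12, 0], [1.15, 1.02, 1.02, 1.15], color="k", lw=1.2)  # nose
    vmax = max(m.values.max(), 1e-9)
    for i in range(m.n_channels):
        for j in range(i + 1, m.n_channels):
            w = m.values[i, j]
            if w < cutoff:
                continue
            ax.plot(
                pos[[i, j], 0], pos[[i, j], 1],
                color=plt.cm.viridis(w / vmax), lw=0.6 + 2.0 * w / vmax, alpha=0.75,
            )
    if highlight_edges is not None:
        for _, row in highlight_edges.iterrows():
            i, j = montage.index(row["chan_i"]), montage.index(row["chan_j"])
            ax.plot(pos[[i, j], 0], pos[[i, j], 1], color="crimson", lw=1.8)
    ax.scatter(pos[:, 0], pos[:, 1], s=90, c="white", edgecolors="k", zorder=3)
    for lab, (x, y) in zip(montage.channel_labels, pos):
        ax.annotate(lab, (x, y), ha="center", va="center", fontsize=5.5, zorder=4)
    ax.set_xlim(-1.35, 1.35)
    ax.set_ylim(-1.35, 1.35)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"{m.method} {m.band.name} ({m.condition})", fontsize=10)
    return _save(fig, Path(path))


def plot_relative_ratio(comparisons: pd.DataFrame, path: str | Path) -> list[Path]:
    """Post/pre ratio of each global measure per band, baseline drawn at 1.0;
    significant rows (q < 0.05) marked with an asterisk."""
    df = comparisons.copy()
    df["ratio"] = df["mean_post"] / df["mean_pre"]
    measures = sorted(df["measure"].unique())
    bands = [b for b in ("delta", "theta", "alpha", "beta", "gamma")
             if b in set(df["band"])]
    n = len(measures)
    fig, axes = plt.subplots(1, n, figsize=(2.1 * n, 3.2), sharey=False, squeeze=False)
    for ax, measure in zip(axes[0], measures):
        sub = df[df["measure"] == measure].set_index("band").reindex(bands)
        ax.bar(range(len(bands)), sub["ratio"], color="steelblue")
        ax.axhline(1.0, color="k", lw=1)
        for x, (band, row) in enumerate(sub.iterrows()):
            if np.isfinite(row.get("q_fdr", np.nan)) and row["q_fdr"] < 0.05:
                ax.annotate("*", (x, row["ratio"]), ha="center", fontsize=12)
        ax.set_xticks(range(len(bands)), bands, rotation=60, fontsize=7)
        ax.set_title(measure, fontsize=8)
    fig.suptitle("post/pre ratio of global graph measures (baseline = 1.0)")
    return _save(fig, Path(path))


def plot_nodal_changes(
    measures: pd.DataFrame, measure: str, band: str, method: str, path: str | Path
) -> list[Path]:
    """Montage map of mean nodal post-pre change; marker size = |change|."""
    montage = standard_montage()
    pos = montage.position_array()
    sub = measures[
        (measures["node"] != "global")
        & (measures["measure"] == measure)
        & (measures["band"] == band)
        & (measures["method"] == method)
    ]
    wide = sub.pivot_table(index="node", columns="condition", values="value")
    change = (wide["post"] - wide["pre"]).reindex([str(i) for i in range(19)]).to_numpy()
    fig, ax = plt.subplots(figsize=(4.6, 4.6))
    ax.add_patch(plt.Circle((0, 0), 1.15, fill=False, lw=1.2, color="k"))
    size = 60 + 900 * np.abs(change) / max(np.abs(change).max(), 1e-12)
    sc = ax.scatter(
        pos[:, 0], pos[:, 1], s=size, c=change, cmap="coolwarm",
        vmin=-np.abs(change).max(), vmax=np.abs(change).max(),
        edgecolors="k", zorder=3,
    )
    for lab, (x, y) in zip(montage.channel_labels, pos):
        ax.annotate(lab, (x, y), ha="center", va="center", fontsize=5.5, zorder=4)
    fig.colorbar(sc, ax=ax, shrink=0.75, label="post - pre")
    ax.set_xlim(-1.35, 1.35)
    ax.set_ylim(-1.35, 1.35)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(f"nodal {measure}, {method} {band}", fontsize=10)
    return _save(fig, Path(path))


def plot_correlation_bars(correlations: pd.DataFrame, path: str | Path) -> list[Path]:
    """Horizontal bars of Pearson r per (measure, band); p < 0.05 starred."""
    df = correlations.sort_values("r").reset_index(drop=True)
    labels = [f"{r.measure} ({r.band})" for r in df.itertuples()]
    fig, ax = plt.subplots(figsize=(5.2, 0.28 * max(len(df), 4) + 1.2))
    colors = plt.cm.RdYlBu_r(df["p"].clip(0, 0.2) / 0.2)
    ax.barh(range(len(df)), df["r"], color=colors)
    for y, row in df.iterrows():
        if row["p"] < 0.05:
            ax.annotate(
                "*", (row["r"], y), va="center",
                ha="left" if row["r"] >= 0 else "right", fontsize=12,
            )
    ax.set_yticks(range(len(df)), labels, fontsize=7)
    ax.axvline(0, color="k", lw=1)
    ax.set_xlabel("Pearson r (change vs. score improvement)")
    return _save(fig, Path(path))


def render_outputs(result, outdir: str | Path) -> list[Path]:
    """All standard figures for a pipeline result bundle."""
    outdir = Path(outdir)
    written: list[Path] = []
    for (method, band, cond), m in result.means.items():
        written += plot_adjacency_heatmap(
            m, outdir / f"heatmap_{method}_{band}_{cond}"
        )
        top = result.top_edges
        overlay = None
        if cond == "post" and len(top):
            overlay = top[(top["method"] == method) & (top["band"] == band)]
        written += plot_montage_lines(
            m, outdir / f"lines_{method}_{band}_{cond}", highlight_edges=overlay
        )
    if len(result.comparisons):
        for method, sub in result.comparisons.groupby("method"):
            written += plot_relative_ratio(sub, outdir / f"ratio_{method}")
    if len(result.correlations):
        for method, sub in result.correlations.groupby("method"):
            written += plot_correlation_bars(sub, outdir / f"correlation_{method}")
    return written
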