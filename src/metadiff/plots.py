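"""Headless publication figures for comparative abundance analysis.

Every function writes exactly one file at the requested path and returns
that path; no window is ever opened (the Agg backend is forced on import).
Vector output (SVG/PDF) is rendered deterministically — fixed hash salt, no
embedded timestamps — so identical calls produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import numpy as np
import pandas as pd
from matplotlib import pyplot as plt
from matplotlib.collections import LineCollection

from .abundance import AbundanceTable, mean_relative_abundance
from .errors import EmptyResultError, UsageError
from .metadata import SampleGroups
from .multivariate import ClusteringResult, OrdinationResult

__all__ = [
    "FigureSpec",
    "plot_comparison_bars",
    "plot_comparison_boxes",
    "plot_pie",
    "plot_area_profiles",
    "plot_pca_scores",
    "plot_heatmap",
]

matplotlib.rcParams["svg.hashsalt"] = "metadiff"

_FORMATS = ("png", "svg", "pdf")
_GROUP_COLORS = ("#4c72b0", "#dd8452")


@dataclass
class FigureSpec:
    """Where and how a figure is written."""

    out_path: str
    format: str | None = None  # inferred from the suffix when None
    dpi: int = 300
    color_map: str = "viridis"
    title: str | None = None
    figsize: tuple[float, float] | None = None
    extra: dict = field(default_factory=dict)

    def resolved_format(self) -> str:
        fmt = self.format or Path(self.out_path).suffix.lstrip(".").lower()
        if fmt not in _FORMATS:
            raise UsageError(f"format must be one of {_FORMATS}, got {fmt!r}")
        return fmt

    def __post_init__(self):
        if self.dpi < 72:
            raise UsageError(f"dpi must be >= 72, got {self.dpi}")
        self.resolved_format()


def _save(fig, spec: FigureSpec) -> str:
    fmt = spec.resolved_format()
    path = Path(spec.out_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    metadata = None
    if fmt == "svg":
        metadata = {"Date": None}
    elif fmt == "pdf":
        metadata = {"CreationDate": None}
    fig.savefig(path, format=fmt, dpi=spec.dpi, metadata=metadata)
    plt.close(fig)
    return str(path)


def _group_stats(table: AbundanceTable, samples, features) -> tuple[np.ndarray, np.ndarray]:
    sub = table.data.loc[features, list(samples)].to_numpy()
    mean = sub.mean(axis=1)
    se = sub.std(axis=1, ddof=1) / np.sqrt(sub.shape[1]) if sub.shape[1] > 1 else np.zeros(len(features))
    return mean, se


def plot_comparison_bars(
    results: pd.DataFrame,
    table: AbundanceTable,
    groups: SampleGroups,
    spec: FigureSpec,
    max_features: int = 30,
) -> str:
    """Paired horizontal bars of group mean relative abundance per feature.

    Features come from a (filtered) comparison result, ordered by ascending
    adjusted p-value top to bottom, with standard-error bars.
    """
    if results.empty:
        raise EmptyResultError(
            "no features retained; loosen the p/fold-change/abundance filters"
        )
    feats = list(results.index[:max_features])[::-1]  # most significant on top
    mean_a, se_a = _group_stats(table, groups.samples_a, feats)
    mean_b, se_b = _group_stats(table, groups.samples_b, feats)
    pos = np.arange(len(feats), dtype=float)
    height = 0.38
    fig, ax = plt.subplots(figsize=spec.figsize or (7, max(2.5, 0.42 * len(feats) + 1.2)))
    ax.barh(pos + height / 2, mean_a, height=height, xerr=se_a,
            color=_GROUP_COLORS[0], label=groups.label_a, error_kw={"lw": 0.8})
    ax.barh(pos - height / 2, mean_b, height=height, xerr=se_b,
            color=_GROUP_COLORS[1], label=groups.label_b, error_kw={"lw": 0.8})
    ax.set_yticks(pos, feats)
    ax.set_xlabel("mean relative abundance")
    ax.set_ylabel(results["level_name"].iloc[0] if "level_name" in results else "feature")
    ax.legend(frameon=False)
    if spec.title:
        ax.set_title(spec.title)
    fig.tight_layout()
    return _save(fig, spec)


def plot_comparison_boxes(
    results: pd.DataFrame,
    table: AbundanceTable,
    groups: SampleGroups,
    spec: FigureSpec,
    max_features: int = 12,
) -> str:
    """Side-by-side boxplots of per-sample relative abundance per feature."""
    if results.empty:
        raise EmptyResultError(
            "no features retained; loosen the p/fold-change/abundance filters"
        )
    feats = list(results.index[:max_features])
    fig, ax = plt.subplots(figsize=spec.figsize or (max(4, 0.9 * len(feats) + 1.5), 4))
    pos_a = np.arange(len(feats), dtype=float) - 0.18
    pos_b = np.arange(len(feats), dtype=float) + 0.18
    data_a = [table.data.loc[f, list(groups.samples_a)].to_numpy() for f in feats]
    data_b = [table.data.loc[f, list(groups.samples_b)].to_numpy() for f in feats]
    for pos, data, color, label in (
        (pos_a, data_a, _GROUP_COLORS[0], groups.label_a),
        (pos_b, data_b, _GROUP_COLORS[1], groups.label_b),
    ):
        bp = ax.boxplot(data, positions=pos, widths=0.3, patch_artist=True)
        for patch in bp["boxes"]:
            patch.set_facecolor(color)
        ax.plot([], [], color=color, label=label)
    ax.set_xticks(np.arange(len(feats)), feats, rotation=45, ha="right")
    ax.set_ylabel("relative abundance")
    ax.legend(frameon=False)
    if spec.title:
        ax.set_title(spec.title)
    fig.tight_layout()
    return _save(fig, spec)


def plot_pie(
    table: AbundanceTable,
    samples,
    spec: FigureSpec,
    min_fraction: float = 0.01,
    group_label: str = "",
) -> str:
    """Composition pie of mean relative abundance within one sample group.

    Slices below ``min_fraction`` of the total are merged into "Other".
    """
    means = mean_relative_abundance(table, samples).sort_values(ascending=False)
    major = means[means >= min_fraction]
    other = means[means < min_fraction].sum()
    labels = list(major.index)
    sizes = list(major.to_numpy())
    if other > 0:
        labels.append("Other")
        sizes.append(float(other))
    fig, ax = plt.subplots(figsize=spec.figsize or (6, 6))
    cmap = plt.get_cmap(spec.color_map)
    colors = [cmap(i / max(1, len(sizes) - 1)) for i in range(len(sizes))]
    ax.pie(sizes, labels=labels, colors=colors, autopct="%1.1f%%", startangle=90,
           counterclock=False)
    ax.set_title(spec.title or (f"Composition ({table.level_name})"
                                + (f" — {group_label}" if group_label else "")))
    fig.tight_layout()
    return _save(fig, spec)


def plot_area_profiles(
    table: AbundanceTable,
    groups: SampleGroups,
    spec: FigureSpec,
    top_k: int = 10,
) -> str:
    """Per-sample stacked relative abundance profiles, grouped on the x-axis.

    The ``top_k`` features by overall mean get their own layers; everything
    else is lumped into "Other" so each stack still sums to 1.
    """
    if table.mode != "relative":
        raise UsageError("area profiles require a relative table; normalize first")
    if top_k < 1:
        raise UsageError(f"top_k must be >= 1, got {top_k}")
    samples = list(groups.samples_a) + list(groups.samples_b)
    sub = table.subset_samples(samples)
    means = sub.data.mean(axis=1).sort_values(ascending=False)
    top = list(means.index[:top_k])
    rest = [f for f in sub.feature_ids if f not in top]
    layers = sub.data.loc[top]
    labels = list(top)
    if rest:
        layers = pd.concat([layers, sub.data.loc[rest].sum().to_frame("Other").T])
        labels.append("Other")
    fig, ax = plt.subplots(figsize=spec.figsize or (max(6, 0.25 * len(samples) + 2), 4))
    x = np.arange(len(samples))
    cmap = plt.get_cmap(spec.color_map)
    colors = [cmap(i / max(1, len(labels) - 1)) for i in range(len(labels))]
    ax.stackplot(x, layers.to_numpy(), labels=labels, colors=colors)
    boundary = len(groups.samples_a) - 0.5
    ax.axvline(boundary, color="black", lw=1.2, ls="--")
    ax.set_xticks(x, samples, rotation=90, fontsize=6)
    ax.set_ylim(0, 1)
    ax.set_ylabel("relative abundance")
    mid_a = (len(groups.samples_a) - 1) / 2
    mid_b = len(groups.samples_a) + (len(groups.samples_b) - 1) / 2
    sec = ax.secondary_xaxis("top")
    sec.set_xticks([mid_a, mid_b], [groups.label_a, groups.label_b])
    ax.legend(loc="center left", bbox_to_anchor=(1.01, 0.5), fontsize=7, frameon=False)
    if spec.title:
        ax.set_title(spec.title)
    fig.tight_layout()
    return _save(fig, spec)


def plot_pca_scores(
    ordination: OrdinationResult,
    spec: FigureSpec,
    groups: SampleGroups | None = None,
    components: tuple[int, int] = (0, 1),
) -> str:
    """Scatter of sample scores on two principal components."""
    ci, cj = components
    if max(ci, cj) >= ordination.n_components:
        raise UsageError(
            f"requested components {components} but only {ordination.n_components} available"
        )
    fig, ax = plt.subplots(figsize=spec.figsize or (5.5, 5))
    xs, ys = ordination.scores[:, ci], ordination.scores[:, cj]
    if groups is not None:
        idx = {s: i for i, s in enumerate(ordination.sample_ids)}
        for samples, label, color in (
            (groups.samples_a, groups.label_a, _GROUP_COLORS[0]),
            (groups.samples_b, groups.label_b, _GROUP_COLORS[1]),
        ):
            sel = [idx[s] for s in samples if s in idx]
            ax.scatter(xs[sel], ys[sel], s=28, color=color, label=label, edgecolor="white",
                       linewidth=0.4)
        ax.legend(frameon=False)
    else:
        ax.scatter(xs, ys, s=28, color=_GROUP_COLORS[0], edgecolor="white", linewidth=0.4)
    ev = ordination.explained_fraction
    ax.set_xlabel(f"PC{ci + 1} ({ev[ci] * 100:.1f}% variance)")
    ax.set_ylabel(f"PC{cj + 1} ({ev[cj] * 100:.1f}% variance)")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    if spec.title:
        ax.set_title(spec.title)
    fig.tight_layout()
    return _save(fig, spec)


def _dendrogram_segments(tree: np.ndarray, order: list[int]) -> list:
    """Line segments of a dendrogram in (leaf position, height) coordinates."""
    n = len(order)
    pos = {leaf: float(i) for i, leaf in enumerate(order)}
    coords: dict[int, tuple[float, float]] = {leaf: (pos[leaf], 0.0) for leaf in order}
    segs = []
    for i, (a, b, h, _) in enumerate(tree):
        (xa, ha), (xb, hb) = coords[int(a)], coords[int(b)]
        segs += [[(xa, ha), (xa, h)], [(xb, hb), (xb, h)], [(xa, h), (xb, h)]]
        coords[n + i] = ((xa + xb) / 2.0, float(h))
    return segs


def plot_heatmap(
    matrix,
    clustering: ClusteringResult,
    spec: FigureSpec,
) -> str:
    """Clustered heatmap with marginal dendrograms on the clustered axes."""
    if isinstance(matrix, AbundanceTable):
        matrix = matrix.data
    df = pd.DataFrame(matrix)
    n_rows, n_cols = df.shape
    if clustering.row_order is not None and sorted(clustering.row_order) != list(range(n_rows)):
        raise UsageError(
            f"row clustering covers {len(clustering.row_order)} items, matrix has {n_rows} rows"
        )
    if clustering.col_order is not None and sorted(clustering.col_order) != list(range(n_cols)):
        raise UsageError(
            f"column clustering covers {len(clustering.col_order)} items, "
            f"matrix has {n_cols} columns"
        )
    row_order = clustering.row_order or list(range(n_rows))
    col_order = clustering.col_order or list(range(n_cols))
    data = df.to_numpy()[np.ix_(row_order, col_order)]

    fig = plt.figure(figsize=spec.figsize or (8, 6.5))
    gs = fig.add_gridspec(
        2, 3, width_ratios=[0.16, 1.0, 0.05], height_ratios=[0.16, 1.0],
        wspace=0.04, hspace=0.04,
    )
    ax_col = fig.add_subplot(gs[0, 1])
    ax_row = fig.add_subplot(gs[1, 0])
    ax_main = fig.add_subplot(gs[1, 1])
    ax_cbar = fig.add_subplot(gs[1, 2])

    vmin, vmax = float(np.min(data)), float(np.max(data))
    if vmin == vmax:  # constant matrix: give the color scale a tiny range
        vmin, vmax = vmin - 0.5, vmax + 0.5
    im = ax_main.imshow(data, aspect="auto", cmap=spec.color_map, vmin=vmin, vmax=vmax,
                        interpolation="nearest")
    ax_main.set_xticks(range(n_cols), [str(df.columns[i]) for i in col_order],
                       rotation=90, fontsize=6)
    ax_main.set_yticks(range(n_rows), [str(df.index[i]) for i in row_order], fontsize=6)
    ax_main.yaxis.tick_right()

    if clustering.col_tree is not None:
        segs = _dendrogram_segments(clustering.col_tree, col_order)
        ax_col.add_collection(LineCollection(segs, colors="black", linewidths=0.8))
        ax_col.set_xlim(-0.5, n_cols - 0.5)
        top = max(h for _, _, h, _ in clustering.col_tree) or 1.0
        ax_col.set_ylim(0, top * 1.05)
    ax_col.axis("off")
    if clustering.row_tree is not None:
        segs = [[(h, x) for x, h in seg] for seg in
                _dendrogram_segments(clustering.row_tree, row_order)]
        ax_row.add_collection(LineCollection(segs, colors="black", linewidths=0.8))
        ax_row.set_ylim(n_rows - 0.5, -0.5)
        top = max(h for _, _, h, _ in clustering.row_tree) or 1.0
        ax_row.set_xlim(top * 1.05, 0)
    ax_row.axis("off")

    fig.colorbar(im, cax=ax_cbar)
    if spec.title:
        ax_col.set_title(spec.title)
    return _save(fig, spec)
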