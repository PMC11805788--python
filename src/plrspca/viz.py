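"""Visual tools: sparsity/variability trade-off, stability heatmap,
part-occurrence heatmap, and the clr biplot."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .coda import CompositionTable, clr_matrix, pair_label
from .stability import StabilityPaths, part_occurrence_counts

__all__ = [
    "plot_tradeoff",
    "plot_stability_heatmap",
    "plot_part_heatmap",
    "plot_biplot",
    "tradeoff_crossing_index",
]


def tradeoff_crossing_index(paths: StabilityPaths) -> int:
    """Grid index where the zero-logratio and explained-variability curves
    cross (argmin of |sparsity% - explained%|), the heuristic model pick."""
    sparsity_pct = 100.0 * paths.zero_proportion
    return int(np.argmin(np.abs(sparsity_pct - paths.grid_exvar)))


def plot_tradeoff(paths: StabilityPaths, out_path, explained=None) -> None:
    """Dual-axis line plot of zero-logratio % (black) and explained
    variability % (red) against alpha, with the crossing point annotated."""
    explained = paths.grid_exvar if explained is None else np.asarray(explained)
    alphas = paths.grid.values
    sparsity_pct = 100.0 * paths.zero_proportion
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.plot(alphas, sparsity_pct, color="black", label="zero logratios (%)")
    ax.plot(alphas, explained, color="red", label="explained variability (%)")
    cross = int(np.argmin(np.abs(sparsity_pct - explained)))
    ax.axvline(alphas[cross], color="grey", linestyle=":")
    ax.annotate(
        f"crossing: alpha={alphas[cross]:.4g}",
        (alphas[cross], sparsity_pct[cross]),
        textcoords="offset points",
        xytext=(6, 6),
        fontsize=8,
    )
    ax.set_xlabel("sparsity parameter alpha")
    ax.set_ylabel("%")
    ax.set_ylim(-2, 102)
    ax.legend(loc="center right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def plot_stability_heatmap(paths: StabilityPaths, out_path) -> None:
    """Binary selection heatmap: PLRs (stability order) x alpha grid, with
    'total' and 'exvar' columns appended on the right."""
    rows = paths.order
    sel = paths.selection[rows]
    P, G = sel.shape
    fig, (ax, ax_tot) = plt.subplots(
        1, 2, figsize=(9, max(3.0, 0.16 * P)), width_ratios=[G, 6], sharey=True
    )
    ax.imshow(sel, aspect="auto", cmap="Blues", vmin=0, vmax=1, interpolation="nearest")
    ax.set_yticks(range(P))
    ax.set_yticklabels([pair_label(*paths.pairs[p]) for p in rows], fontsize=6)
    ticks = np.linspace(0, G - 1, 6).astype(int)
    ax.set_xticks(ticks)
    ax.set_xticklabels([f"{paths.grid.values[t]:.3g}" for t in ticks], fontsize=6)
    ax.set_xlabel("alpha")
    ax_tot.axis("off")
    for i, p in enumerate(rows):
        ax_tot.text(0.05, i, str(paths.totals[p]), fontsize=6, va="center")
        ax_tot.text(0.55, i, f"{paths.exvar[p]:.1f}", fontsize=6, va="center")
    ax_tot.set_ylim(P - 0.5, -0.5)
    ax_tot.text(0.05, -1.2, "total", fontsize=7, weight="bold")
    ax_tot.text(0.55, -1.2, "exvar", fontsize=7, weight="bold")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def plot_part_heatmap(paths: StabilityPaths, part_names, out_path) -> None:
    """Heatmap of part occurrence counts across selected PLRs: parts x alpha,
    darker shading = the part appears in more nonzero logratios."""
    counts = part_occurrence_counts(paths, part_names)
    D, G = counts.shape
    fig, ax = plt.subplots(figsize=(7, max(2.5, 0.3 * D)))
    im = ax.imshow(counts, aspect="auto", cmap="Greys", interpolation="nearest")
    ax.set_yticks(range(D))
    ax.set_yticklabels(part_names, fontsize=7)
    ticks = np.linspace(0, G - 1, 6).astype(int)
    ax.set_xticks(ticks)
    ax.set_xticklabels([f"{paths.grid.values[t]:.3g}" for t in ticks], fontsize=6)
    ax.set_xlabel("alpha")
    fig.colorbar(im, ax=ax, label="occurrences in nonzero PLRs")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def plot_biplot(table: CompositionTable, out_path) -> None:
    """Classical PCA biplot of the clr representation: points = sample
    scores, arrows = clr loadings, first two components.

    Components are oriented so the largest-|.| loading is positive; the
    axis labels carry the eigenvalue-ratio explained percentages.
    """
    if table.n < 3:
        raise ValueError("biplot needs at least 3 samples")
    clr = clr_matrix(table)
    clr = clr - clr.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(clr, full_matrices=False)
    for c in range(2):
        if Vt[c, np.argmax(np.abs(Vt[c]))] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores = U[:, :2] * s[:2]
    loadings = Vt[:2].T
    lam = s**2
    pct = 100.0 * lam / lam.sum()
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(scores[:, 0], scores[:, 1], s=12, color="steelblue", zorder=2)
    scale = 0.9 * np.max(np.abs(scores)) / max(np.max(np.abs(loadings)), 1e-12)
    for j, name in enumerate(table.part_names):
        ax.annotate(
            "",
            xy=(loadings[j, 0] * scale, loadings[j, 1] * scale),
            xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="firebrick", lw=1),
        )
        ax.annotate(
            name,
            (loadings[j, 0] * scale, loadings[j, 1] * scale),
            fontsize=8,
            color="firebrick",
        )
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"PC1 ({pct[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({pct[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
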