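"""Figure outputs: volcano plot, enrichment bars, qPCR validation bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def volcano_plot(
    de_results: pd.DataFrame,
    path: str | Path,
    fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    title: str = "Differential expression",
) -> None:
    """log2FC vs -log10 P with the screening thresholds drawn."""
    fig, ax = plt.subplots(figsize=(5, 4))
    x = de_results["log2fc"]
    y = -np.log10(np.clip(de_results["p_value"], 1e-300, None))
    colors = np.where(
        ~de_results["is_de"], "grey", np.where(x > 0, "crimson", "royalblue")
    )
    ax.scatter(x, y, s=4, c=colors, alpha=0.6, linewidths=0)
    lfc = np.log2(fc_threshold)
    for xx in (-lfc, lfc):
        ax.axvline(xx, color="k", ls="--", lw=0.6)
    ax.axhline(-np.log10(p_threshold), color="k", ls="--", lw=0.6)
    ax.set_xlabel("log2 fold change (case - control)")
    ax.set_ylabel("-log10 P")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def enrichment_bars(
    results: pd.DataFrame, path: str | Path, title: str = "Enriched gene sets"
) -> None:
    """Horizontal bars of -log10 P for significant sets."""
    sig = results[results["significant"]]
    fig, ax = plt.subplots(figsize=(5, max(2, 0.3 * len(sig) + 1)))
    if len(sig):
        ax.barh(sig["set_id"], -np.log10(sig["p_value"]), color="seagreen")
        ax.invert_yaxis()
    ax.set_xlabel("-log10 P")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qpcr_bars(
    rel: pd.DataFrame,
    compare: pd.DataFrame,
    path: str | Path,
    control_label: str = "control",
) -> None:
    """Grouped mean-fold bars per gene with significance stars (P<0.05/<0.01)."""
    genes = compare["gene_id"].tolist()
    fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(genes) + 1), 4))
    xs = np.arange(len(genes))
    width = 0.38
    means = rel.groupby(["gene_id", "group"])["fold"].mean()
    sems = rel.groupby(["gene_id", "group"])["fold"].sem()
    for offset, group, color in (
        (-width / 2, control_label, "slategray"),
        (width / 2, "case", "crimson"),
    ):
        vals = [means.get((g, group), np.nan) for g in genes]
        errs = [sems.get((g, group), 0.0) for g in genes]
        ax.bar(xs + offset, vals, width, yerr=errs, label=group, color=color, capsize=2)
    for i, gene in enumerate(genes):
        p = float(compare.loc[compare["gene_id"] == gene, "p_value"].iloc[0])
        star = "**" if p < 0.01 else "*" if p < 0.05 else ""
        if star:
            top = max(
                means.get((gene, "case"), 0), means.get((gene, control_label), 0)
            )
            ax.text(i, top * 1.05, star, ha="center")
    ax.set_xticks(xs, genes, rotation=45, ha="right")
    ax.set_ylabel("relative expression (2^-ddCt)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
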