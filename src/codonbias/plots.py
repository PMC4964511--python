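"""The three standard codon-usage figures: ENC plot, neutrality plot and
the ENC-ratio histogram."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .enc_neutrality import EncRatioDistribution, NeutralityFit, enc_expected


def enc_plot(profiles: pd.DataFrame, path: str | Path) -> None:
    """Per-gene ENC against GC3s with the mutation-only null curve."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(profiles["gc3s"], profiles["enc"], s=4, alpha=0.4, linewidths=0)
    grid = np.linspace(0.0, 1.0, 200)
    ax.plot(grid, [enc_expected(s) for s in grid], "k-", lw=1.2, label="expected")
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENC")
    ax.set_ylim(15, 65)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def neutrality_plot(
    profiles: pd.DataFrame, fit: NeutralityFit, path: str | Path
) -> None:
    """GC12 against GC3 with the fitted regression line."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(profiles["gc3"], profiles["gc12"], s=4, alpha=0.4, linewidths=0)
    xs = np.array([profiles["gc3"].min(), profiles["gc3"].max()])
    ax.plot(xs, fit.intercept + fit.slope * xs, "k-", lw=1.2,
            label=f"slope={fit.slope:.4f}, r={fit.pearson_r:.3f}")
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def enc_ratio_hist_plot(dist: EncRatioDistribution, path: str | Path) -> None:
    """Frequency distribution of the per-gene ENC ratio."""
    fig, ax = plt.subplots(figsize=(5, 4))
    widths = np.diff(dist.bin_edges)
    ax.bar(dist.bin_edges[:-1], dist.bin_counts, width=widths, align="edge",
           edgecolor="white")
    ax.set_xlabel("(ENC_exp − ENC_obs) / ENC_exp")
    ax.set_ylabel("number of genes")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
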