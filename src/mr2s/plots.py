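"""Optional rendering of the four standard MR sensitivity panels.

Built entirely from the plot-ready tables the diagnostics module emits;
nothing here feeds back into any estimate.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .summary_data import HarmonizedDataset


def four_panel(
    ds: HarmonizedDataset,
    forest: pd.DataFrame,
    loo: pd.DataFrame,
    funnel: pd.DataFrame,
):
    """Forest, leave-one-out, scatter and funnel panels as one figure."""
    fig, axes = plt.subplots(2, 2, figsize=(11, 9))

    snp = forest[forest["kind"] == "snp"]
    pooled = forest[forest["kind"] == "pooled"]
    ax = axes[0, 0]
    y = range(len(snp))
    ax.errorbar(
        snp["estimate"],
        y,
        xerr=[snp["estimate"] - snp["ci_low"], snp["ci_high"] - snp["estimate"]],
        fmt="o",
        color="black",
        ms=3,
    )
    ax.set_yticks(list(y), snp["label"])
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("log odds per exposure unit")
    ax.set_title("Forest")

    ax = axes[0, 1]
    y = range(len(loo))
    ax.errorbar(
        loo["estimate"],
        y,
        xerr=[loo["estimate"] - loo["ci_low"], loo["ci_high"] - loo["estimate"]],
        fmt="o",
        color="black",
        ms=3,
    )
    ax.set_yticks(list(y), loo["excluded"])
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_title("Leave-one-out (IVW)")

    ax = axes[1, 0]
    bx = [p.beta_exposure for p in ds.pairs]
    by = [p.beta_outcome for p in ds.pairs]
    ax.errorbar(
        bx,
        by,
        xerr=[p.se_exposure for p in ds.pairs],
        yerr=[p.se_outcome for p in ds.pairs],
        fmt="o",
        color="black",
        ms=3,
        lw=0.8,
    )
    for _, row in pooled.iterrows():
        ax.axline((0, 0), slope=row["estimate"], lw=0.8, label=row["label"])
    ax.legend(fontsize=7)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome (log odds)")
    ax.set_title("Scatter")

    ax = axes[1, 1]
    ax.scatter(funnel["estimate"], funnel["inv_se"], color="black", s=12)
    for _, row in pooled.iterrows():
        ax.axvline(row["estimate"], lw=0.8)
    ax.set_xlabel("per-SNP causal estimate")
    ax.set_ylabel("1 / SE")
    ax.set_title("Funnel")

    fig.tight_layout()
    return fig
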