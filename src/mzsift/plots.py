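"""Figure exports: volcano plots, QC drift trends, PCA scores, heatmaps."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .mva import ClusterResult, PcaResult  # noqa: E402
from .table import FeatureTable  # noqa: E402

__all__ = ["volcano_plot", "qc_trend_plot", "pca_scores_plot", "heatmap_plot"]

_GROUP_COLORS = {"Blank": "tab:blue", "Low": "tab:orange",
                 "High": "tab:red", "qc": "tab:green",
                 "substrate_blank": "tab:gray", "enzyme_blank": "tab:purple"}


def volcano_plot(comparisons: pd.DataFrame, pair: str, path: str | Path,
                 fc_thresh: float = 1.5, p_thresh: float = 0.001) -> None:
    sub = comparisons[comparisons["pair"] == pair]
    fc = sub["fold_change"].replace([np.inf, -np.inf], np.nan)
    logp = -np.log10(sub["p_value"].clip(lower=1e-300))
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(fc, logp, s=8, alpha=0.6)
    ax.axhline(-np.log10(p_thresh), ls="--", c="gray", lw=0.8)
    for x in (-fc_thresh, fc_thresh):
        ax.axvline(x, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("signed fold change")
    ax.set_ylabel("-log10 p")
    ax.set_title(pair)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def qc_trend_plot(before: FeatureTable, after: FeatureTable, feature: str,
                  path: str | Path) -> None:
    qc_ids = before.type_columns("qc")
    idx = before.samples.loc[qc_ids, "injection_index"]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(idx, before.abundance.loc[feature, qc_ids], "o-",
            label="before")
    ax.plot(idx, after.abundance.loc[feature, qc_ids], "s-",
            label="after")
    ax.set_xlabel("injection index")
    ax.set_ylabel("log10 abundance")
    ax.set_title(f"QC drift, {feature}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pca_scores_plot(result: PcaResult, samples: pd.DataFrame,
                    path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    groups = samples.loc[result.scores.index, "group"]
    for g in groups.unique():
        m = groups == g
        ax.scatter(result.scores.loc[m, "PC1"], result.scores.loc[m, "PC2"],
                   label=g, color=_GROUP_COLORS.get(g), s=25)
    ax.set_xlabel(f"PC1 ({result.variance_explained[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({result.variance_explained[1]:.1f}%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def heatmap_plot(result: ClusterResult, path: str | Path) -> None:
    z = result.zscores.loc[result.feature_order, result.sample_order]
    fig, ax = plt.subplots(figsize=(6, max(3, 0.12 * len(z))))
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r",
                   vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(len(z.columns)))
    ax.set_xticklabels(z.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(z.index)))
    ax.set_yticklabels(z.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
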