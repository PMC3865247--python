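"""Evaluation surfaces of the depth titration.

Quantifies how the outcome of differential expression analysis changes
with sequencing depth: how many genes are called, how strong the called
effects are (mean M and D among DEGs), whether a benchmark gene set
(e.g. experimentally verified tissue markers) is recovered, how a
low-expression gene class (TF-like) compares to the transcriptome-wide
mean, and how fold-change estimates correlate with an external
reference (e.g. qPCR) at each depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CountExperiment
from .noise_odds import compute_md, replace_zeros
from .normalization import sizefactor_normalize


@dataclass
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: frozenset[str]

    def __init__(self, name: str, members) -> None:
        object.__setattr__(self, "name", name)
        ms = frozenset(members)
        if not ms:
            raise ValueError("gene set must be non-empty")
        object.__setattr__(self, "members", ms)


def recovery_count(results: pd.DataFrame, gene_set: GeneSet) -> int:
    """Number of set members with called == True; absent members count as missed."""
    present = results.index.intersection(list(gene_set.members))
    if len(present) == 0:
        return 0
    return int(results.loc[present, "called"].astype(bool).sum())


def missing_members(results: pd.DataFrame, gene_set: GeneSet) -> list[str]:
    """Set members absent from the result table (reported, never dropped silently)."""
    return sorted(gene_set.members - set(results.index))


def deg_effect_summary(results: pd.DataFrame) -> tuple[int, float, float]:
    """(n_deg, mean M among called, mean D among called); NaN means when no calls."""
    called = results["called"].astype(bool)
    n = int(called.sum())
    if n == 0:
        return 0, float("nan"), float("nan")
    return n, float(results.loc[called, "M"].mean()), float(results.loc[called, "D"].mean())


def md_scatter_table(results: pd.DataFrame) -> pd.DataFrame:
    """Per-gene (M, D, called) export for joint M-D structure plots."""
    return results[["M", "D", "called"]].copy()


def attach_md(results: pd.DataFrame, experiment: CountExperiment) -> pd.DataFrame:
    """Recompute M and D from size-factor-normalized condition means.

    Used for engines (the NB exact test) whose native output does not
    carry (M, D), so effect summaries are comparable across engines.
    """
    _, _, samples_a, samples_b = experiment.condition_split()
    values = sizefactor_normalize(experiment.counts).values
    expressed = experiment.counts.sum(axis=1) > 0
    values = replace_zeros(values.loc[expressed])
    m, d = compute_md(values[samples_a].mean(axis=1).to_numpy(),
                      values[samples_b].mean(axis=1).to_numpy())
    md = pd.DataFrame({"M": m, "D": d}, index=values.index)
    out = results.copy()
    out["M"] = md["M"].reindex(results.index)
    out["D"] = md["D"].reindex(results.index)
    return out


def expression_class_test(values: pd.DataFrame, gene_set: GeneSet,
                          samples: list[str] | None = None
                          ) -> tuple[float, float, float, float]:
    """Welch t-test of a gene class's expression against all genes.

    Per-gene expression is the mean normalized value over ``samples``
    (all samples by default). Returns (mean_all, mean_set, t, p); the set
    is compared against the full gene background, so a set equal to all
    genes has mean difference exactly 0.
    """
    if samples is None:
        samples = list(values.columns)
    expr = values[samples].mean(axis=1)
    members = expr.index.intersection(list(gene_set.members))
    if len(members) < 2:
        raise ValueError("gene set needs >= 2 members present in the matrix")
    set_expr = expr.loc[members]
    t, p = stats.ttest_ind(set_expr, expr, equal_var=False)
    return float(expr.mean()), float(set_expr.mean()), float(t), float(p)


def foldchange_correlation(fc_by_depth: dict[int, pd.Series],
                           fc_reference: pd.Series) -> pd.DataFrame:
    """Spearman and Pearson correlation of per-depth log2FC against a reference.

    Spearman uses average ranks on ties; Pearson is computed on the log2
    fold changes directly. One row per depth, needs >= 3 shared genes.
    """
    rows = []
    for depth in sorted(fc_by_depth):
        est = fc_by_depth[depth].replace([np.inf, -np.inf], np.nan).dropna()
        shared = est.index.intersection(fc_reference.index)
        if len(shared) < 3:
            raise ValueError(f"fewer than 3 shared genes at depth {depth}")
        x = est.loc[shared].to_numpy(dtype=float)
        y = fc_reference.loc[shared].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"zero variance in fold changes at depth {depth}")
        rho = stats.spearmanr(x, y).statistic
        r = stats.pearsonr(x, y).statistic
        rows.append((depth, len(shared), float(rho), float(r)))
    return pd.DataFrame(rows, columns=["depth", "n_genes", "spearman_rho",
                                       "pearson_r"]).set_index("depth")


# ---------------------------------------------------------------------------
# Simple figures (M-D scatter, titration curves)
# ---------------------------------------------------------------------------

def plot_md_scatter(results: pd.DataFrame, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tab = md_scatter_table(results)
    fig, ax = plt.subplots(figsize=(5, 4))
    for flag, color, label in ((False, "0.7", "not called"), (True, "C3", "DEG")):
        sub = tab[tab["called"] == flag]
        ax.scatter(sub["M"], sub["D"], s=4, c=color, label=label, alpha=0.6)
    ax.set_xlabel("M (|log2 fold difference|)")
    ax.set_ylabel("D (|expression difference|)")
    ax.set_yscale("symlog")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_titration_curves(summary: pd.DataFrame, path: str) -> None:
    """DEG count vs depth, one line per (method, normalization)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for (method, norm), sub in summary.groupby(["method", "normalization"]):
        sub = sub.sort_values("depth")
        ax.plot(sub["depth"] / 1e6, sub["n_deg"], marker="o", label=f"{method} ({norm})")
    ax.set_xlabel("reads per replicate (millions)")
    ax.set_ylabel("number of DEGs")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
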