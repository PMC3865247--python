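"""Core containers and text-table I/O for depth-titration experiments.

A :class:`CountExperiment` bundles the three tables every stage of the
pipeline needs: a genes x samples matrix of non-negative integer read
counts, per-gene lengths in base pairs, and a sample design mapping each
sample to a condition and replicate label.

All tables are plain tab-separated text (UTF-8, header row, no quoting);
the count matrix carries gene identifiers in its first column and one
column per sample named ``<condition>_<replicate>``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GENE_ID = "gene_id"


@dataclass
class CountExperiment:
    """Replicated two-condition count data.

    Parameters
    ----------
    counts
        Integer DataFrame, genes in rows (index = gene identifiers),
        samples in columns.
    lengths
        Series of gene lengths in bp, indexed like ``counts``.
    design
        DataFrame indexed by sample name with columns ``condition`` and
        ``replicate``; row order fixes the condition order (the first
        condition encountered is condition A in fold-change conventions).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    design: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()][:3].tolist()
            raise ValueError(f"gene lengths missing for {missing} ...")
        if (self.lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        extra = set(self.counts.columns) - set(self.design.index)
        if extra:
            raise ValueError(f"samples missing from design: {sorted(extra)}")
        self.design = self.design.loc[list(self.counts.columns)]

    @property
    def conditions(self) -> list[str]:
        """Condition labels in design order (first = condition A)."""
        return list(dict.fromkeys(self.design["condition"]))

    def samples_of(self, condition: str) -> list[str]:
        mask = self.design["condition"] == condition
        return list(self.design.index[mask])

    def condition_split(self) -> tuple[str, str, list[str], list[str]]:
        """Return (cond_A, cond_B, samples_A, samples_B); errors unless 2 conditions."""
        conds = self.conditions
        if len(conds) != 2:
            raise ValueError(f"expected exactly 2 conditions, got {conds}")
        a, b = conds
        return a, b, self.samples_of(a), self.samples_of(b)

    @property
    def depths(self) -> pd.Series:
        """Per-sample total read counts (column sums)."""
        return self.counts.sum(axis=0)

    def copy(self) -> "CountExperiment":
        return CountExperiment(self.counts.copy(), self.lengths.copy(), self.design.copy())


def derive_seed(root_seed: int, *keys: int) -> int:
    """Derive an independent stream seed < 2**31 from a root seed and keys.

    Deterministic and order-sensitive in ``keys``; used so per-sample,
    per-rung draws are reproducible regardless of evaluation order.
    """
    ss = np.random.SeedSequence(entropy=int(root_seed), spawn_key=tuple(int(k) for k in keys))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# TSV round-trip helpers
# ---------------------------------------------------------------------------

def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label=GENE_ID)


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(np.int64)


def write_lengths(lengths: pd.Series, path: str | Path) -> None:
    lengths.rename("length_bp").to_csv(path, sep="\t", index_label=GENE_ID)


def read_lengths(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(np.int64)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index_label="sample")


def read_design(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if not {"condition", "replicate"} <= set(df.columns):
        raise ValueError("design needs 'condition' and 'replicate' columns")
    return df


def write_experiment(exp: CountExperiment, outdir: str | Path, prefix: str = "") -> dict[str, Path]:
    """Write counts/lengths/design TSVs into ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / f"{prefix}counts.tsv",
        "lengths": outdir / f"{prefix}lengths.tsv",
        "design": outdir / f"{prefix}design.tsv",
    }
    write_counts(exp.counts, paths["counts"])
    write_lengths(exp.lengths, paths["lengths"])
    write_design(exp.design, paths["design"])
    return paths


def read_experiment(counts_path: str | Path, lengths_path: str | Path,
                    design_path: str | Path) -> CountExperiment:
    return CountExperiment(
        counts=read_counts(counts_path),
        lengths=read_lengths(lengths_path),
        design=read_design(design_path),
    )


def read_gene_set(path: str | Path) -> list[str]:
    """Newline-delimited gene identifiers; blank lines and '#' comments skipped."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_fold_changes(path: str | Path) -> pd.Series:
    """Two-column TSV (gene_id, log2fc) -> Series of reference log2 fold changes."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(float)
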