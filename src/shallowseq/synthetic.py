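"""Synthetic two-condition RNA-seq count data with a known truth table.

The generator emulates the statistical structure of a glandular bulk
transcriptome: ~10^4 genes with heavy-tailed (log-normal) relative
abundances so a few dominant transcripts soak up a large share of reads;
a small planted "focal" set of highly expressed, strongly differential
genes (the analogue of experimentally verified tissue-specific marker
genes); and a "TF-like" class whose baseline expression sits well below
the gene-wide mean but which can still carry large fold differences.

Counts are drawn as a multinomial allocation of a fixed per-sample read
budget over genes, with per-replicate gamma perturbation of the gene
probabilities (variance parameter ``dispersion``), so marginal counts
behave like negative binomials while every column sum equals the
configured depth exactly. That makes downstream read subsampling and
depth semantics exact rather than approximate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .core import GENE_ID, CountExperiment

GENE_CLASSES = ("null", "de", "focal", "tf_null", "tf_de")


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Defaults reflect the study conditions this package benchmarks:
    two biological replicates per condition at 12 million reads each,
    a honey-bee-scale gene set (10,000 genes), 11 focal marker genes,
    and a few-hundred-gene low-abundance TF-like class.
    """

    n_genes: int = 10_000
    n_replicates: int = 2
    depth_per_replicate: int = 12_000_000
    #: log-normal parameters of relative abundance; sdlog 1.8 gives the
    #: heavy tail where the top transcripts dominate the library.
    baseline_meanlog: float = 1.0
    baseline_sdlog: float = 1.8
    #: gamma noise variance on per-replicate gene rates (NB overdispersion phi)
    dispersion: float = 0.05
    frac_de: float = 0.05
    #: |log2FC| for DE genes ~ |Normal(lfc_mean, lfc_sd)|, sign +/- equiprobable
    lfc_mean: float = 1.5
    lfc_sd: float = 0.8
    n_focal: int = 11
    focal_lfc_min: float = 3.0
    focal_baseline_quantile: float = 0.9
    n_tf: int = 400
    tf_abundance_scale: float = 0.1
    frac_tf_de: float = 0.25
    length_min: int = 500
    length_max: int = 5_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_replicates <= 0:
            raise ValueError("n_genes and n_replicates must be positive")
        if not isinstance(self.depth_per_replicate, (int, np.integer)):
            raise ValueError("depth_per_replicate must be an integer")
        if self.depth_per_replicate <= 0:
            raise ValueError("depth_per_replicate must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for name in ("frac_de", "frac_tf_de", "focal_baseline_quantile"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_focal < 0 or self.n_tf < 0:
            raise ValueError("n_focal and n_tf must be non-negative")
        if self.n_focal + self.n_tf > self.n_genes:
            raise ValueError("n_focal + n_tf exceeds n_genes")
        if self.n_focal > 0 and self.frac_de * self.n_genes < self.n_focal:
            raise ValueError("frac_de * n_genes < n_focal: focal genes are a subset of DE genes")
        if not 0.0 < self.tf_abundance_scale <= 1.0:
            raise ValueError("tf_abundance_scale must be in (0, 1]")
        if self.focal_lfc_min <= 0:
            raise ValueError("focal_lfc_min must be positive")
        if self.length_min <= 0 or self.length_max < self.length_min:
            raise ValueError("need 0 < length_min <= length_max")


def _gene_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def simulate_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-gene class, true log2 fold change, baseline abundance and length."""
    n = config.n_genes
    genes = _gene_ids(n)
    baseline = rng.lognormal(config.baseline_meanlog, config.baseline_sdlog, size=n)

    gene_class = np.array(["null"] * n, dtype=object)
    lfc = np.zeros(n)

    # TF-like class: baseline scaled down; a fraction carries real fold changes.
    idx = rng.permutation(n)
    tf_idx = idx[: config.n_tf]
    rest = idx[config.n_tf:]
    baseline[tf_idx] *= config.tf_abundance_scale
    n_tf_de = int(round(config.frac_tf_de * config.n_tf))
    tf_de_idx = tf_idx[:n_tf_de]
    gene_class[tf_idx] = "tf_null"
    gene_class[tf_de_idx] = "tf_de"

    # Ordinary DE genes among the remaining pool, focal genes as a subset.
    n_de = int(round(config.frac_de * config.n_genes))
    n_de = min(n_de, len(rest))
    de_idx = rest[:n_de]
    gene_class[de_idx] = "de"
    focal_idx = de_idx[: config.n_focal]
    gene_class[focal_idx] = "focal"

    sign = rng.choice([-1.0, 1.0], size=n)
    mag = np.abs(rng.normal(config.lfc_mean, config.lfc_sd, size=n))
    active = np.isin(gene_class, ("de", "tf_de"))
    lfc[active] = (sign * mag)[active]

    if config.n_focal > 0:
        # high baseline: resample from the upper tail of the same log-normal
        u = rng.uniform(size=len(focal_idx))
        q = config.focal_baseline_quantile + u * (1.0 - config.focal_baseline_quantile)
        q = np.clip(q, None, 1 - 1e-12)
        baseline[focal_idx] = stats.lognorm.ppf(
            q, s=config.baseline_sdlog, scale=np.exp(config.baseline_meanlog))
        lfc[focal_idx] = sign[focal_idx] * (
            config.focal_lfc_min + np.abs(rng.normal(0.0, config.lfc_sd, size=len(focal_idx))))

    lengths = rng.integers(config.length_min, config.length_max + 1, size=n)
    truth = pd.DataFrame(
        {
            "gene_class": gene_class,
            "true_log2fc": lfc,
            "baseline_abundance": baseline,
            "length_bp": lengths,
        },
        index=pd.Index(genes, name=GENE_ID),
    )
    return truth


def simulate_experiment(config: SimConfig) -> tuple[CountExperiment, pd.DataFrame]:
    """Generate a replicated two-condition experiment plus its truth table.

    Condition A relative abundances equal ``baseline * 2**true_log2fc``
    (renormalized); condition B uses the baseline. Each replicate's gene
    probabilities are perturbed by mean-1 gamma noise with variance
    ``dispersion`` before a multinomial draw of exactly
    ``depth_per_replicate`` reads.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = simulate_truth(config, rng)

    baseline = truth["baseline_abundance"].to_numpy()
    lfc = truth["true_log2fc"].to_numpy()
    rel = {"A": baseline * np.exp2(lfc), "B": baseline}

    columns: dict[str, np.ndarray] = {}
    design_rows = []
    for cond in ("A", "B"):
        p0 = rel[cond] / rel[cond].sum()
        for rep in range(1, config.n_replicates + 1):
            if config.dispersion > 0:
                shape = 1.0 / config.dispersion
                noise = rng.gamma(shape, 1.0 / shape, size=config.n_genes)
            else:
                noise = 1.0
            p = p0 * noise
            p = p / p.sum()
            columns[f"{cond}_{rep}"] = rng.multinomial(config.depth_per_replicate, p)
            design_rows.append((f"{cond}_{rep}", cond, str(rep)))

    counts = pd.DataFrame(columns, index=truth.index, dtype=np.int64)
    design = pd.DataFrame(
        [(c, r) for _, c, r in design_rows],
        index=pd.Index([s for s, _, _ in design_rows], name="sample"),
        columns=["condition", "replicate"],
    )
    exp = CountExperiment(counts=counts, lengths=truth["length_bp"], design=design)
    return exp, truth


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index_label=GENE_ID)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def truth_recall(results: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    """Per-class sensitivity and overall false-discovery proportion.

    ``results`` must carry a boolean ``called`` column indexed by gene.
    Sensitivity within a class is (called and truly DE) / truly DE; the
    false-discovery proportion within a class is (called and truly null) /
    called among that class's genes, 0 when nothing is called. Classes with
    no truly-DE member report sensitivity 0. An ``overall`` row pools all
    classes.
    """
    shared = results.index.intersection(truth.index)
    if len(shared) == 0:
        raise ValueError("results and truth share no genes")
    called = results.loc[shared, "called"].astype(bool)
    t = truth.loc[shared]
    truly_de = t["true_log2fc"] != 0

    def _row(mask: pd.Series) -> tuple[int, float, float]:
        de = mask & truly_de
        denom = int(de.sum())
        sens = float((called & de).sum() / denom) if denom else 0.0
        n_called = int((called & mask).sum())
        fdp = float((called & mask & ~truly_de).sum() / n_called) if n_called else 0.0
        return denom, sens, fdp

    rows = []
    for cls in GENE_CLASSES:
        rows.append((cls, *_row(t["gene_class"] == cls)))
    rows.append(("overall", *_row(pd.Series(True, index=t.index))))
    return pd.DataFrame(rows, columns=["gene_class", "n_true_de", "sensitivity",
                                       "false_discovery_proportion"]).set_index("gene_class")
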