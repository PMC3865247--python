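"""One-command titration study: simulate/load -> titrate -> test -> summarize.

A :class:`RunConfig` (a plain YAML file on disk) pins everything a run
needs — the input tables or a synthetic-data configuration, the depth
ladder, the engines with their thresholds, the normalizations and one
root seed — and :func:`run_titration_study` executes every
(depth, engine, normalization) combination, writing one DE result TSV
per combination, a titration summary TSV, and a JSON manifest with the
seed and a config hash. Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .benchmark import GeneSet, attach_md, deg_effect_summary, recovery_count
from .core import CountExperiment, derive_seed, read_experiment, read_fold_changes, read_gene_set
from .nb_exact import nb_exact_test
from .noise_odds import noise_odds_test
from .subsampling import DepthLadder, titrate
from .synthetic import SimConfig, simulate_experiment, write_truth

log = logging.getLogger("shallowseq")

ENGINES = ("noiseq", "nbexact")


@dataclass
class RunConfig:
    """Inputs, ladder, engines and seed of a titration study."""

    counts: str | None = None
    lengths: str | None = None
    design: str | None = None
    sim: SimConfig | None = None
    depths: tuple[int, ...] = (1_000_000, 3_000_000, 6_000_000, 12_000_000)
    engines: tuple[str, ...] = ("noiseq", "nbexact")
    normalizations: tuple[str, ...] = ("rpkm", "uq")
    prob_threshold: float = 0.8
    alpha: float = 0.05
    gene_sets: dict[str, str] = field(default_factory=dict)  # name -> ID-file path
    fc_reference: str | None = None  # two-column TSV gene_id, log2fc
    nested: bool = False
    seed: int = 0
    outdir: str = "shallowseq_run"

    def __post_init__(self) -> None:
        self.depths = tuple(int(d) for d in self.depths)
        self.engines = tuple(self.engines)
        self.normalizations = tuple(self.normalizations)
        unknown = set(self.engines) - set(ENGINES)
        if unknown:
            raise ValueError(f"unknown engines {sorted(unknown)}")
        if not 0.0 < self.prob_threshold < 1.0 or not 0.0 < self.alpha < 1.0:
            raise ValueError("thresholds must lie in (0, 1)")
        if self.sim is None and not (self.counts and self.lengths and self.design):
            raise ValueError("need either a sim config or counts/lengths/design paths")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" in raw and raw["sim"] is not None:
            raw["sim"] = SimConfig(**raw["sim"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.sim is not None:
            d["sim"] = asdict(self.sim)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _combos(config: RunConfig):
    for engine in config.engines:
        if engine == "noiseq":
            for norm in config.normalizations:
                yield engine, norm
        else:
            yield engine, "sizefactor"


def _run_engine(engine: str, norm: str, exp: CountExperiment,
                config: RunConfig) -> pd.DataFrame:
    if engine == "noiseq":
        return noise_odds_test(exp, normalization=norm, threshold=config.prob_threshold)
    results = nb_exact_test(exp, alpha=config.alpha)
    return attach_md(results, exp)


def run_titration_study(config: RunConfig) -> pd.DataFrame:
    """Execute the full study described by ``config``.

    Returns the titration summary (one row per depth x engine x
    normalization) and writes all artifacts under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    if config.sim is not None:
        sim = SimConfig(**{**asdict(config.sim), "seed": derive_seed(config.seed, 1)})
        exp, truth = simulate_experiment(sim)
        write_truth(truth, outdir / "truth.tsv")
        log.info("simulated %d genes x %d samples", *exp.counts.shape)
    else:
        exp = read_experiment(config.counts, config.lengths, config.design)
        log.info("loaded %d genes x %d samples", *exp.counts.shape)

    gene_sets = [GeneSet(name, read_gene_set(path))
                 for name, path in sorted(config.gene_sets.items())]

    ladder = DepthLadder(depths=config.depths, seed=derive_seed(config.seed, 2))
    rungs = titrate(exp, ladder, nested=config.nested)

    rows = []
    fc_by_depth: dict[int, pd.Series] = {}
    for depth in ladder.depths:
        sub = rungs[depth]
        for engine, norm in _combos(config):
            t1 = time.time()
            results = _run_engine(engine, norm, sub, config)
            n_deg, mean_m, mean_d = deg_effect_summary(results)
            row = {
                "depth": depth,
                "method": engine,
                "normalization": norm,
                "n_genes_tested": len(results),
                "n_deg": n_deg,
                "mean_M_deg": mean_m,
                "mean_D_deg": mean_d,
            }
            for gs in gene_sets:
                row[f"recovery_{gs.name}"] = recovery_count(results, gs)
                row[f"set_size_{gs.name}"] = len(gs.members)
            rows.append(row)
            results.to_csv(outdir / f"de_{engine}_{norm}_{depth}.tsv", sep="\t",
                           index_label="gene_id")
            if engine == "nbexact":
                fc_by_depth[depth] = results["log2fc"]
            log.info("depth=%d engine=%s norm=%s tested=%d called=%d (%.1fs)",
                     depth, engine, norm, len(results), n_deg, time.time() - t1)

    summary = pd.DataFrame(rows)
    summary.to_csv(outdir / "titration_summary.tsv", sep="\t", index=False)

    if config.fc_reference and fc_by_depth:
        from .benchmark import foldchange_correlation
        ref = read_fold_changes(config.fc_reference)
        corr = foldchange_correlation(fc_by_depth, ref)
        corr.to_csv(outdir / "foldchange_correlation.tsv", sep="\t")

    manifest = {
        "seed": config.seed,
        "config_hash": config.digest(),
        "config": config.to_dict(),
        "version": __version__,
        "elapsed_s": round(time.time() - t0, 2),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return summary
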