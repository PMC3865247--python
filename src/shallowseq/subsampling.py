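"""Read-level rarefaction of count matrices to exact target depths.

Subsampling draws reads without replacement from each sample's observed
reads — a multivariate hypergeometric draw over genes — so every output
column sums to the target depth exactly and no entry exceeds its input.
This mirrors drawing a shallow sequencing run at random out of a deeper
one, which makes depth a controlled variable of the titration rather
than an expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CountExperiment, derive_seed


@dataclass
class DepthLadder:
    """Ordered per-replicate target depths of a titration.

    Default rungs are 1, 3, 6 and 12 million reads per replicate.
    """

    depths: tuple[int, ...] = (1_000_000, 3_000_000, 6_000_000, 12_000_000)
    seed: int = 0

    def __post_init__(self) -> None:
        depths = tuple(int(d) for d in self.depths)
        if any(d <= 0 for d in depths):
            raise ValueError("depths must be positive")
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ValueError("depths must be strictly increasing")
        self.depths = depths


def _subsample_column(counts: np.ndarray, target: int, seed: int) -> np.ndarray:
    total = int(counts.sum())
    if target > total:
        raise ValueError(f"target depth {target} exceeds sample total {total}")
    if target == total:
        return counts.copy()
    if target == 0:
        return np.zeros_like(counts)
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, target, method="marginals")


def subsample_counts(experiment: CountExperiment, target_depth: int,
                     seed: int) -> CountExperiment:
    """Rarefy every sample to ``target_depth`` reads without replacement.

    Deterministic given ``seed``; per-sample streams are derived from
    (seed, sample index) so column order does not alter any draw.
    """
    if not isinstance(target_depth, (int, np.integer)):
        raise ValueError("target_depth must be an integer")
    if target_depth < 0:
        raise ValueError("target_depth must be non-negative")
    cols = {}
    for j, sample in enumerate(experiment.counts.columns):
        col = experiment.counts[sample].to_numpy()
        cols[sample] = _subsample_column(col, int(target_depth), derive_seed(seed, j))
    counts = pd.DataFrame(cols, index=experiment.counts.index, dtype=np.int64)
    return CountExperiment(counts, experiment.lengths, experiment.design)


def titrate(experiment: CountExperiment, ladder: DepthLadder,
            nested: bool = False) -> dict[int, CountExperiment]:
    """Subsample the experiment once per ladder rung.

    By default each rung is an independent draw from the full-depth matrix.
    With ``nested=True`` each rung is drawn from the next-deeper rung, so
    shallower rungs are subsets of deeper ones.
    """
    min_total = int(experiment.depths.min())
    if ladder.depths[-1] > min_total:
        raise ValueError(
            f"deepest rung {ladder.depths[-1]} exceeds shallowest sample total {min_total}")
    out: dict[int, CountExperiment] = {}
    if nested:
        current = experiment
        for r, depth in reversed(list(enumerate(ladder.depths))):
            current = subsample_counts(current, depth, derive_seed(ladder.seed, r))
            out[depth] = current
        return {d: out[d] for d in ladder.depths}
    for r, depth in enumerate(ladder.depths):
        out[depth] = subsample_counts(experiment, depth, derive_seed(ladder.seed, r))
    return out
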