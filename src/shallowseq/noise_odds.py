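"""Nonparametric noise-odds differential expression test.

Each gene's between-condition signal is the pair (M, D), where M is the
absolute log2 fold difference and D the absolute raw difference between
the replicate-averaged normalized expressions of the two conditions. The
null is the empirical "noise" distribution of the same (M, D) pairs
computed between replicate samples of the same condition, pooled over
genes and both conditions. The probability of differential expression
is the fraction of noise pairs strictly dominated by the signal in both
coordinates; a gene is called at probability > 0.8 by default.

Zeros are replaced by half the smallest positive value of the normalized
matrix before any ratio is formed, so M is always finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CountExperiment
from .normalization import NormalizedMatrix, normalize

DEFAULT_THRESHOLD = 0.8


@dataclass
class NoiseDistribution:
    """Pooled within-condition replicate (M, D) pairs."""

    M: np.ndarray
    D: np.ndarray

    @property
    def n_pairs(self) -> int:
        return len(self.M)


def replace_zeros(values: pd.DataFrame) -> pd.DataFrame:
    """Replace every zero by 0.5 x the smallest positive value of the matrix."""
    arr = values.to_numpy(dtype=float)
    positive = arr[arr > 0]
    if positive.size == 0:
        raise ValueError("matrix is entirely zero")
    k = 0.5 * positive.min()
    out = values.copy()
    out[out == 0] = k
    return out


def compute_md(x_a, x_b) -> tuple:
    """M = |log2(x_a / x_b)|, D = |x_a - x_b|; inputs must be positive.

    Accepts scalars or aligned arrays.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if (x_a <= 0).any() or (x_b <= 0).any():
        raise ValueError("compute_md needs positive inputs (run replace_zeros first)")
    m = np.abs(np.log2(x_a / x_b))
    d = np.abs(x_a - x_b)
    if m.ndim == 0:
        return float(m), float(d)
    return m, d


def build_noise(values: pd.DataFrame, design: pd.DataFrame) -> NoiseDistribution:
    """Pool (M, D) over all unordered within-condition replicate pairs and genes.

    ``values`` must already be zero-replaced.
    """
    ms, ds = [], []
    for cond in dict.fromkeys(design["condition"]):
        samples = list(design.index[design["condition"] == cond])
        for i in range(len(samples)):
            for j in range(i + 1, len(samples)):
                m, d = compute_md(values[samples[i]].to_numpy(),
                                  values[samples[j]].to_numpy())
                ms.append(m)
                ds.append(d)
    if not ms:
        raise ValueError("no condition has >= 2 replicates")
    return NoiseDistribution(M=np.concatenate(ms), D=np.concatenate(ds))


def de_probability(signal_m: np.ndarray, signal_d: np.ndarray,
                   noise: NoiseDistribution, chunk: int = 256) -> np.ndarray:
    """Fraction of noise pairs strictly dominated by each signal pair.

    probability(g) = #{(M*, D*) in noise : M(g) > M* and D(g) > D*} / n_pairs.
    Strict dominance makes the probability of a (0, 0) signal exactly 0.
    Vectorized in blocks of genes to bound memory.
    """
    if noise.n_pairs == 0:
        raise ValueError("empty noise distribution")
    signal_m = np.atleast_1d(np.asarray(signal_m, dtype=float))
    signal_d = np.atleast_1d(np.asarray(signal_d, dtype=float))
    out = np.empty(len(signal_m))
    for start in range(0, len(signal_m), chunk):
        sm = signal_m[start:start + chunk, None]
        sd = signal_d[start:start + chunk, None]
        dominated = (sm > noise.M[None, :]) & (sd > noise.D[None, :])
        out[start:start + chunk] = dominated.sum(axis=1) / noise.n_pairs
    return out


def noise_odds_test(experiment: CountExperiment, normalization: str = "rpkm",
                    threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Run the full noise-odds pipeline on a two-condition experiment.

    Pipeline: normalize -> drop genes with zero counts in every sample ->
    replace zeros -> per-condition replicate means -> per-gene (M, D)
    signal -> within-condition noise distribution -> dominance probability.

    Returns a per-tested-gene DataFrame with columns ``mean_A``,
    ``mean_B``, ``M``, ``D``, ``probability`` and ``called``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    cond_a, cond_b, samples_a, samples_b = experiment.condition_split()
    if len(samples_a) < 2 and len(samples_b) < 2:
        raise ValueError("noise-odds test needs >= 2 replicates in a condition")

    norm = normalize(experiment.counts, normalization, experiment.lengths)
    expressed = experiment.counts.sum(axis=1) > 0
    values = norm.values.loc[expressed]
    values = replace_zeros(values)

    mean_a = values[samples_a].mean(axis=1)
    mean_b = values[samples_b].mean(axis=1)
    m, d = compute_md(mean_a.to_numpy(), mean_b.to_numpy())
    noise = build_noise(values, experiment.design)
    prob = de_probability(m, d, noise)

    return pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "M": m,
            "D": d,
            "probability": prob,
            "called": prob > threshold,
        },
        index=values.index,
    )
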