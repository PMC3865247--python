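"""Expression normalizations: RPKM, upper-quartile, and size factors.

RPKM and upper-quartile scaling feed the noise-odds differential
expression engine; median-of-ratios size factors feed the negative
binomial exact test. All three keep the gene x sample shape of the input
counts, preserve zeros exactly, and record the per-sample scale they
applied so the transformation can be inverted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class NormalizedMatrix:
    """Normalized expression values plus the scaling that produced them."""

    values: pd.DataFrame
    method: str  # one of {"rpkm", "uq", "sizefactor"}
    scale_metadata: pd.Series  # per-sample denominator / factor


def rpkm_normalize(counts: pd.DataFrame, lengths_bp: pd.Series) -> NormalizedMatrix:
    """Reads per kilobase of gene model per million assigned reads.

    value(g, j) = 1e9 * count(g, j) / (length_bp(g) * total(j)), with
    total(j) the sample's assigned read count (its column sum).
    """
    lengths_bp = lengths_bp.reindex(counts.index)
    if lengths_bp.isna().any() or (lengths_bp <= 0).any():
        raise ValueError("every gene needs a positive length")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero samples cannot be RPKM-normalized: {bad}")
    values = counts.div(totals, axis=1).div(lengths_bp, axis=0) * 1e9
    return NormalizedMatrix(values=values, method="rpkm", scale_metadata=totals.astype(float))


UQ_SCALE = 1_000.0


def uq_normalize(counts: pd.DataFrame, rescale: str = "fixed") -> NormalizedMatrix:
    """Upper-quartile normalization on nonzero counts.

    The per-sample denominator is the 75th percentile (linear
    interpolation) of that sample's nonzero counts. With
    ``rescale="fixed"`` (default) values are count/denominator * 1000:
    a ratio of two depth-proportional quantities times a constant, so
    the unit is stationary across sequencing depths and expression
    differences (D) can be compared between titration rungs. With
    ``rescale="mean"`` values are instead rescaled by the mean
    denominator across samples, which keeps magnitudes count-like at the
    matrix's own depth (two identical samples come back unchanged) but
    grows linearly with depth. Differential expression calls are
    identical under the two variants: the noise-odds probability is
    invariant to any common scale factor.
    """
    denoms = {}
    for sample in counts.columns:
        col = counts[sample].to_numpy()
        nonzero = col[col > 0]
        if nonzero.size == 0:
            raise ValueError(f"sample {sample!r} has no nonzero counts")
        denoms[sample] = float(np.percentile(nonzero, 75))
    denoms = pd.Series(denoms)
    if rescale == "fixed":
        scale = UQ_SCALE
    elif rescale == "mean":
        scale = denoms.mean()
    else:
        raise ValueError(f"unknown rescale mode {rescale!r}")
    values = counts.div(denoms, axis=1) * scale
    return NormalizedMatrix(values=values, method="uq", scale_metadata=denoms)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors.

    For genes with positive counts in every sample, the per-sample factor
    is the median of count(g, j) / geometric-mean-over-samples(count(g, .)).
    """
    arr = counts.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no gene has positive counts in all samples")
    sub = arr[all_positive]
    geomean = np.exp(np.log(sub).mean(axis=1))
    factors = np.median(sub / geomean[:, None], axis=0)
    return pd.Series(factors, index=counts.columns)


def sizefactor_normalize(counts: pd.DataFrame) -> NormalizedMatrix:
    """Counts divided by their median-of-ratios size factors."""
    s = size_factors(counts)
    return NormalizedMatrix(values=counts.div(s, axis=1), method="sizefactor",
                            scale_metadata=s)


def normalize(counts: pd.DataFrame, method: str,
              lengths_bp: pd.Series | None = None) -> NormalizedMatrix:
    """Dispatch on method name: 'rpkm' (needs lengths), 'uq', or 'sizefactor'."""
    if method == "rpkm":
        if lengths_bp is None:
            raise ValueError("rpkm normalization needs gene lengths")
        return rpkm_normalize(counts, lengths_bp)
    if method == "uq":
        return uq_normalize(counts)
    if method == "sizefactor":
        return sizefactor_normalize(counts)
    raise ValueError(f"unknown normalization method {method!r}")
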