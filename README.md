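# shallowseq

How much biology can *shallow* RNA-seq see? `shallowseq` benchmarks
replicated two-condition RNA-seq differential expression (DE) as a
function of sequencing depth. It subsamples a count matrix to a ladder
of exact read depths (1, 3, 6 and 12 million reads per replicate by
default), calls DE at every rung with two internally implemented
statistical engines, and measures how the number of DE genes (DEGs),
their effect magnitudes, the recovery of a benchmark marker-gene set,
and the detectability of weakly expressed genes (a transcription-factor-
like class) change with depth. A synthetic-data generator with a known
truth table makes every stage testable end to end.

The motivating use case is glandular/tissue-comparison bulk RNA-seq of
the kind done in insect systems (e.g. honey-bee sting gland vs digestive
tract): a few dominant transcripts, a handful of experimentally
verified, strongly differential marker genes, and a regulatory gene
class expressed far below the transcriptome-wide mean.

## The statistics inside

**Noise-odds test (NOISeq-style).** For each gene, the signal is the pair

- M = |log2( x̄_A / x̄_B )| — absolute log2 fold difference,
- D = |x̄_A − x̄_B| — absolute raw difference,

computed from replicate-averaged normalized expression (RPKM or
upper-quartile; zeros replaced by half the smallest positive value). The
null ("noise") distribution pools the same (M, D) pairs computed between
replicate samples of the *same* condition, across all genes and both
conditions. The DE probability of a gene is the fraction of noise pairs
its signal strictly dominates in both coordinates,

p(g) = #{(M*, D*) ∈ noise : M_g > M* and D_g > D*} / |noise|,

and a gene is called at p > 0.8.

**Negative-binomial exact test (DESeq-style).** Per-sample size factors
come from the median-of-ratios method; per-gene dispersions from a
method-of-moments estimate with a parametric mean–dispersion trend
α(q) = a₁/q + a₀ shared across genes. Each gene's condition count
totals K_A, K_B are modelled as negative binomials (mean q·s, variance
q·s + α·q²·Σs_j²) and the two-sided exact p value sums the
probabilities of all splits of K_A + K_B no more likely than the
observed one. Benjamini–Hochberg adjustment is applied and genes are
called at adjusted p < 0.05.

**Subsampling.** Target depths are hit *exactly* by drawing reads
without replacement (multivariate hypergeometric over genes), mirroring
drawing a shallow run out of a deeper sequenced library.

## Worked example

```python
import shallowseq as ss

cfg = ss.SimConfig(seed=1)                       # 10,000 genes, 2x2, 12 M reads
exp, truth = ss.simulate_experiment(cfg)
focal = ss.GeneSet("focal", truth.index[truth.gene_class == "focal"])

rungs = ss.titrate(exp, ss.DepthLadder(seed=2))  # 1 / 3 / 6 / 12 M
for depth, sub in rungs.items():
    res = ss.noise_odds_test(sub, "rpkm")        # p > 0.8 calls
    n_deg, mean_m, mean_d = ss.deg_effect_summary(res)
    rec = ss.recovery_count(res, focal)
    print(f"{depth//10**6:>2} M: {n_deg:3d} DEGs  mean M {mean_m:.2f}  "
          f"mean D {mean_d:6.1f}  focal {rec}/11")
```

prints

```
 1 M: 151 DEGs  mean M 2.26  mean D  337.7  focal 11/11
 3 M: 218 DEGs  mean M 1.96  mean D  257.3  focal 11/11
 6 M: 261 DEGs  mean M 1.82  mean D  225.9  focal 11/11
12 M: 298 DEGs  mean M 1.71  mean D  209.3  focal 11/11
```

The pattern is the point: the DEG count keeps rising with depth (the
titration has not saturated at 12 M reads), the average effect size of
what is found *falls* with depth (deeper sequencing adds subtler genes),
and the planted high-expression, high-fold-change marker set is already
fully recovered at 1 M reads — shallow sequencing finds the strong,
functionally central genes first.

The same study runs from the shell:

```sh
shallowseq run --config config.yaml --seed 1
shallowseq simulate --seed 1 --out sim/
shallowseq detest --counts sim/counts.tsv --lengths sim/lengths.tsv \
    --design sim/design.tsv --method nbexact --out de.tsv
```

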