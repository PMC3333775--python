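# omicsets

Gene-set level integration of multi-platform genomic data.

Modern cancer studies measure several genomic data types — expression,
copy number, methylation — on the same tumors. Genes in a disease pathway
are often altered through *different* mechanisms in different patients: one
gene amplified, another over-expressed, a third mutated. Analyzing each
data type separately misses such pathways; `omicsets` is a toolkit for
statisticians and computational biologists who want to find them by
integrating all data types at the gene set level.

## The method

The analysis runs in two stages over D gene-by-sample matrices
X¹, …, X^D and a phenotype Y (binary class or survival), cross-referenced
to a gene set membership matrix M.

**Stage I — gene scores.** For each gene g, a logistic regression of the
phenotype on the gene's measurements gives a deviance-difference score.
The *integrative* score uses all platforms that measured the gene jointly:

    logit E(Y_i | X) = β₀ + Σ_d X_gi^d β_gd,
    s_g = D(null) − D(full)        (≈ χ² with one df per platform, under H₀)

Single-platform scores s_g^d use one predictor at a time. For survival
phenotypes the Cox partial-likelihood ratio replaces the deviance.

**Stage II — set tests.** Gene sets are tested on the score vector either
*competitively* (one-sided Mann-Whitney of in-set scores against the rest
of the annotated genes — requires the intersection universe of genes
measured on all platforms) or in a *self-contained* way (permutation-
averaged Wilcoxon signed rank against B = 500 phenotype-label shuffles —
valid on the union universe). Alternatively, per-platform set P-values are
combined meta-analytically: geometric mean (**AvgP**) or minimum
(**MinP**).

A spike-in simulation suite benchmarks all of these: sets are planted into
a null backbone with signal strength β (the power of a two-sample t-test
at the injected shift) and expected altered-gene fraction γ, independently
per platform, and methods are ranked by ROC/AUC, top-k discoveries and
exclusive-discovery fractions.

## Worked example

Simulate a 4-platform study of 2,000 genes on 99 samples, plant signal
into 10 of 40 disjoint sets (β = 0.5, γ = 0.3), and rank sets with the
integrative score and the competitive test:

```python
from omicsets import (
    BackboneConfig, SpikeInConfig, generate_backbone, synthetic_collection,
    spike_in, score_all_genes, competitive_all, truth_labels,
)

study = generate_backbone(BackboneConfig(n_genes=2000, seed=7))
collection = synthetic_collection(sorted(study.availability), n_sets=40, seed=8)
study, truth = spike_in(study, collection, SpikeInConfig(beta=0.5, gamma=0.3), seed=9)

scores = score_all_genes(study, universe="intersection")
print(scores.frame.head(3).round(3))
```

```
         s_E1   s_E2   s_C1    s_C2   s_INT  n_platforms  flagged
gene
g00000  1.468  0.326  1.279   0.286   3.406            4    False
g00001  2.870  0.305  0.121  20.815  25.096            4    False
g00002  0.009  2.803  0.037   0.690   3.571            4    False
```

Each row is one gene: four single-platform deviance scores, the
integrative score from the joint four-predictor fit (always at least as
large as each single score), and fit diagnostics. Gene `g00001` carries a
strong copy-number signal (s_C2 ≈ 20.8) that dominates its integrative
score.

```python
results = competitive_all(scores, collection, method="INT")
top = results.sort_values("p").head(5)
top["spiked"] = truth_labels(collection, truth).reindex(top.set_id).to_numpy()
print(top.to_string(index=False))
```

```
set_id method  n_genes  statistic        p  spiked
 set05    INT       74   9.54e+04 3.56e-07    True
 set29    INT       41   5.82e+04 3.96e-07    True
 set10    INT       30   4.42e+04  1.6e-06    True
 set14    INT       16   2.61e+04 4.01e-06    True
 set32    INT       17   2.71e+04 7.59e-06    True
```

All five top-ranked sets are genuinely spiked; 9 of the 10 planted sets
appear in the integrative top ten. The `statistic` column is the
Mann-Whitney U of in-set versus out-of-set gene scores and `p` its
one-sided tail probability.

The same pipeline is scriptable from the shell: `omicsets synth`,
`score`, `gsa`, `meta`, `simulate` (YAML-configured benchmark) and
`evaluate` — every run writes a JSON manifest with seeds and input hashes.

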