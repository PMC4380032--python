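# m3dtest

A kernel-based two-sample test for **differentially methylated regions
(DMRs)** in reduced-representation bisulfite sequencing (RRBS) data. Instead
of testing cytosines one at a time and stitching the results together, the
test compares the whole methylation *profile* of a region between two groups
of replicates, so spatially correlated changes — shifts, shape changes,
localized bumps — are detected even when no single CpG changes dramatically.

It is aimed at analysts with per-CpG methylated/unmethylated read counts
(bismark coverage files or ENCODE-style RRBS BED) for a two-group comparison
with replicates, typically at low replication (2 vs 2).

## The statistic

A sample's observations over a region are its individual reads
x\_i = (C\_i, Meth\_i): the CpG position and the methylation call. Two
samples X (m reads) and Y (n reads) are compared with the biased sample
estimate of the maximum mean discrepancy,

```
MMD[X, Y; k] = sqrt( K_xx / m^2  -  2 K_xy / (m n)  +  K_yy / n^2 ),
```

where K_xy = Σ_ij k(x_i, y_j), under the composite kernel

```
k_full(x_i, x_j) = exp( -(C_i - C_j)^2 / 2σ^2 ) · 1[Meth_i = Meth_j],
```

an RBF kernel on position times a 0/1 string kernel on the call. The
bandwidth σ is set per region by the median heuristic, σ² = x̄²/2 with x̄
the median pairwise read distance pooled over all samples. Computing the
same MMD with the position-only kernel measures how different the two
*coverage* profiles are; the test statistic

```
M3D = MMD_full − MMD_coverage
```

cancels that coverage confounder and responds only to methylation-profile
changes. All sums are evaluated from per-site counts (never by expanding
reads), which makes the cost O(sites²) per pair instead of O(reads²).

Inference is data-driven: the null distribution is the pool of M3D values
of all within-group (replicate) pairs over all regions; a region's score
μ\_r is the mean M3D over its between-group pairs, its p-value the
probability of a null value ≥ μ\_r (optionally from an exponential fit to
the null's top-5% tail), and Benjamini–Hochberg at 1% FDR makes the calls.

## Worked example

A fully synthetic benchmark: 1000 CpG-cluster regions, 2+2 replicates with
RRBS-like coverage, 250 regions altered in the test group by a
full-strength (α = 1) methylation shift:

```python
from m3dtest import GeneratorConfig, make_benchmark, confusion, roc_tpr_vs_fdr
from m3dtest.testing import test_regions

cfg = GeneratorConfig(seed=1)          # 1000 regions, 2+2 replicates
exp, regions, truth = make_benchmark(cfg, alpha=1.0, n_altered=250)
out = test_regions(exp, regions, mode="empirical", fdr_level=0.01)
print(f"null size: {out.null.n}, q95: {out.null.q95:.4f}")
print(f"called: {out.n_called}, t_fdr: {out.t_fdr:.4f}")
c = confusion(out.results, truth)
print(f"correct: {c.correct}, type1: {c.type1}, type2: {c.type2}")
print(f"AUC (empirical p): {roc_tpr_vs_fdr(out.results, truth).auc:.3f}")
```

prints

```
null size: 2000, q95: 0.0329
called: 243, t_fdr: 0.0673
correct: 243, type1: 0, type2: 7
AUC (empirical p): 0.995
```

The 2000 replicate-pair M3D values form the null; its 95th percentile is
0.033, so replicate disagreement is tiny. 243 of the 250 truly altered
regions are called at 1% FDR with **zero** false calls; the implied calling
threshold on μ\_r is t\_fdr = 0.067. Sweeping the nominal FDR level over
[0, 1] gives a true-positive-rate curve with area 0.995.

The same pipeline is available from the shell:

```
m3d simulate --out-dir sim --seed 7 --alpha 1.0
m3d test --manifest sim/manifest.tsv --regions sim/regions.bed --out results.tsv
m3d evaluate --results results.tsv --truth sim/truth.tsv --out-dir eval
```

`m3d cluster` builds dense-CpG testing regions from real coverage files.

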