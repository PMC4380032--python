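# Methods

## Model and test

The unit of testing is a pre-defined genomic region containing CpG sites;
each bisulfite sample contributes a multiset of reads x = (position,
methylation call) over the region. Two samples are compared with the biased
(V-statistic) estimate of the maximum mean discrepancy (MMD) in the RKHS of
a composite kernel: a Gaussian RBF on genomic position multiplied by a 0/1
string kernel on the methylation call. The double sums run over all index
pairs including the diagonal, so the estimator is exactly zero for
identical samples. The position-only (methylation-blind) MMD of the same
two samples measures how far apart their *coverage* profiles are; the test
statistic is

    m3d = MMD_full − MMD_coverage.

In the large-sample limit the blind MMD is the MMD of the data projected on
a methylation-blind subspace, so the difference is non-negative; in finite
samples it can be slightly negative and is deliberately not floored — the
empirical null absorbs those values, and flooring would bias the null
upward.

All gram sums are computed from per-site counts: a site with m methylated
and u unmethylated reads enters the methylated component with weight m and
the unmethylated one with weight u, which reproduces the per-read double
sum exactly (the test suite keeps the read-expansion form as an oracle).
Cost is O(sites²) per region plus O(sites) per sample pair, so a
1000-region, 4-sample experiment tests in well under a minute.

### Bandwidth

The RBF bandwidth is set per region and shared by every sample pair in
that region: σ² = x̄²/2, where x̄ is the median of all pairwise absolute
distances between reads pooled over all samples, each site counting with
multiplicity equal to its pooled coverage (zero distances between reads at
the same site included). The weighted median reproduces `np.median` of the
fully expanded distance list, interpolating between the two central order
statistics when the pair count is even. Degenerate cases: if the weighted
median is zero, the median over distances between distinct site positions
is used; a single-site region gets σ = 1 bp. An unweighted
(distinct-site-distance) variant is available behind a switch
(`weighted_median=False`); sharing σ across pairs keeps the within- and
between-group statistics of a region on the same scale, which the null
construction relies on.

### Null distribution and p-values

The null is the pool of m3d values from **all within-group sample pairs
over all testing regions** — inter-replicate variability measured on the
same footing as the between-group comparison. A region's score μ_r is the
arithmetic mean of m3d over its between-group pairs. The empirical p-value
is (1 + #{null ≥ μ_r}) / (1 + N): add-one smoothing keeps p strictly
positive so Benjamini–Hochberg is well defined, and ties count toward the
tail. Consequently the smallest attainable p is 1/(N+1); with 2+2
replicates and R regions, N = 2R.

The model-based alternative fits an exponential to the null tail:
q95 is the 95th percentile (linear interpolation between order statistics),
and the rate is the closed-form peaks-over-threshold estimate
1/mean(excess above q95). For μ_r ≥ q95, p = 0.05·exp(−rate·(μ_r − q95)),
which equals 0.05 exactly at the threshold; below the threshold the
empirical p-value is used, so the two modes coincide there by construction.
(The branch is taken at μ_r = q95 rather than above it so the printed
boundary value holds exactly.) A degenerate tail (no strictly positive
excess) falls back to the empirical p-value with a logged warning. The
model mode exists because the empirical p saturates at 1/(N+1): in large
studies the exponential tail discriminates among the extreme regions and
slightly improves the ranking.

Calls are made with Benjamini–Hochberg step-up q-values
(statsmodels' `fdr_bh`) at a default 1% FDR; the implied calling threshold
t_fdr — the smallest called μ_r — is reported. Negative null values are
retained (they only add conservatism). Note an interaction worth knowing:
BH at level f with R regions needs p ≤ f·k/R for some rank k, so with the
empirical floor 1/(2R+1) the test can call nothing at stringent levels in
*small* experiments (few regions ⇒ few null values) even under perfect
separation; the model-based p-values do not have this floor.

## Region construction

Dense-CpG clusters follow the standard RRBS clustering recipe: a site is
"frequently covered" if it has coverage ≥ `min_site_cov` (default 1) in at
least `min_sample_frac` (default 0.75) of samples; frequently covered
sites are grouped greedily left-to-right, breaking when the gap to the next
site *strictly exceeds* `max_gap` (default 100 bp, so a gap equal to the
threshold does not break); clusters with fewer than `min_sites` (default
10) sites are dropped. User-supplied BED regions bypass clustering but pass
the same exclusion filters: fewer than `min_sites` member CpGs, or (when
enabled) no covered site in at least one sample. Coordinates are 0-based
half-open internally; bismark coverage input is 1-based and shifted on
read. Minus-strand CpG cytosines are merged into the forward-strand C at
p − 1 by summing counts, without consulting a reference genome.

## Synthetic benchmark generator

The generator emulates an RRBS experiment over CpG clusters; its defaults
define the benchmark conditions:

| parameter | default | meaning |
|---|---|---|
| n_regions | 1000 | CpG-cluster regions on one synthetic chromosome |
| sites per region | Uniform{10..40} | member CpGs |
| spacing | 2 + Geometric(mean 23) bp | neighbour CpG distance (mean 25 bp) |
| coverage_mean / dispersion | 34.5 / 0.9 | marginal NB reads per site; calibrated so the mean is ~34.5 and the median 23 |
| base methylation | 0.6·Beta(0.5, 8) + 0.4·Beta(8, 0.5) | bimodal per-site levels, as in real CpG data |
| replicate_precision | 100 | Beta concentration of per-replicate jitter around the per-site truth (sd ≈ 0.05 at mid-level) |
| replicates | 2 + 2 | the low-replication regime the test targets |

Coverage is drawn hierarchically: a per-site Gamma(r, mean/r) intensity
**shared by all samples**, then per-replicate Poisson counts (clipped below
at 1 read: uncovered sites carry no data). The mixture makes the marginal
coverage exactly negative binomial at the calibrated mean/dispersion while
inducing the strong cross-replicate coverage correlation (~0.97) that real
RRBS shows, because coverage is driven by the same restriction fragments in
every library. This correlation matters: it is what makes the full and
coverage MMDs of replicate pairs agree, concentrating the null near zero.
With independent per-replicate coverage the null tail widens by an order of
magnitude and the benchmark becomes unrealistically hard.

Methylated counts are Binomial(coverage, level) with per-replicate levels
Beta(κL, κ(1−L)) around the per-site truth L. Both groups draw from the
same truth, so the unaltered benchmark is exchangeable under the null.

Alterations are injected into one group only (the "testing group"):

* **Fixed shift** of strength α ∈ [0, 1] on a span: the span is grown from
  a random site until it is ≥ 100 bp long with pooled group coverage
  ≥ 100, then until it holds n ~ Uniform{4..20} sites (capped at the
  region; if the constraints are unsatisfiable the whole region is used
  and recorded as such). Per-site L_old is the pooled methylated fraction
  of the group; the span is hyper-methylated
  (L_new = (1−α)·L_old + α) when its mean level is below 50% and
  hypo-methylated (L_new = (1−α)·L_old) otherwise.
* **Gaussian bump**: L_new = clip(L_old + height·exp(−(pos−center)²/2w²)),
  with center uniform in the region, width uniform in 50–200 bp and height
  of random sign, magnitude uniform in 0.3–0.8. The replicate-simulation
  and bump-parameter recipes of the original study are not published in
  the available text; these ranges are the package's own stand-ins and are
  exercised but not tuned.

Injections resample methylation calls as Binomial(original coverage,
L_new); coverage is never modified, so the coverage MMD is a genuine
confounder control in the benchmark. All randomness flows through one
seeded generator; equal seeds give bit-identical experiments.

## Evaluation

Confusion counts split regions into correct (altered, called), type1
(unaltered, called), type2 (altered, missed) and true negatives. The ROC
sweeps the nominal BH FDR level over a 1001-point grid of [0, 1]; because
calls at level f are exactly {q ≤ f}, one adjustment pass serves the whole
sweep. TPR is integrated over the nominal axis by the trapezoid rule; the
realized false-discovery proportion per level is reported alongside for
diagnostics but does not enter the AUC. The AUC stabilizes once the grid is
finer than the number of distinct p-values.

## Problem sizes and determinism

The shipped benchmark uses the full 1000-region, 2+2-replicate layout;
a complete generate–test–score cycle takes about one second on one CPU, and
the headline quantities are averaged over three seeds. Region-parallel
execution (`n_jobs`/`--threads`) is a pure map over regions and cannot
change results. Every CLI run writes its resolved configuration next to its
outputs.

## Limitations

* The statistic measures the strength, not the direction, of a profile
  change; hyper vs hypo must be read off the profiles themselves.
* The empirical p-value resolution is bounded by the number of replicate
  pairs times regions; small studies should use the model-based mode and
  interpret stringent FDR levels cautiously.
* The generator emulates marginal coverage statistics, coverage
  correlation, bimodal levels and replicate jitter, but not fragment-level
  read structure, conversion errors, SNPs, or non-CpG contexts; passing
  benchmarks here demonstrates correctness of the method and realistic
  statistical behaviour, not performance on any particular real dataset.
* One bandwidth per region is shared across pairs; strongly heteroscedastic
  pairs within a region are not given individual scales.
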