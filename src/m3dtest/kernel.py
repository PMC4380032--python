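"""Kernel machinery: bandwidth heuristic, MMD estimator, M3D statistic.

The observations of a bisulfite sample over a region are its individual
mapped reads, each a pair (genomic position of the CpG, methylation call).
Two samples are compared with the biased (V-statistic) estimate of the
maximum mean discrepancy under a composite kernel: an RBF kernel on
position times a 0/1 string kernel on the methylation call. Computing the
same MMD with the position-only kernel measures how far apart the two
*coverage* profiles are; the M3D statistic is the difference

    m3d = MMD_full - MMD_coverage,

which cancels the coverage confounder and responds only to changes in the
methylation profile.

Everything is computed from per-site counts: a site with m methylated and
u unmethylated reads contributes with weight m to the methylated component
and u to the unmethylated one, which reproduces the per-read double sums
exactly without ever expanding reads (coverage is ~35x in RRBS, so read
expansion would be quadratically wasteful). The read-expansion form is
kept in the test suite as an oracle.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import Experiment, SampleTable
from .regions import Region

PAIR_COLUMNS = [
    "region_id", "chrom", "start", "end", "sample_a", "sample_b",
    "pair_type", "sigma", "full_mmd", "cov_mmd", "m3d",
]


@dataclass(frozen=True)
class RegionSlice:
    """Counts of one sample restricted to one region's site positions."""

    positions: np.ndarray
    meth_counts: np.ndarray
    unmeth_counts: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.positions) == len(self.meth_counts) == len(self.unmeth_counts)):
            raise ValueError("slice arrays must have equal length")
        if (self.meth_counts < 0).any() or (self.unmeth_counts < 0).any():
            raise ValueError("negative counts in region slice")

    @property
    def coverage(self) -> np.ndarray:
        return self.meth_counts + self.unmeth_counts

    @property
    def total_reads(self) -> int:
        return int(self.coverage.sum())


def region_slice(sample: SampleTable, region: Region) -> RegionSlice:
    """Slice one sample's counts to a region's member positions (0-filled)."""
    pos = np.asarray(region.site_positions, dtype=np.int64)
    m, u = sample.counts_at(region.chrom, pos)
    return RegionSlice(pos, m, u)


def median_heuristic_sigma(slices: Sequence[RegionSlice], weighted: bool = True) -> float:
    """RBF bandwidth for a region from the median pairwise read distance.

    Pools the reads of all given samples; each site contributes with
    multiplicity equal to its pooled coverage. The median x̄ of all
    pairwise absolute distances between reads (zero distances between
    reads at the same site included) sets the bandwidth through
    sigma^2 = x̄^2 / 2.

    Degenerate cases: if the weighted median is 0 (reads piled on few
    sites), fall back to the unweighted median over distances between
    distinct site positions; a single-site region gets sigma = 1 bp.
    With ``weighted=False`` the distinct-site median is used directly.
    """
    if not slices:
        raise ValueError("no slices given")
    pos = np.asarray(slices[0].positions, dtype=np.float64)
    if any(len(s.positions) != len(pos) for s in slices):
        raise ValueError("slices must share the region's position vector")
    w = np.zeros(len(pos), dtype=np.int64)
    for s in slices:
        w += s.coverage
    if w.sum() == 0:
        raise ValueError("region has no observations in any sample")
    if len(pos) == 1:
        return 1.0
    xbar = None
    if weighted:
        xbar = _weighted_pairwise_median(pos, w)
    if xbar is None or xbar == 0.0:
        d = np.abs(pos[:, None] - pos[None, :])
        xbar = float(np.median(d[np.triu_indices(len(pos), k=1)]))
    if xbar == 0.0:
        return 1.0
    return math.sqrt(xbar * xbar / 2.0)


def _weighted_pairwise_median(pos: np.ndarray, w: np.ndarray) -> float | None:
    """Median of |p_i - p_j| over all unordered read pairs, by multiplicity.

    Equivalent to ``np.median`` of the fully expanded distance list:
    site pair (i, j), i < j, appears w_i * w_j times; a same-site pair
    contributes C(w_i, 2) zero distances.
    """
    keep = w > 0
    pos, w = pos[keep], w[keep].astype(np.float64)
    W = w.sum()
    n_pairs = W * (W - 1) / 2.0
    if n_pairs < 1:
        return None
    i, j = np.triu_indices(len(pos), k=1)
    dist = np.abs(pos[i] - pos[j])
    mult = w[i] * w[j]
    zero_mult = (w * (w - 1) / 2.0).sum()
    dists = np.concatenate(([0.0], dist))
    mults = np.concatenate(([zero_mult], mult))
    order = np.argsort(dists, kind="mergesort")
    dists, mults = dists[order], mults[order]
    csum = np.cumsum(mults)
    n = int(round(n_pairs))
    # expanded sorted list: element k (0-based) is the first d with csum > k
    lo = float(dists[np.searchsorted(csum, (n - 1) // 2, side="right")])
    hi = float(dists[np.searchsorted(csum, n // 2, side="right")])
    return (lo + hi) / 2.0


def weighted_rbf_gram_sum(
    pos_a: np.ndarray, w_a: np.ndarray,
    pos_b: np.ndarray, w_b: np.ndarray,
    sigma: float,
) -> float:
    """Sum_{s,t} w_a[s] w_b[t] exp(-(pos_a[s]-pos_b[t])^2 / (2 sigma^2)).

    With integer read counts as weights this equals the per-read double
    sum of the RBF kernel over the expanded observation lists, diagonal
    terms included.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    pos_a = np.asarray(pos_a, dtype=np.float64)
    pos_b = np.asarray(pos_b, dtype=np.float64)
    w_a = np.asarray(w_a, dtype=np.float64)
    w_b = np.asarray(w_b, dtype=np.float64)
    d = pos_a[:, None] - pos_b[None, :]
    g = np.exp(-(d * d) / (2.0 * sigma * sigma))
    return float(w_a @ g @ w_b)


def mmd_biased(
    slice_x: RegionSlice, slice_y: RegionSlice, sigma: float,
    methylation_aware: bool = True,
) -> float:
    """Biased (V-statistic) MMD between two samples over a region.

    With the composite kernel (``methylation_aware=True``) the cross term
    decomposes over counts as

        Kxy = sum_{s,t} k_RBF(p_s, p_t) (m_s m_t + u_s u_t),

    because the string kernel is 1 only between reads with equal
    methylation call. With ``methylation_aware=False`` the position-only
    kernel is used with total coverages as weights (the coverage MMD).
    Sums include the diagonal; identical samples give exactly 0.
    """
    m = slice_x.total_reads
    n = slice_y.total_reads
    if m == 0 or n == 0:
        raise ValueError("cannot compute MMD for a sample with no reads in the region")
    px, py = slice_x.positions, slice_y.positions
    if methylation_aware:
        kxx = (
            weighted_rbf_gram_sum(px, slice_x.meth_counts, px, slice_x.meth_counts, sigma)
            + weighted_rbf_gram_sum(px, slice_x.unmeth_counts, px, slice_x.unmeth_counts, sigma)
        )
        kxy = (
            weighted_rbf_gram_sum(px, slice_x.meth_counts, py, slice_y.meth_counts, sigma)
            + weighted_rbf_gram_sum(px, slice_x.unmeth_counts, py, slice_y.unmeth_counts, sigma)
        )
        kyy = (
            weighted_rbf_gram_sum(py, slice_y.meth_counts, py, slice_y.meth_counts, sigma)
            + weighted_rbf_gram_sum(py, slice_y.unmeth_counts, py, slice_y.unmeth_counts, sigma)
        )
    else:
        cx, cy = slice_x.coverage, slice_y.coverage
        kxx = weighted_rbf_gram_sum(px, cx, px, cx, sigma)
        kxy = weighted_rbf_gram_sum(px, cx, py, cy, sigma)
        kyy = weighted_rbf_gram_sum(py, cy, py, cy, sigma)
    mmd2 = kxx / (m * m) - 2.0 * kxy / (m * n) + kyy / (n * n)
    return math.sqrt(max(0.0, mmd2))


@dataclass(frozen=True)
class PairStatistics:
    """Full MMD, coverage MMD and their difference for one sample pair."""

    region_id: int
    sample_a: str
    sample_b: str
    full_mmd: float
    cov_mmd: float
    m3d: float


def m3d_statistic(slice_x: RegionSlice, slice_y: RegionSlice, sigma: float,
                  region_id: int = -1, sample_a: str = "x", sample_b: str = "y") -> PairStatistics:
    """Coverage-corrected methylation discrepancy for one sample pair.

    ``m3d = full_mmd - cov_mmd``; small negative values can occur in
    finite samples and are returned unmodified (the empirical null
    absorbs them).
    """
    full = mmd_biased(slice_x, slice_y, sigma, methylation_aware=True)
    cov = mmd_biased(slice_x, slice_y, sigma, methylation_aware=False)
    return PairStatistics(region_id, sample_a, sample_b, full, cov, full - cov)


def _region_pair_rows(exp: Experiment, region: Region, weighted_median: bool) -> list[tuple]:
    pos = np.asarray(region.site_positions, dtype=np.float64)
    n_sites = len(pos)
    meth = np.empty((len(exp.samples), n_sites))
    unmeth = np.empty((len(exp.samples), n_sites))
    for k, s in enumerate(exp.samples):
        m, u = s.counts_at(region.chrom, np.asarray(region.site_positions, dtype=np.int64))
        if int(m.sum() + u.sum()) == 0:
            raise ValueError(
                f"sample {s.sample_id!r} has no coverage in region {region.region_id}; "
                "filter regions first"
            )
        meth[k], unmeth[k] = m, u
    cov = meth + unmeth
    slices = [
        RegionSlice(pos, meth[k].astype(np.int64), unmeth[k].astype(np.int64))
        for k in range(len(exp.samples))
    ]
    sigma = median_heuristic_sigma(slices, weighted=weighted_median)

    d = pos[:, None] - pos[None, :]
    g = np.exp(-(d * d) / (2.0 * sigma * sigma))
    gm, gu, gc = meth @ g, unmeth @ g, cov @ g  # per-sample G-products
    reads = cov.sum(axis=1)

    rows = []
    for a in range(len(exp.samples)):
        for b in range(a + 1, len(exp.samples)):
            kxx_f = gm[a] @ meth[a] + gu[a] @ unmeth[a]
            kxy_f = gm[a] @ meth[b] + gu[a] @ unmeth[b]
            kyy_f = gm[b] @ meth[b] + gu[b] @ unmeth[b]
            kxx_c = gc[a] @ cov[a]
            kxy_c = gc[a] @ cov[b]
            kyy_c = gc[b] @ cov[b]
            m, n = reads[a], reads[b]
            full = math.sqrt(max(0.0, kxx_f / m**2 - 2 * kxy_f / (m * n) + kyy_f / n**2))
            covm = math.sqrt(max(0.0, kxx_c / m**2 - 2 * kxy_c / (m * n) + kyy_c / n**2))
            sa, sb = exp.samples[a], exp.samples[b]
            pair_type = "within" if sa.group == sb.group else "between"
            rows.append((
                region.region_id, region.chrom, region.start, region.end,
                sa.sample_id, sb.sample_id, pair_type, sigma, full, covm, full - covm,
            ))
    return rows


def all_pair_statistics(
    exp: Experiment,
    regions: Sequence[Region],
    weighted_median: bool = True,
    n_jobs: int = 1,
) -> pd.DataFrame:
    """M3D statistics for every region and every unordered sample pair.

    One bandwidth per region, shared by all pairs, from
    :func:`median_heuristic_sigma` over all samples pooled. Returns a
    frame with within- and between-group rows; results are deterministic
    and independent of ``n_jobs``.
    """
    if n_jobs > 1:
        with ThreadPoolExecutor(max_workers=n_jobs) as pool:
            chunks = list(pool.map(
                lambda r: _region_pair_rows(exp, r, weighted_median), regions
            ))
    else:
        chunks = [_region_pair_rows(exp, r, weighted_median) for r in regions]
    rows = [row for chunk in chunks for row in chunk]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)
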