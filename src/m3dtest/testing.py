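"""Region-level testing: empirical null, p-values, FDR and DMR calls.

The null distribution of the statistic is taken from the data itself: the
M3D values of all within-group (replicate) sample pairs pooled over all
testing regions. A region's score mu_r is the mean M3D over its
between-group pairs, and its p-value is the probability of seeing a null
value at least as large. A model-based alternative fits an exponential
tail to the null's top 5% exceedances so that extreme p-values do not
saturate at the empirical resolution. Benjamini-Hochberg converts either
p-value into q-values; regions with q <= fdr_level are called DMRs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data import Experiment
from .kernel import all_pair_statistics
from .regions import Region

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "region_id", "chrom", "start", "end", "n_sites", "sigma",
    "mu_r", "p_empirical", "p_model", "q_value", "called",
]

TAIL_FRACTION = 0.05  # upper tail used for the exponential fit


@dataclass
class NullDistribution:
    """Replicate-pair M3D pool with its 95th percentile and tail fit.

    ``tail_rate`` is the closed-form exponential rate fitted to the
    exceedances above ``q95`` (peaks-over-threshold): 1 / mean(excess).
    ``None`` when the tail is degenerate (no strictly positive excess);
    model p-values then fall back to the empirical ones.
    """

    values: np.ndarray
    q95: float = field(init=False)
    tail_rate: float | None = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size == 0:
            raise ValueError("null distribution is empty")
        self.q95 = float(np.percentile(self.values, 100 * (1 - TAIL_FRACTION)))
        excess = self.values[self.values > self.q95] - self.q95
        if excess.size and excess.mean() > 0:
            self.tail_rate = float(1.0 / excess.mean())
        else:
            self.tail_rate = None

    @property
    def n(self) -> int:
        return int(self.values.size)


def build_null(pairs: pd.DataFrame) -> NullDistribution:
    """Pool within-group M3D values over all regions into the null.

    Requires at least one within-group pair, i.e. replicates in at least
    one group; negative M3D values are retained (they only make the test
    more conservative).
    """
    within = pairs.loc[pairs["pair_type"] == "within", "m3d"]
    if within.empty:
        raise ValueError(
            "no within-group sample pairs: the empirical null needs at least "
            "one group with two or more replicates"
        )
    return NullDistribution(within.to_numpy())


def region_mu(pairs: pd.DataFrame, region_id: int) -> float:
    """Mean M3D over the between-group pairs of one region."""
    sub = pairs[(pairs["region_id"] == region_id) & (pairs["pair_type"] == "between")]
    if sub.empty:
        raise ValueError(f"region {region_id}: no between-group pairs")
    return float(sub["m3d"].mean())


def empirical_pvalue(mu: float, null: NullDistribution) -> float:
    """P(null >= mu) with add-one smoothing so that p > 0; ties count."""
    return (1.0 + int(np.sum(null.values >= mu))) / (1.0 + null.n)


def exponential_tail_pvalue(mu: float, null: NullDistribution) -> float:
    """Model-based p-value from the exponential fit to the null's tail.

    For mu >= q95 (the fitted regime) p = 0.05 * exp(-rate * (mu - q95)),
    which equals 0.05 exactly at the threshold; below the threshold, and
    whenever the tail fit is degenerate, the empirical p-value is used.
    Clamped to (0, 1].
    """
    if null.tail_rate is not None and mu >= null.q95:
        p = TAIL_FRACTION * math.exp(-null.tail_rate * (mu - null.q95))
        return min(1.0, max(p, 5e-324))
    if null.tail_rate is None and mu >= null.q95:
        logger.warning("degenerate null tail; falling back to empirical p-value")
    return empirical_pvalue(mu, null)


def bh_fdr(pvalues: Sequence[float], fdr_level: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and calls at ``fdr_level``."""
    pvalues = np.asarray(pvalues, dtype=np.float64)
    if pvalues.size == 0:
        return np.empty(0), np.empty(0, dtype=bool)
    if (pvalues <= 0).any() or (pvalues > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    _, qvals, _, _ = multipletests(pvalues, alpha=fdr_level, method="fdr_bh")
    return qvals, qvals <= fdr_level


@dataclass
class DMRTestOutcome:
    """Results of a two-group region test.

    ``results`` has one row per region (RESULT_COLUMNS); ``null`` is the
    replicate-pair null; ``t_fdr`` is the implied M3D threshold — the
    smallest mu_r among called regions (NaN when nothing is called).
    """

    results: pd.DataFrame
    null: NullDistribution
    pairs: pd.DataFrame

    @property
    def t_fdr(self) -> float:
        called = self.results.loc[self.results["called"], "mu_r"]
        return float(called.min()) if len(called) else float("nan")

    @property
    def n_called(self) -> int:
        return int(self.results["called"].sum())


def test_regions(
    exp: Experiment,
    regions: Sequence[Region],
    mode: str = "empirical",
    fdr_level: float = 0.01,
    weighted_median: bool = True,
    n_jobs: int = 1,
) -> DMRTestOutcome:
    """End-to-end two-group DMR test over pre-defined regions.

    Computes all pair statistics, builds the replicate null, scores each
    region by mu_r, converts to p-values (``mode`` selects ``empirical``
    or ``model``), adjusts with Benjamini-Hochberg and calls regions at
    ``fdr_level``. Deterministic given inputs.
    """
    if mode not in ("empirical", "model"):
        raise ValueError(f"mode must be 'empirical' or 'model', got {mode!r}")
    pairs = all_pair_statistics(exp, regions, weighted_median=weighted_median, n_jobs=n_jobs)
    null = build_null(pairs)

    between = pairs[pairs["pair_type"] == "between"]
    mu = between.groupby("region_id", sort=False)["m3d"].mean()
    region_info = {r.region_id: r for r in regions}
    rows = []
    for region in regions:
        if region.region_id not in mu.index:
            raise ValueError(f"region {region.region_id}: no between-group pairs")
    sigma_by_region = pairs.groupby("region_id", sort=False)["sigma"].first()
    p_emp = np.array([empirical_pvalue(m, null) for m in mu.to_numpy()])
    p_mod = np.array([exponential_tail_pvalue(m, null) for m in mu.to_numpy()])
    p_used = p_emp if mode == "empirical" else p_mod
    qvals, called = bh_fdr(p_used, fdr_level)
    for i, rid in enumerate(mu.index):
        r = region_info[rid]
        rows.append((
            rid, r.chrom, r.start, r.end, r.n_sites, sigma_by_region[rid],
            mu.iloc[i], p_emp[i], p_mod[i], qvals[i], bool(called[i]),
        ))
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    outcome = DMRTestOutcome(results=results, null=null, pairs=pairs)
    logger.info(
        "tested %d regions: null n=%d, q95=%.4g, t_fdr=%.4g, %d called at FDR %g",
        len(results), null.n, null.q95, outcome.t_fdr, outcome.n_called, fdr_level,
    )
    return outcome
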