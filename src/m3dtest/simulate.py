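"""Synthetic RRBS experiments with known, injectable methylation changes.

The generator emulates the statistics of an RRBS experiment on CpG-dense
clusters: regions of 10-40 CpG sites with ~25 bp spacing, per-site
coverage from a negative binomial calibrated to a mean of 34.5 and a
median of 23 reads per site, and bimodal per-site methylation levels
(most CpGs are either mostly unmethylated or mostly methylated).
Replicates jitter around the per-site truth with a Beta concentration
parameter, and read counts are binomial given coverage and level. Both
groups are drawn from the same truth, so the base experiment is
exchangeable under the null.

Two alteration mechanisms create ground-truth DMRs in one group (the
testing group) only:

* a fixed shift of strength alpha on a sub-span of the region, pushing
  levels toward 1 (hyper) when the span averages below 50% methylation
  and toward 0 (hypo) otherwise;
* a Gaussian bump added to the level profile, centred at a random
  position with a random width and signed height.

Coverage is never modified by either mechanism: only methylation calls
are resampled, which is exactly what makes the coverage-MMD correction
testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import Experiment, SampleTable
from .regions import Region

_LEVEL_EPS = 1e-6


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic RRBS generator.

    Coverage defaults are calibrated so that per-site per-sample coverage
    has mean ~34.5 and median ~23 reads (negative binomial, dispersion
    0.9, clipped below at 1 read).
    """

    n_regions: int = 1000
    min_sites_per_region: int = 10
    max_sites_per_region: int = 40
    mean_spacing: float = 25.0          # bp between neighbouring CpGs (>= 2)
    coverage_mean: float = 34.5         # reads per site
    coverage_dispersion: float = 0.9    # NB size parameter; smaller = more skew
    low_frac: float = 0.6               # fraction of sites in the low-methylation mode
    low_beta: tuple[float, float] = (0.5, 8.0)
    high_beta: tuple[float, float] = (8.0, 0.5)
    replicate_precision: float = 100.0  # Beta concentration of replicate jitter
    n_replicates_per_group: int = 2
    group_labels: tuple[str, str] = ("control", "test")
    chrom: str = "chrSim"
    region_gap: float = 1000.0          # mean bp between consecutive regions
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if not 1 <= self.min_sites_per_region <= self.max_sites_per_region:
            raise ValueError("invalid sites_per_region bounds")
        if self.mean_spacing < 2:
            raise ValueError("mean_spacing must be >= 2 bp (CpG geometry)")
        for name in ("coverage_mean", "coverage_dispersion", "replicate_precision", "region_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 <= self.low_frac <= 1:
            raise ValueError("low_frac must lie in [0, 1]")
        for pair in (self.low_beta, self.high_beta):
            if pair[0] <= 0 or pair[1] <= 0:
                raise ValueError("Beta parameters must be strictly positive")
        if self.n_replicates_per_group < 1:
            raise ValueError("n_replicates_per_group must be >= 1")
        if self.group_labels[0] == self.group_labels[1]:
            raise ValueError("group labels must differ")


@dataclass(frozen=True)
class GroundTruthEntry:
    """How one region was altered."""

    region_id: int
    mechanism: str                       # "shift" | "bump"
    direction: str                       # "hyper" | "hypo"
    affected_positions: tuple[int, ...]
    alpha: float | None = None
    center: float | None = None
    width: float | None = None
    height: float | None = None
    whole_region: bool = False


@dataclass
class GroundTruth:
    """Which regions were altered, by which mechanism and strength."""

    entries: dict[int, GroundTruthEntry] = field(default_factory=dict)

    @property
    def altered_region_ids(self) -> set[int]:
        return set(self.entries)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                e.region_id, e.mechanism, e.direction,
                "" if e.alpha is None else e.alpha,
                "" if e.center is None else e.center,
                "" if e.width is None else e.width,
                "" if e.height is None else e.height,
                int(e.whole_region),
                ",".join(str(p) for p in e.affected_positions),
            )
            for e in self.entries.values()
        ]
        return pd.DataFrame(rows, columns=[
            "region_id", "mechanism", "direction", "alpha",
            "center", "width", "height", "whole_region", "affected_positions",
        ])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GroundTruth":
        truth = cls()
        for row in frame.itertuples(index=False):
            pos = tuple(int(p) for p in str(row.affected_positions).split(",") if p != "")
            truth.entries[int(row.region_id)] = GroundTruthEntry(
                region_id=int(row.region_id),
                mechanism=str(row.mechanism),
                direction=str(row.direction),
                affected_positions=pos,
                alpha=None if row.alpha in ("", None) or pd.isna(row.alpha) else float(row.alpha),
                center=None if row.center in ("", None) or pd.isna(row.center) else float(row.center),
                width=None if row.width in ("", None) or pd.isna(row.width) else float(row.width),
                height=None if row.height in ("", None) or pd.isna(row.height) else float(row.height),
                whole_region=bool(int(row.whole_region)),
            )
        return truth


def _draw_levels(rng: np.random.Generator, n: int, config: GeneratorConfig) -> np.ndarray:
    low = rng.random(n) < config.low_frac
    levels = np.where(
        low,
        rng.beta(*config.low_beta, size=n),
        rng.beta(*config.high_beta, size=n),
    )
    return np.clip(levels, _LEVEL_EPS, 1 - _LEVEL_EPS)


def _draw_site_intensity(rng: np.random.Generator, n: int, config: GeneratorConfig) -> np.ndarray:
    """Per-site expected coverage, shared by all samples.

    RRBS coverage is fragment-driven: the same MspI fragments are
    enriched in every library, so per-site depth is strongly correlated
    across replicates. A Gamma site intensity mixed with per-replicate
    Poisson draws reproduces that correlation while keeping the marginal
    coverage exactly negative binomial with the configured mean and
    dispersion.
    """
    r = config.coverage_dispersion
    return rng.gamma(r, config.coverage_mean / r, size=n)


def _draw_coverage(rng: np.random.Generator, intensity: np.ndarray) -> np.ndarray:
    return np.maximum(1, rng.poisson(intensity))


def generate_base_dataset(config: GeneratorConfig) -> tuple[Experiment, list[Region]]:
    """Draw a null two-group RRBS experiment and its region layout.

    Both groups come from the same per-site truth; any between-group
    difference is replicate jitter plus binomial sampling noise. Fully
    deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    regions: list[Region] = []
    cursor = 1000
    all_pos: list[np.ndarray] = []
    for rid in range(config.n_regions):
        n_sites = int(rng.integers(config.min_sites_per_region, config.max_sites_per_region + 1))
        spacing = 2 + rng.geometric(1.0 / (config.mean_spacing - 1.0), size=max(n_sites - 1, 0))
        pos = cursor + np.concatenate(([0], np.cumsum(spacing)))
        regions.append(Region(
            region_id=rid, chrom=config.chrom,
            start=int(pos[0]), end=int(pos[-1]) + 1,
            site_positions=tuple(int(p) for p in pos),
        ))
        all_pos.append(pos.astype(np.int64))
        cursor = int(pos[-1]) + 1 + int(rng.integers(1, 2 * config.region_gap))
    positions = np.concatenate(all_pos)
    n_total = len(positions)
    truth_levels = _draw_levels(rng, n_total, config)

    site_intensity = _draw_site_intensity(rng, n_total, config)
    kappa = config.replicate_precision
    samples: list[SampleTable] = []
    for group in config.group_labels:
        for i in range(config.n_replicates_per_group):
            rep_levels = rng.beta(kappa * truth_levels, kappa * (1 - truth_levels))
            coverage = _draw_coverage(rng, site_intensity)
            meth = rng.binomial(coverage, rep_levels)
            frame = pd.DataFrame({
                "chrom": config.chrom,
                "pos": positions,
                "meth": meth,
                "unmeth": coverage - meth,
            })
            samples.append(SampleTable(f"{group}_{i + 1}", frame, group=group))
    return Experiment(samples), regions


def _group_arrays(samples: Sequence[SampleTable], region: Region) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pos = np.asarray(region.site_positions, dtype=np.int64)
    meth = np.stack([s.counts_at(region.chrom, pos)[0] for s in samples])
    unmeth = np.stack([s.counts_at(region.chrom, pos)[1] for s in samples])
    return pos, meth, meth + unmeth


def _shift_levels(l_old: np.ndarray, alpha: float) -> tuple[np.ndarray, str]:
    """Apply the fixed-shift rule: hyper when the span mean is < 50%."""
    direction = "hyper" if float(l_old.mean()) < 0.5 else "hypo"
    l_new = (1 - alpha) * l_old + (alpha if direction == "hyper" else 0.0)
    return l_new, direction


def _bump_levels(
    l_old: np.ndarray, pos: np.ndarray, center: float, width_bp: float, height: float
) -> np.ndarray:
    bump = height * np.exp(-((pos - center) ** 2) / (2.0 * width_bp**2))
    return np.clip(l_old + bump, 0.0, 1.0)


def _select_span_indices(
    pos: np.ndarray, site_cov: np.ndarray, rng: np.random.Generator
) -> tuple[int, int, bool]:
    """Span-selection core on arrays; returns (lo, hi, whole_region)."""
    n_sites = len(pos)
    n_target = min(int(rng.integers(4, 21)), n_sites)
    lo = int(rng.integers(0, n_sites))
    hi = lo

    def ok_geometry() -> bool:
        return (pos[hi] - pos[lo] + 1 >= 100) and (site_cov[lo:hi + 1].sum() >= 100)

    while not ok_geometry() and (hi < n_sites - 1 or lo > 0):
        if hi < n_sites - 1:
            hi += 1
        else:
            lo -= 1
    while (hi - lo + 1) < n_target and (hi < n_sites - 1 or lo > 0):
        if hi < n_sites - 1:
            hi += 1
        else:
            lo -= 1
    whole = lo == 0 and hi == n_sites - 1
    if not ok_geometry() or (hi - lo + 1) < n_target:
        lo, hi, whole = 0, n_sites - 1, True
    return lo, hi, whole


def select_alter_span(
    region: Region,
    samples: Sequence[SampleTable],
    rng: np.random.Generator,
) -> tuple[tuple[int, ...], bool]:
    """Pick the sub-span of a region to alter.

    Starts from a random site and extends until the span is at least
    100 bp long with a pooled coverage (over the given replicates) of at
    least 100 reads, then keeps widening until it holds n sites with
    n ~ Uniform{4..20} (capped at the region size). Returns the member
    positions and whether the whole region had to be used.
    """
    pos, _, cov = _group_arrays(samples, region)
    lo, hi, whole = _select_span_indices(pos, cov.sum(axis=0), rng)
    return tuple(int(p) for p in pos[lo:hi + 1]), whole


def _resample_group(
    samples: Sequence[SampleTable],
    region: Region,
    span_positions: Sequence[int],
    new_levels: np.ndarray,
    rng: np.random.Generator,
) -> list[SampleTable]:
    """Redraw methylation calls at span sites from new_levels; coverage kept."""
    span = np.asarray(span_positions, dtype=np.int64)
    out: list[SampleTable] = []
    for s in samples:
        frame = s.data.copy()
        sel = (frame["chrom"] == region.chrom) & frame["pos"].isin(span)
        idx = frame.index[sel]
        order = frame.loc[idx, "pos"].to_numpy().argsort()
        idx = idx[order]
        cov = (frame.loc[idx, "meth"] + frame.loc[idx, "unmeth"]).to_numpy()
        present = np.isin(span, frame.loc[idx, "pos"].to_numpy())
        meth_new = rng.binomial(cov, new_levels[present])
        frame.loc[idx, "meth"] = meth_new
        frame.loc[idx, "unmeth"] = cov - meth_new
        out.append(SampleTable(s.sample_id, frame, group=s.group))
    return out


def inject_fixed_shift(
    samples: Sequence[SampleTable],
    region: Region,
    span_positions: Sequence[int],
    alpha: float,
    rng: np.random.Generator,
    whole_region: bool = False,
) -> tuple[list[SampleTable], GroundTruthEntry]:
    """Shift methylation levels over a span by strength ``alpha`` in [0, 1].

    The per-site level L_old is the pooled methylated fraction over the
    given replicates. If the span averages below 50% methylation the span
    is hyper-methylated, L_new = (1 - alpha) L_old + alpha; otherwise it
    is hypo-methylated, L_new = (1 - alpha) L_old. Methylation calls are
    redrawn per replicate as Binomial(coverage, L_new); coverage is
    untouched.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    span = np.asarray(span_positions, dtype=np.int64)
    pos, meth, cov = _group_arrays(samples, region)
    mask = np.isin(pos, span)
    pooled_meth = meth.sum(axis=0)[mask]
    pooled_cov = cov.sum(axis=0)[mask]
    if (pooled_cov == 0).any():
        raise ValueError("span contains sites with no coverage in the group")
    l_old = pooled_meth / pooled_cov
    l_new, direction = _shift_levels(l_old, alpha)
    altered = _resample_group(samples, region, span, l_new, rng)
    entry = GroundTruthEntry(
        region_id=region.region_id, mechanism="shift", direction=direction,
        affected_positions=tuple(int(p) for p in span), alpha=alpha,
        whole_region=whole_region,
    )
    return altered, entry


def inject_gaussian_bump(
    samples: Sequence[SampleTable],
    region: Region,
    center: float,
    width_bp: float,
    height: float,
    rng: np.random.Generator,
) -> tuple[list[SampleTable], GroundTruthEntry]:
    """Add a Gaussian bump of signed ``height`` to the level profile.

    L_new(i) = clip(L_old(i) + height * exp(-(pos_i - center)^2 /
    (2 width_bp^2)), 0, 1) over all region sites; calls are redrawn per
    replicate at unchanged coverage.
    """
    if abs(height) > 1:
        raise ValueError("bump height must satisfy |height| <= 1")
    if width_bp <= 0:
        raise ValueError("bump width must be positive")
    pos, meth, cov = _group_arrays(samples, region)
    pooled_cov = cov.sum(axis=0)
    if (pooled_cov == 0).any():
        raise ValueError("region contains sites with no coverage in the group")
    l_old = meth.sum(axis=0) / pooled_cov
    l_new = _bump_levels(l_old, pos.astype(np.float64), center, width_bp, height)
    altered = _resample_group(samples, region, pos, l_new, rng)
    entry = GroundTruthEntry(
        region_id=region.region_id, mechanism="bump",
        direction="hyper" if height >= 0 else "hypo",
        affected_positions=tuple(int(p) for p in pos),
        center=float(center), width=float(width_bp), height=float(height),
    )
    return altered, entry


def make_benchmark(
    config: GeneratorConfig | None = None,
    mechanism: str = "shift",
    alpha: float = 1.0,
    n_altered: int = 250,
    bump_width_range: tuple[float, float] = (50.0, 200.0),
    bump_height_range: tuple[float, float] = (0.3, 0.8),
) -> tuple[Experiment, list[Region], GroundTruth]:
    """Generate a ground-truthed two-group benchmark.

    Draws the base dataset, selects ``n_altered`` regions at random and
    alters them in the second (testing) group only, by the chosen
    mechanism. Fully deterministic given ``config.seed``.
    """
    config = config or GeneratorConfig()
    if mechanism not in ("shift", "bump"):
        raise ValueError(f"mechanism must be 'shift' or 'bump', got {mechanism!r}")
    if n_altered > config.n_regions:
        raise ValueError("n_altered cannot exceed n_regions")
    exp, regions = generate_base_dataset(config)
    rng = np.random.default_rng([config.seed, 0x5EED])
    chosen = rng.choice(config.n_regions, size=n_altered, replace=False)
    chosen = sorted(int(c) for c in chosen)

    control_label, testing_label = config.group_labels
    testing = exp.group(testing_label)
    truth = GroundTruth()
    region_by_id = {r.region_id: r for r in regions}

    # fast path: mutate per-replicate count arrays, rebuild tables once
    chrom = regions[0].chrom
    pos_all = testing[0].sites(chrom)[0]
    meths = [s.sites(chrom)[1].copy() for s in testing]
    unmeths = [s.sites(chrom)[2].copy() for s in testing]
    covs = [m + u for m, u in zip(meths, unmeths)]
    for rid in chosen:
        region = region_by_id[rid]
        i0 = int(np.searchsorted(pos_all, region.site_positions[0]))
        i1 = i0 + region.n_sites
        rpos = pos_all[i0:i1].astype(np.float64)
        pooled_meth = sum(m[i0:i1] for m in meths)
        pooled_cov = sum(c[i0:i1] for c in covs)
        l_old = pooled_meth / pooled_cov
        if mechanism == "shift":
            lo, hi, whole = _select_span_indices(pos_all[i0:i1], pooled_cov, rng)
            l_new, direction = _shift_levels(l_old[lo:hi + 1], alpha)
            s0, s1 = i0 + lo, i0 + hi + 1
            entry = GroundTruthEntry(
                region_id=rid, mechanism="shift", direction=direction,
                affected_positions=tuple(int(p) for p in pos_all[s0:s1]),
                alpha=alpha, whole_region=whole,
            )
        else:
            center = float(rng.uniform(region.start, region.end))
            width = float(rng.uniform(*bump_width_range))
            height = float(rng.choice([-1.0, 1.0]) * rng.uniform(*bump_height_range))
            l_new = _bump_levels(l_old, rpos, center, width, height)
            s0, s1 = i0, i1
            entry = GroundTruthEntry(
                region_id=rid, mechanism="bump",
                direction="hyper" if height >= 0 else "hypo",
                affected_positions=tuple(int(p) for p in pos_all[s0:s1]),
                center=center, width=width, height=height,
            )
        for m, u, c in zip(meths, unmeths, covs):
            new_meth = rng.binomial(c[s0:s1], l_new)
            m[s0:s1] = new_meth
            u[s0:s1] = c[s0:s1] - new_meth
        truth.entries[rid] = entry

    new_testing = []
    for s, m, u in zip(testing, meths, unmeths):
        frame = pd.DataFrame({"chrom": chrom, "pos": pos_all, "meth": m, "unmeth": u})
        new_testing.append(SampleTable(s.sample_id, frame, group=s.group))
    exp = Experiment(exp.group(control_label) + new_testing)
    return exp, regions, truth
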