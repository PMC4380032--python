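"""Testing-region construction: dense-CpG clusters and BED regions.

Regions are the unit of testing. They can be built from the data by
clustering frequently covered CpG sites (the usual choice for RRBS), or
supplied as a BED file of intervals; either way they pass through the same
exclusion filters before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import Experiment


@dataclass(frozen=True)
class Region:
    """A genomic interval with its member CpG sites (union over samples)."""

    region_id: int
    chrom: str
    start: int
    end: int
    site_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        pos = self.site_positions
        if len(pos) == 0:
            raise ValueError(f"region {self.region_id}: no member sites")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"region {self.region_id}: site positions not strictly increasing")
        if self.start > pos[0] or pos[-1] >= self.end:
            raise ValueError(
                f"region {self.region_id}: sites outside [{self.start}, {self.end})"
            )

    @property
    def n_sites(self) -> int:
        return len(self.site_positions)

    @property
    def width(self) -> int:
        return self.end - self.start


def cluster_cpgs(
    exp: Experiment,
    min_sample_frac: float = 0.75,
    min_site_cov: int = 1,
    max_gap: int = 100,
    min_sites: int = 10,
) -> list[Region]:
    """Cluster frequently covered CpG sites into dense testing regions.

    A site is *frequently covered* when its coverage is at least
    ``min_site_cov`` in at least ``min_sample_frac`` of the samples.
    Frequently covered sites are grouped greedily left to right; a gap
    strictly greater than ``max_gap`` bp starts a new cluster, and clusters
    with fewer than ``min_sites`` sites are discarded. Region bounds are
    ``[first_site, last_site + 1)``.
    """
    n_samples = len(exp.samples)
    needed = min_sample_frac * n_samples - 1e-9
    regions: list[Region] = []
    rid = 0
    for chrom in exp.chroms:
        union = exp.site_union(chrom)
        if len(union) == 0:
            continue
        support = np.zeros(len(union), dtype=np.int64)
        for s in exp.samples:
            m, u = s.counts_at(chrom, union)
            support += (m + u) >= min_site_cov
        frequent = union[support >= needed]
        if len(frequent) == 0:
            continue
        breaks = np.flatnonzero(np.diff(frequent) > max_gap)
        for block in np.split(frequent, breaks + 1):
            if len(block) < min_sites:
                continue
            regions.append(
                Region(
                    region_id=rid,
                    chrom=chrom,
                    start=int(block[0]),
                    end=int(block[-1]) + 1,
                    site_positions=tuple(int(p) for p in block),
                )
            )
            rid += 1
    return regions


def filter_regions(
    regions: Sequence[Region],
    exp: Experiment,
    min_sites: int = 5,
    require_all_samples_covered: bool = True,
) -> list[Region]:
    """Apply the exclusion filters used before testing.

    Removes regions with fewer than ``min_sites`` member CpG sites and
    (when ``require_all_samples_covered``) regions in which at least one
    sample has no covered site at all.
    """
    kept: list[Region] = []
    for region in regions:
        if region.n_sites < min_sites:
            continue
        if require_all_samples_covered:
            pos = np.asarray(region.site_positions, dtype=np.int64)
            ok = True
            for s in exp.samples:
                m, u = s.counts_at(region.chrom, pos)
                if int(m.sum() + u.sum()) == 0:
                    ok = False
                    break
            if not ok:
                continue
        kept.append(region)
    return kept


def regions_from_bed(path: str | Path, exp: Experiment) -> list[Region]:
    """Load BED3/BED6 intervals and attach member sites from the experiment.

    Intervals are 0-based half-open. Member sites are the union of sample
    positions falling inside each interval; intervals containing no site
    are dropped (they carry no data to test). Region ids come from the BED
    name column when it is an integer, otherwise from file order.
    """
    frame = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    regions: list[Region] = []
    for i in range(len(frame)):
        chrom = str(frame.iat[i, 0])
        start, end = int(frame.iat[i, 1]), int(frame.iat[i, 2])
        union = exp.site_union(chrom)
        inside = union[(union >= start) & (union < end)]
        if len(inside) == 0:
            continue
        rid = i
        if frame.shape[1] > 3:
            try:
                rid = int(frame.iat[i, 3])
            except (TypeError, ValueError):
                pass
        regions.append(Region(rid, chrom, start, end, tuple(int(p) for p in inside)))
    return regions


def write_regions_bed(regions: Sequence[Region], path: str | Path) -> None:
    """Write regions as BED6 with the region id in the name column."""
    with open(path, "wt") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.region_id}\t{r.n_sites}\t+\n")
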