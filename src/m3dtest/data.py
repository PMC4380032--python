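"""Containers for per-CpG bisulfite read-count data.

All coordinates are internally 0-based positions of the forward-strand
cytosine of a CpG dinucleotide. Readers that consume 1-based formats
(bismark coverage files) shift on input; writers shift back on output.

A :class:`SampleTable` holds the methylated/unmethylated read counts of one
RRBS replicate. An :class:`Experiment` bundles the replicates of a two-group
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SITE_COLUMNS = ["chrom", "pos", "meth", "unmeth"]


@dataclass(frozen=True)
class SiteRecord:
    """Read counts observed at one CpG site in one sample."""

    chrom: str
    pos: int
    meth_count: int
    unmeth_count: int

    def __post_init__(self) -> None:
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValueError(
                f"negative read count at {self.chrom}:{self.pos}: "
                f"({self.meth_count}, {self.unmeth_count})"
            )

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count


class SampleTable:
    """Per-CpG counts of one sample, sorted and unique per (chrom, pos).

    Parameters
    ----------
    sample_id:
        Identifier of the replicate.
    data:
        Frame with columns ``chrom, pos, meth, unmeth`` (and optionally
        ``strand``, before strand merging). Normalised on construction:
        duplicate positions are summed, zero-coverage rows dropped, rows
        sorted by (chrom, pos).
    group:
        Comparison-group label, or ``None`` when not yet assigned.
    """

    def __init__(self, sample_id: str, data: pd.DataFrame, group: str | None = None):
        self.sample_id = str(sample_id)
        self.group = group
        self.data = _normalise_sites(data)
        # per-chromosome position/count arrays for fast region slicing
        self._index: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in self.data.groupby("chrom", sort=False):
            self._index[str(chrom)] = (
                sub["pos"].to_numpy(np.int64),
                sub["meth"].to_numpy(np.int64),
                sub["unmeth"].to_numpy(np.int64),
            )

    @classmethod
    def from_records(
        cls, sample_id: str, records: Iterable[SiteRecord], group: str | None = None
    ) -> "SampleTable":
        rows = [(r.chrom, r.pos, r.meth_count, r.unmeth_count) for r in records]
        frame = pd.DataFrame(rows, columns=SITE_COLUMNS)
        return cls(sample_id, frame, group=group)

    @property
    def chroms(self) -> list[str]:
        return list(self._index)

    @property
    def n_sites(self) -> int:
        return len(self.data)

    @property
    def total_reads(self) -> int:
        return int(self.data["meth"].sum() + self.data["unmeth"].sum())

    def sites(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (positions, meth, unmeth) arrays for one chromosome."""
        empty = np.empty(0, dtype=np.int64)
        return self._index.get(chrom, (empty, empty, empty))

    def counts_at(self, chrom: str, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Meth/unmeth counts at the given sorted positions (0 where absent)."""
        pos, meth, unmeth = self.sites(chrom)
        positions = np.asarray(positions, dtype=np.int64)
        idx = np.searchsorted(pos, positions)
        idx_c = np.clip(idx, 0, max(len(pos) - 1, 0))
        hit = (len(pos) > 0) & (pos[idx_c] == positions) if len(pos) else np.zeros(len(positions), bool)
        m = np.where(hit, meth[idx_c], 0) if len(pos) else np.zeros(len(positions), np.int64)
        u = np.where(hit, unmeth[idx_c], 0) if len(pos) else np.zeros(len(positions), np.int64)
        return m.astype(np.int64), u.astype(np.int64)

    def records(self) -> list[SiteRecord]:
        return [
            SiteRecord(row.chrom, int(row.pos), int(row.meth), int(row.unmeth))
            for row in self.data.itertuples(index=False)
        ]

    def __repr__(self) -> str:  # pragma: no cover
        return f"SampleTable({self.sample_id!r}, group={self.group!r}, n_sites={self.n_sites})"


def _normalise_sites(frame: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SITE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"site frame missing columns: {missing}")
    keys = ["chrom", "pos"] + (["strand"] if "strand" in frame.columns else [])
    frame = frame.copy()
    frame["pos"] = frame["pos"].astype(np.int64)
    frame["meth"] = frame["meth"].astype(np.int64)
    frame["unmeth"] = frame["unmeth"].astype(np.int64)
    if (frame["meth"] < 0).any() or (frame["unmeth"] < 0).any():
        bad = frame.index[(frame["meth"] < 0) | (frame["unmeth"] < 0)][0]
        raise ValueError(f"negative read count in row {bad}")
    if "strand" in frame.columns:
        bad_strand = ~frame["strand"].isin(["+", "-"])
        if bad_strand.any():
            raise ValueError(f"invalid strand value {frame.loc[bad_strand, 'strand'].iloc[0]!r}")
    cols = keys + ["meth", "unmeth"]
    frame = frame[cols]
    frame = frame.groupby(keys, as_index=False, sort=False).sum()
    frame = frame[(frame["meth"] + frame["unmeth"]) >= 1]
    frame = frame.sort_values(keys, kind="mergesort").reset_index(drop=True)
    return frame


class Experiment:
    """A two-group RRBS comparison: replicates with group labels.

    Exactly two distinct group labels are required. Statistic computation
    works with one replicate per group; hypothesis testing additionally
    needs at least one group with two or more replicates (enforced where
    the empirical null is built).
    """

    def __init__(self, samples: Sequence[SampleTable]):
        samples = list(samples)
        if not samples:
            raise ValueError("experiment needs at least one sample")
        labels: list[str] = []
        for s in samples:
            if s.group is None:
                raise ValueError(f"sample {s.sample_id!r} has no group label")
            if s.group not in labels:
                labels.append(s.group)
        if len(labels) != 2:
            raise ValueError(f"experiment needs exactly two group labels, got {labels}")
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        self.samples = samples
        self.group_labels: tuple[str, str] = (labels[0], labels[1])

    def group(self, label: str) -> list[SampleTable]:
        if label not in self.group_labels:
            raise KeyError(f"unknown group {label!r}")
        return [s for s in self.samples if s.group == label]

    @property
    def chroms(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            for c in s.chroms:
                if c not in seen:
                    seen.append(c)
        return sorted(seen)

    def site_union(self, chrom: str) -> np.ndarray:
        """Sorted union of site positions over all samples on a chromosome."""
        arrays = [s.sites(chrom)[0] for s in self.samples]
        arrays = [a for a in arrays if len(a)]
        if not arrays:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(arrays))

    def __repr__(self) -> str:  # pragma: no cover
        a, b = self.group_labels
        return (
            f"Experiment({len(self.group(a))}x{a!r} vs {len(self.group(b))}x{b!r}, "
            f"{len(self.samples)} samples)"
        )
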