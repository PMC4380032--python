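"""Readers and writers for per-CpG count files, and CpG strand merging.

Supported formats:

* bismark coverage dialect (``.cov``/``.cov.gz``): tab-separated
  ``chrom, start, end, percent_methylated, count_methylated,
  count_unmethylated`` with 1-based inclusive coordinates.
* ENCODE-style RRBS BED9+ (0-based half-open) carrying a read-count column
  and a percent-methylated column; column indices are configurable because
  published layouts vary.

Zero-coverage rows are dropped on load and duplicate positions are summed
(both handled by :class:`~m3dtest.data.SampleTable` normalisation).
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import IO

import numpy as np
import pandas as pd

from .data import SampleTable


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return _io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_bismark_cov(
    path: str | Path, sample_id: str | None = None, group: str | None = None
) -> SampleTable:
    """Read a bismark coverage file into a :class:`SampleTable`.

    The dialect is 1-based; positions are shifted to the internal 0-based
    convention. Rows with zero total coverage are dropped; rows sharing a
    position are summed.
    """
    sample_id = sample_id or Path(path).name.split(".")[0]
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >= 6 tab-separated fields")
            try:
                start = int(fields[1])
                meth = int(fields[4])
                unmeth = int(fields[5])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if meth < 0 or unmeth < 0:
                raise ValueError(f"{path}: line {lineno}: negative read count")
            rows.append((fields[0], start - 1, meth, unmeth))
    frame = pd.DataFrame(rows, columns=["chrom", "pos", "meth", "unmeth"])
    return SampleTable(sample_id, frame, group=group)


def write_bismark_cov(table: SampleTable, path: str | Path) -> None:
    """Write a sample in the bismark coverage dialect (1-based, both ends)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for row in table.data.itertuples(index=False):
            cov = row.meth + row.unmeth
            pct = 100.0 * row.meth / cov
            fh.write(f"{row.chrom}\t{row.pos + 1}\t{row.pos + 1}\t{pct:g}\t{row.meth}\t{row.unmeth}\n")


def read_encode_rrbs_bed(
    path: str | Path,
    sample_id: str | None = None,
    group: str | None = None,
    count_col: int = 4,
    percent_col: int = 10,
    strand_col: int = 5,
    combine: bool = True,
) -> SampleTable:
    """Read an ENCODE-style RRBS BED9+ file.

    ``count_col``/``percent_col``/``strand_col`` are 0-based column indices
    (defaults: BED score column = read count, column 11 = percent
    methylated, column 6 = strand). Methylated counts are reconstructed as
    ``round(coverage * percent / 100)`` with round-half-even.

    When ``combine`` is true (default), minus-strand cytosines are merged
    into the forward-strand C of their CpG via :func:`combine_strands`.
    """
    sample_id = sample_id or Path(path).name.split(".")[0]
    rows = []
    has_strand = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            needed = max(count_col, percent_col) + 1
            if len(fields) < needed:
                raise ValueError(f"{path}: line {lineno}: expected >= {needed} fields")
            try:
                start = int(fields[1])
                cov = int(fields[count_col])
                pct = float(fields[percent_col])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if not 0.0 <= pct <= 100.0:
                raise ValueError(f"{path}: line {lineno}: percent {pct} outside [0, 100]")
            if cov < 0:
                raise ValueError(f"{path}: line {lineno}: negative read count")
            if cov == 0:
                continue
            # round-half-even, as numpy/python round
            meth = int(round(cov * pct / 100.0))
            strand = fields[strand_col] if len(fields) > strand_col and fields[strand_col] in "+-" else "+"
            has_strand = has_strand or strand == "-"
            rows.append((fields[0], start, strand, meth, cov - meth))
    frame = pd.DataFrame(rows, columns=["chrom", "pos", "strand", "meth", "unmeth"])
    table = SampleTable(sample_id, frame, group=group)
    if combine:
        table = combine_strands(table)
    return table


def combine_strands(table: SampleTable) -> SampleTable:
    """Merge minus-strand cytosines into the forward-strand C of their CpG.

    In a CpG dinucleotide the reverse-strand cytosine sits one base
    downstream of the forward-strand one, so a minus-strand record at
    position ``p`` is summed into position ``p - 1``. No reference genome
    is consulted: orphan minus-strand sites are still shifted and kept.
    Tables without strand annotation are returned unchanged (already
    combined).
    """
    frame = table.data
    if "strand" not in frame.columns:
        return table
    frame = frame.copy()
    minus = frame["strand"] == "-"
    frame.loc[minus, "pos"] -= 1
    frame = frame.drop(columns="strand")
    return SampleTable(table.sample_id, frame, group=table.group)


def read_sample_manifest(path: str | Path) -> pd.DataFrame:
    """Read a TSV manifest with columns sample_id, group, path."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "group", "path"} - set(frame.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    return frame


def load_experiment(manifest_path: str | Path, fmt: str = "bismark"):
    """Load all samples named in a manifest into an :class:`Experiment`."""
    from .data import Experiment

    manifest = read_sample_manifest(manifest_path)
    base = Path(manifest_path).parent
    samples = []
    for row in manifest.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        if fmt == "bismark":
            samples.append(read_bismark_cov(p, sample_id=row.sample_id, group=row.group))
        elif fmt == "encode-bed":
            samples.append(read_encode_rrbs_bed(p, sample_id=row.sample_id, group=row.group))
        else:
            raise ValueError(f"unknown format {fmt!r}")
    return Experiment(samples)
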