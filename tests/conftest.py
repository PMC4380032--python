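import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from m3dtest import Experiment, Region, RegionSlice, SampleTable

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_slice(pos, meth, unmeth) -> RegionSlice:
    return RegionSlice(
        np.asarray(pos, dtype=np.int64),
        np.asarray(meth, dtype=np.int64),
        np.asarray(unmeth, dtype=np.int64),
    )


def make_sample(sample_id, group, rows, chrom="chr1") -> SampleTable:
    """rows: iterable of (pos, meth, unmeth)."""
    frame = pd.DataFrame(rows, columns=["pos", "meth", "unmeth"])
    frame.insert(0, "chrom", chrom)
    return SampleTable(sample_id, frame, group=group)


def expand_reads(sl: RegionSlice):
    """Oracle: expand counts into individual (position, status) reads."""
    pos, status = [], []
    for p, m, u in zip(sl.positions, sl.meth_counts, sl.unmeth_counts):
        pos.extend([p] * (m + u))
        status.extend([1] * m + [0] * u)
    return np.asarray(pos, dtype=float), np.asarray(status)


def brute_mmd(sl_x: RegionSlice, sl_y: RegionSlice, sigma: float, aware: bool) -> float:
    """Oracle: biased MMD by direct per-read double sums."""
    px, sx = expand_reads(sl_x)
    py, sy = expand_reads(sl_y)

    def gram(pa, sa, pb, sb):
        k = np.exp(-((pa[:, None] - pb[None, :]) ** 2) / (2 * sigma**2))
        if aware:
            k = k * (sa[:, None] == sb[None, :])
        return k.sum()

    m, n = len(px), len(py)
    mmd2 = gram(px, sx, px, sx) / m**2 - 2 * gram(px, sx, py, sy) / (m * n) + gram(py, sy, py, sy) / n**2
    return np.sqrt(max(0.0, mmd2))


def random_slice(rng, n_sites_max=6, count_max=5, span=60) -> RegionSlice:
    n = int(rng.integers(1, n_sites_max + 1))
    pos = np.sort(rng.choice(span, size=n, replace=False))
    meth = rng.integers(0, count_max + 1, size=n)
    unmeth = rng.integers(0, count_max + 1, size=n)
    if (meth + unmeth).sum() == 0:
        meth[0] = 1
    return make_slice(pos, meth, unmeth)


@pytest.fixture
def two_by_two() -> Experiment:
    """2+2 experiment over three sites with distinct count patterns."""
    rows_a = [(100, 5, 2), (130, 1, 6), (170, 4, 4)]
    rows_b = [(100, 4, 3), (130, 2, 5), (170, 5, 3)]
    rows_c = [(100, 0, 7), (130, 6, 1), (170, 2, 6)]
    rows_d = [(100, 1, 6), (130, 5, 2), (170, 3, 5)]
    return Experiment([
        make_sample("a1", "A", rows_a),
        make_sample("a2", "A", rows_b),
        make_sample("b1", "B", rows_c),
        make_sample("b2", "B", rows_d),
    ])


@pytest.fixture
def one_region() -> Region:
    return Region(0, "chr1", 100, 171, (100, 130, 170))
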