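"""Scoring DMR calls against simulation ground truth.

Confusion counts follow the benchmark's table semantics: "correct" are
truly altered regions that were called, "type1" are unaltered regions
falsely called, "type2" are altered regions missed. The ROC sweeps the
nominal Benjamini-Hochberg FDR level over [0, 1] and records the true
positive rate at each level; its area summarises ranking quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GroundTruth
from .testing import bh_fdr


@dataclass(frozen=True)
class ConfusionCounts:
    correct: int
    type1: int
    type2: int
    true_negatives: int

    @property
    def n_altered(self) -> int:
        return self.correct + self.type2

    @property
    def n_unaltered(self) -> int:
        return self.type1 + self.true_negatives

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.correct, self.type1, self.type2, self.true_negatives]],
            columns=["correct", "type1", "type2", "true_negatives"],
        )


@dataclass(frozen=True)
class RocCurve:
    """TPR against the nominal FDR level, with trapezoid AUC.

    ``realized_fdp`` carries the realized false-discovery proportion at
    each level for diagnostics; the AUC integrates TPR over the nominal
    axis.
    """

    fdr_grid: np.ndarray
    tpr: np.ndarray
    auc: float
    realized_fdp: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "fdr_level": self.fdr_grid, "tpr": self.tpr, "realized_fdp": self.realized_fdp,
        })


def confusion(results: pd.DataFrame, truth: GroundTruth) -> ConfusionCounts:
    """Confusion counts of a results table against ground truth."""
    ids = set(int(i) for i in results["region_id"])
    missing = truth.altered_region_ids - ids
    if missing:
        raise ValueError(f"results missing truth regions: {sorted(missing)[:5]}...")
    altered = results["region_id"].astype(int).isin(truth.altered_region_ids).to_numpy()
    called = results["called"].to_numpy(dtype=bool)
    return ConfusionCounts(
        correct=int((altered & called).sum()),
        type1=int((~altered & called).sum()),
        type2=int((altered & ~called).sum()),
        true_negatives=int((~altered & ~called).sum()),
    )


def roc_tpr_vs_fdr(
    results: pd.DataFrame,
    truth: GroundTruth,
    grid_size: int = 1001,
    pvalue_col: str = "p_empirical",
) -> RocCurve:
    """ROC of TPR versus the nominal BH FDR level swept over [0, 1].

    Calls at level f are the regions whose BH q-value is <= f, so the
    whole sweep needs a single adjustment pass. AUC is the trapezoid
    integral of TPR over the nominal axis.
    """
    if pvalue_col not in results.columns:
        raise ValueError(f"results lack a {pvalue_col!r} column")
    ids = set(int(i) for i in results["region_id"])
    if truth.altered_region_ids - ids:
        raise ValueError("results do not cover all truth regions")
    qvals, _ = bh_fdr(results[pvalue_col].to_numpy(), fdr_level=1.0)
    altered = results["region_id"].astype(int).isin(truth.altered_region_ids).to_numpy()
    n_alt = int(altered.sum())
    if n_alt == 0:
        raise ValueError("ground truth contains no altered regions")
    grid = np.linspace(0.0, 1.0, grid_size)
    calls = qvals[None, :] <= grid[:, None]
    tpr = (calls & altered[None, :]).sum(axis=1) / n_alt
    n_called = calls.sum(axis=1)
    fp = (calls & ~altered[None, :]).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fdp = np.where(n_called > 0, fp / np.maximum(n_called, 1), 0.0)
    auc = float(np.trapezoid(tpr, grid))
    return RocCurve(fdr_grid=grid, tpr=tpr.astype(float), auc=auc, realized_fdp=fdp)
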