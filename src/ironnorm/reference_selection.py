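"""Median-chip selection by all-vs-all RMSD of log2 intensity vectors.

Every chip is eventually normalized pair-wise against one common reference.
The reference is the "median chip": the sample whose mean root-mean-squared
distance (in log2 intensity space, over retained features) to all other
samples is smallest.  RMSD concurrently favours median brightness and
minimal relative curvature, which correlation-based distances do not.

Distances are computed on raw (pre-background-subtraction) intensities so
the choice of reference does not depend on a tunable correction.  QC probes
and probes without a probeset assignment are excluded when a layout is
supplied; without a layout every feature is retained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ChipLayout, ExpressionMatrix, safe_log

logger = logging.getLogger(__name__)

__all__ = ["DistanceTable", "pairwise_rmsd", "find_median_chip"]


@dataclass
class DistanceTable:
    """Symmetric pairwise RMSD table (log2-intensity units) with per-sample
    mean distance to all other samples."""

    sample_ids: list[str]
    rmsd: np.ndarray
    mean_rmsd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rmsd, index=self.sample_ids, columns=self.sample_ids)
        df["mean_rmsd"] = self.mean_rmsd
        return df


def pairwise_rmsd(
    a: np.ndarray,
    b: np.ndarray,
    exclude: np.ndarray | set | None = None,
    log_base: float = 2.0,
) -> float:
    """RMSD between two chips over retained features.

    ``a`` and ``b`` are aligned linear intensity vectors; values ≤ 0 are
    replaced per chip by that chip's smallest positive value before the log.
    ``exclude`` is a boolean mask or an index collection of features to omit
    (QC probes, unassigned probes).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("chips must be aligned 1-D vectors of equal length")
    keep = np.ones(a.size, dtype=bool)
    if exclude is not None:
        excl = np.asarray(sorted(exclude)) if isinstance(exclude, (set, frozenset)) else np.asarray(exclude)
        if excl.dtype == bool:
            keep = ~excl
        elif excl.size:
            keep[excl.astype(int)] = False
    if not keep.any():
        raise ValueError("no features retained for RMSD")
    la = safe_log(a, log_base)[keep]
    lb = safe_log(b, log_base)[keep]
    return float(np.sqrt(np.mean((la - lb) ** 2)))


def _exclusion_mask(feature_ids: list[str], layout: ChipLayout | None) -> np.ndarray | None:
    if layout is None:
        return None
    drop = layout.qc_probes | layout.unassigned
    # features absent from the layout entirely count as undefined
    known = layout.known_probes
    mask = np.array(
        [fid in drop or fid not in known for fid in feature_ids], dtype=bool
    )
    return mask if mask.any() else None


def find_median_chip(
    matrix: ExpressionMatrix,
    layout: ChipLayout | None = None,
    summarize_first: bool = False,
    log_base: float = 2.0,
) -> tuple[str, DistanceTable]:
    """Pick the sample minimizing mean RMSD to all others.

    With ``summarize_first`` (and a layout) probesets are summarized before
    distance computation, which shrinks the vectors for very large cohorts.
    Deterministic; ties go to the lexicographically smallest sample ID with
    a logged notice.  Chips are visited in pairs so only two log vectors are
    ever materialized at once.
    """
    matrix.require_scale("linear")
    n = matrix.n_samples
    if n < 2:
        raise ValueError("need ≥ 2 samples to select a reference chip")
    if summarize_first:
        if layout is None:
            raise ValueError("summarize_first requires a layout")
        from .summarize import summarize_probesets

        matrix = summarize_probesets(matrix, layout)
        mask = None  # probesets carry no QC/unassigned notion
    else:
        mask = _exclusion_mask(matrix.feature_ids, layout)

    rmsd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_rmsd(
                matrix.values[:, i], matrix.values[:, j], exclude=mask, log_base=log_base
            )
            rmsd[i, j] = rmsd[j, i] = d
    mean_rmsd = rmsd.sum(axis=1) / (n - 1)
    table = DistanceTable(list(matrix.sample_ids), rmsd, mean_rmsd)

    best = np.min(mean_rmsd)
    tied = [sid for sid, m in zip(matrix.sample_ids, mean_rmsd) if m == best]
    if len(tied) > 1:
        logger.info("median-chip tie among %s; choosing %s", tied, min(tied))
    return min(tied), table
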