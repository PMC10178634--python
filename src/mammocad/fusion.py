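"""Serial mid-value feature fusion.

Feature matrices extracted from the original and the contrast-enhanced
images are concatenated column-wise (serial fusion, d = d1 + d2). Each
column of the fused matrix is summarized by a scalar score (mean
activation by default), and the *mid-value* of the scores,

    Fnc = (min(scores) + max(scores)) / 2,

acts as a keep/drop cutoff: columns with score >= Fnc are retained
(boundary inclusive). The maximum-score column always meets the cutoff, so
the retained set is never empty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix

__all__ = [
    "FusedFeatureSet",
    "serial_fuse",
    "column_scores",
    "mid_value",
    "threshold_fuse",
]

_STATISTICS = {
    "mean": lambda v: v.mean(axis=0),
    "max": lambda v: v.max(axis=0),
    "median": lambda v: np.median(v, axis=0),
}


@dataclass
class FusedFeatureSet:
    """Thresholded fusion output: retained submatrix plus the bookkeeping."""

    matrix: FeatureMatrix
    retained_indices: np.ndarray  # strictly increasing, into the concatenated matrix
    threshold: float  # the mid-value Fnc
    scores: np.ndarray  # per-column score of the full concatenated matrix
    statistic: str


def serial_fuse(f1: FeatureMatrix, f2: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation of two feature matrices.

    Requires the same sample count and identical label vectors in the same
    row order; labels are preserved.
    """
    if f1.n_samples != f2.n_samples:
        raise ValueError(
            f"sample count mismatch: {f1.n_samples} vs {f2.n_samples}"
        )
    if not np.array_equal(f1.labels, f2.labels):
        raise ValueError("label vectors differ between the two matrices")
    return FeatureMatrix(
        values=np.hstack([f1.values, f2.values]),
        labels=f1.labels.copy(),
        backbone_id=f"{f1.backbone_id}+{f2.backbone_id}",
        source_id=f"{f1.source_id}+{f2.source_id}",
    )


def column_scores(fused: FeatureMatrix, statistic: str = "mean") -> np.ndarray:
    """Scalar summary per column used for thresholding (default: mean)."""
    if statistic not in _STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic!r}; choose from {sorted(_STATISTICS)}"
        )
    if fused.n_samples == 0:
        raise ValueError("empty feature matrix")
    return _STATISTICS[statistic](fused.values)


def mid_value(scores: np.ndarray) -> float:
    """Midpoint of the lowest and highest score: (lw + hw) / 2."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("empty score vector")
    return float((scores.min() + scores.max()) / 2.0)


def threshold_fuse(
    f1: FeatureMatrix, f2: FeatureMatrix, statistic: str = "mean"
) -> FusedFeatureSet:
    """Fuse serially, then keep exactly the columns scoring >= the mid-value."""
    fused = serial_fuse(f1, f2)
    scores = column_scores(fused, statistic)
    fnc = mid_value(scores)
    retained = np.flatnonzero(scores >= fnc)
    if retained.size == 0:  # unreachable (max >= mid), kept as a hard guard
        retained = np.array([int(np.argmax(scores))])
    sub = FeatureMatrix(
        values=fused.values[:, retained],
        labels=fused.labels.copy(),
        backbone_id=fused.backbone_id,
        source_id=fused.source_id,
    )
    return FusedFeatureSet(
        matrix=sub,
        retained_indices=retained,
        threshold=fnc,
        scores=scores,
        statistic=statistic,
    )
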