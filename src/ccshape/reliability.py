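"""Segmentation accuracy (Dice) and test-retest reliability (ICC(2,1)).

ICC here is the Shrout-Fleiss ICC(2,1): two-way random effects, absolute
agreement, single measurement,

    ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with MSR/MSC/MSE the row (subject), column (session) and residual mean
squares of the two-way ANOVA on an n-subjects x k-sessions matrix.
Missing sessions are rejected rather than imputed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from ccshape.imaging_io import CCMask, ValidationError
from ccshape.shape_metrics import compute_all_metrics

__all__ = ["ReliabilityMatrix", "dice", "icc2", "reliability_study"]


class UndefinedICCError(ValueError):
    """Zero total variance: the ICC is not defined."""


@dataclasses.dataclass
class ReliabilityMatrix:
    """n_subjects x k_sessions matrix of one metric."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValidationError("need at least a 2 x 2 complete matrix")
        if not np.all(np.isfinite(v)):
            raise ValidationError("matrix has missing or non-finite cells")
        self.values = v


def dice(a: CCMask, b: CCMask) -> float:
    """Dice overlap 2|a n b| / (|a| + |b|); 1.0 when both masks are empty."""
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch {a.shape} vs {b.shape}")
    x = a.labels.astype(bool)
    y = b.labels.astype(bool)
    denom = x.sum() + y.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(x, y).sum() / denom)


def icc2(matrix: ReliabilityMatrix | np.ndarray) -> float:
    """ICC(2,1) from the two-way ANOVA decomposition."""
    if not isinstance(matrix, ReliabilityMatrix):
        matrix = ReliabilityMatrix(np.asarray(matrix))
    v = matrix.values
    n, k = v.shape
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ss_total = ((v - grand) ** 2).sum()
    if ss_total == 0:
        raise UndefinedICCError("zero total variance")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse)))


def reliability_study(
    session_masks: dict[str, list[CCMask]],
    truth_masks: dict[str, CCMask] | None = None,
) -> pd.DataFrame:
    """Shape-metric test-retest report across repeated sessions.

    ``session_masks`` maps subject id -> list of per-session masks (every
    subject needs the same number k >= 2 of sessions).  Returns one row
    per metric with its ICC(2,1); if ``truth_masks`` is given, the mean
    Dice of every session mask against the subject's reference mask is
    reported in the attribute ``report.attrs["mean_dice"]``.
    """
    subjects = sorted(session_masks)
    if not subjects:
        raise ValidationError("no subjects")
    k = len(session_masks[subjects[0]])
    if k < 2 or any(len(session_masks[s]) != k for s in subjects):
        raise ValidationError("every subject needs the same k >= 2 sessions")
    rows = {}
    for s in subjects:
        rows[s] = [compute_all_metrics(m).to_dict() for m in session_masks[s]]
    metric_names = list(rows[subjects[0]][0])
    records = []
    for name in metric_names:
        mat = np.array([[rows[s][j][name] for j in range(k)] for s in subjects])
        try:
            val = icc2(mat) if len(subjects) >= 2 else np.nan
        except UndefinedICCError:
            val = np.nan
        records.append({"metric": name, "icc2": val})
    report = pd.DataFrame(records)
    if truth_masks is not None:
        dices = [dice(m, truth_masks[s]) for s in subjects for m in session_masks[s]]
        report.attrs["mean_dice"] = float(np.mean(dices))
    return report
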