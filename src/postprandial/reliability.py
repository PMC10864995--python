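"""Within-person reproducibility: the two-way absolute-agreement ICC.

A biomarker that swings with prandial status has low within-person
reproducibility across a meal-challenge time course. This is quantified by
the intraclass correlation under the two-way random-effects model with no
interaction on log concentrations,

    y_ij = mu + b_i + u_j + e_ij,

where b_i is the subject effect, u_j the timepoint effect and e_ij the
residual. The absolute-agreement ICC is

    ICC = var_subject / (var_subject + var_time + var_residual),

estimated by the ANOVA moment method: var_subject = (MSS - MSE)/k,
var_time = (MST - MSE)/n, var_residual = MSE, with negative component
estimates truncated to zero. With a single measurement per subject x
timepoint cell the interaction is not identifiable, so the no-interaction
model is the natural (and the conventionally named) estimator.

Missing data are handled by listwise deletion: subjects with any missing
timepoint are dropped before the balanced ANOVA, and the drop count is
reported alongside the estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io import PanelMatrix


@dataclass(frozen=True)
class ICCResult:
    metabolite: str
    n_subjects: int
    k_timepoints: int
    n_dropped: int
    mss: float
    mst: float
    mse: float
    var_subject: float
    var_time: float
    var_residual: float
    icc: float


def complete_case_filter(panel: PanelMatrix) -> tuple[PanelMatrix, int]:
    """Drop subjects with any missing timepoint; return the balanced panel."""
    complete = panel.values.dropna(axis=0, how="any")
    n_dropped = panel.n_subjects - complete.shape[0]
    if complete.shape[0] < 2:
        raise ValidationError(
            f"{panel.metabolite!r}: fewer than 2 complete subjects "
            f"({complete.shape[0]} remain after dropping {n_dropped})"
        )
    return PanelMatrix(metabolite=panel.metabolite, values=complete), n_dropped


def anova_mean_squares(log_values: np.ndarray) -> tuple[float, float, float]:
    """Two-way no-interaction ANOVA mean squares on a balanced n x k matrix.

    Returns (MSS, MST, MSE): between-subject, between-timepoint and residual
    mean squares of the row/column decomposition.
    """
    y = np.asarray(log_values, dtype=float)
    if y.ndim != 2 or np.any(~np.isfinite(y)):
        raise ValidationError("balanced complete n x k matrix required")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValidationError("need >= 2 subjects and >= 2 timepoints")
    row = y.mean(axis=1)
    col = y.mean(axis=0)
    grand = y.mean()
    mss = k * np.sum((row - grand) ** 2) / (n - 1)
    mst = n * np.sum((col - grand) ** 2) / (k - 1)
    resid = y - row[:, None] - col[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(mss), float(mst), float(mse)


def icc_absolute_agreement(panel: PanelMatrix) -> ICCResult:
    """Absolute-agreement ICC of one metabolite's log-scale panel."""
    balanced, n_dropped = complete_case_filter(panel)
    y = np.log(balanced.values.to_numpy())
    n, k = y.shape
    mss, mst, mse = anova_mean_squares(y)
    var_subject = max((mss - mse) / k, 0.0)
    var_time = max((mst - mse) / n, 0.0)
    var_residual = mse
    total = var_subject + var_time + var_residual
    icc = var_subject / total if total > 0 else 0.0
    return ICCResult(
        metabolite=panel.metabolite,
        n_subjects=n,
        k_timepoints=k,
        n_dropped=n_dropped,
        mss=mss,
        mst=mst,
        mse=mse,
        var_subject=var_subject,
        var_time=var_time,
        var_residual=var_residual,
        icc=icc,
    )


def icc_from_mean_squares(mss: float, mst: float, mse: float, n: int, k: int) -> float:
    """Closed-form absolute-agreement ICC from mean squares (no truncation).

    ICC = (MSS - MSE) / (MSS + (k-1)MSE + (k/n)(MST - MSE)); algebraically
    identical to the variance-component ratio before truncation.
    """
    denom = mss + (k - 1) * mse + (k / n) * (mst - mse)
    if denom == 0:
        return 0.0
    return (mss - mse) / denom
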