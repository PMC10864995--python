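"""Individual-baseline relative-change trajectories.

Each subject's pre-meal (0 h) sample is their own reference: per-subject
ratios y_ij / y_i,ref cancel stable between-person level differences (for
example the generally higher amino-acid levels in males), and the cohort
change at each timepoint is the geometric mean of those ratios, reported as
a percentage with a ratio-scale geometric confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geostats import DEFAULT_Z, summarize_values
from .io import PanelMatrix
from .synthetic_data import StudyDesign


@dataclass(frozen=True)
class RelativeChangeSeries:
    """Cohort percent-change trajectory for one metabolite and stratum.

    ``table`` has one row per timepoint with columns
    time_h, n, pct_change, ci_low_pct, ci_high_pct.
    """

    metabolite: str
    stratum: str
    reference_time_h: float
    table: pd.DataFrame
    excluded_subjects: tuple[str, ...] = ()


def subject_ratios(
    panel: PanelMatrix, reference_time_h: float = 0.0
) -> tuple[PanelMatrix, tuple[str, ...]]:
    """Per-subject ratios to the individual reference sample.

    Subjects with a missing reference value cannot be normalised and are
    excluded (and reported); the reference column of the result is
    identically 1 for the retained subjects.
    """
    if reference_time_h not in panel.values.columns:
        raise ValidationError(
            f"reference timepoint {reference_time_h} h not in panel "
            f"(timepoints: {panel.timepoints_h})"
        )
    ref = panel.values[reference_time_h]
    excluded = tuple(ref.index[ref.isna()])
    kept = panel.values.loc[ref.notna()]
    if kept.empty:
        raise ValidationError("no subject has a reference value")
    ratios = kept.div(kept[reference_time_h], axis=0)
    return (
        PanelMatrix(metabolite=panel.metabolite, values=ratios),
        excluded,
    )


def combine_percent_change(
    ratios: PanelMatrix,
    reference_time_h: float = 0.0,
    z: float = DEFAULT_Z,
    stratum: str = "all",
) -> RelativeChangeSeries:
    """Geometric-mean percent change per timepoint, with ratio-scale gCI.

    pct_change(t) = 100 * (gMean of ratios at t - 1); the interval is the
    gCI of the ratios mapped through the same transform. At the reference
    timepoint all ratios are exactly 1, so the change is 0 with a degenerate
    interval.
    """
    rows = []
    for t in ratios.timepoints_h:
        col = ratios.values[t].dropna().to_numpy()
        if col.size < 2:
            raise ValidationError(
                f"timepoint {t} h has fewer than 2 ratios (n={col.size})"
            )
        s = summarize_values(col, z=z)
        rows.append(
            {
                "time_h": t,
                "n": s.n,
                "pct_change": 100.0 * (s.gmean - 1.0),
                "ci_low_pct": 100.0 * (s.ci_low - 1.0),
                "ci_high_pct": 100.0 * (s.ci_high - 1.0),
            }
        )
    return RelativeChangeSeries(
        metabolite=ratios.metabolite,
        stratum=stratum,
        reference_time_h=reference_time_h,
        table=pd.DataFrame(rows),
    )


def relative_change(
    panel: PanelMatrix,
    reference_time_h: float = 0.0,
    z: float = DEFAULT_Z,
    stratum: str = "all",
) -> RelativeChangeSeries:
    """Convenience: subject_ratios then combine_percent_change."""
    ratios, excluded = subject_ratios(panel, reference_time_h)
    series = combine_percent_change(ratios, reference_time_h, z=z, stratum=stratum)
    return RelativeChangeSeries(
        metabolite=series.metabolite,
        stratum=stratum,
        reference_time_h=reference_time_h,
        table=series.table,
        excluded_subjects=excluded,
    )


def peak_nadir(
    series: RelativeChangeSeries,
) -> tuple[tuple[float, float], tuple[float, float]]:
    """Largest rise and largest fall over post-reference timepoints.

    Returns ((t_peak, max_pct), (t_nadir, min_pct)); ties break toward the
    earliest timepoint.
    """
    post = series.table[series.table["time_h"] > series.reference_time_h]
    if len(post) < 2:
        raise ValidationError("need at least 2 post-reference timepoints")
    pct = post["pct_change"].to_numpy()
    t = post["time_h"].to_numpy()
    i_max = int(np.argmax(pct))  # argmax/argmin take the first occurrence
    i_min = int(np.argmin(pct))
    return (
        (float(t[i_max]), float(pct[i_max])),
        (float(t[i_min]), float(pct[i_min])),
    )


def stratify_by_sex(
    panel: PanelMatrix,
    design: StudyDesign,
    reference_time_h: float = 0.0,
    z: float = DEFAULT_Z,
) -> dict[str, RelativeChangeSeries | None]:
    """Relative-change series for the pooled cohort and each sex stratum.

    A stratum with fewer than 2 subjects is flagged (None) rather than
    computed.
    """
    sex_of = design.sex_of
    missing = [s for s in panel.subjects if s not in sex_of]
    if missing:
        raise ValidationError(f"design lacks sex for subjects: {missing}")
    out: dict[str, RelativeChangeSeries | None] = {
        "all": relative_change(panel, reference_time_h, z=z, stratum="all")
    }
    for sex in ("male", "female"):
        members = [s for s in panel.subjects if sex_of[s] == sex]
        if len(members) < 2:
            out[sex] = None
            continue
        sub = PanelMatrix(
            metabolite=panel.metabolite, values=panel.values.loc[members]
        )
        out[sex] = relative_change(sub, reference_time_h, z=z, stratum=sex)
    return out
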