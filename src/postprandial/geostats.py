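"""Geometric summary statistics for log-normal biomarkers.

Circulating metabolite concentrations are strictly positive and typically
right-skewed, so location and spread are summarised on the log scale and
back-transformed: the geometric mean (gMean), the geometric standard
deviation (gSD, a multiplicative factor >= 1), the geometric standard error
gSE = gSD**(1/sqrt(n)), and 95% geometric confidence intervals
gCI = gMean x/ gSE**z with z = 1.96.

Natural logarithms are used throughout and the log-scale sample SD uses the
n-1 denominator; both conventions are load-bearing for the sample-size
arithmetic in :mod:`postprandial.precision`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

#: z-multiplier for 95% intervals.
DEFAULT_Z = 1.96


def _as_positive_array(values: Sequence[float], min_n: int = 1) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < min_n:
        raise ValidationError(
            f"need at least {min_n} value(s), got {arr.size}"
        )
    if np.any(~np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValidationError(f"non-finite concentration at position {bad}")
    if np.any(arr <= 0):
        bad = int(np.flatnonzero(arr <= 0)[0])
        raise ValidationError(
            f"non-positive concentration {arr[bad]!r} at position {bad}; "
            "concentrations must be > 0"
        )
    return arr


def gmean(values: Sequence[float]) -> float:
    """Geometric mean: exp of the arithmetic mean of natural-log values."""
    arr = _as_positive_array(values, min_n=1)
    return float(np.exp(np.mean(np.log(arr))))


def gsd(values: Sequence[float]) -> float:
    """Geometric SD: exp of the n-1 sample SD of natural-log values (>= 1)."""
    arr = _as_positive_array(values, min_n=2)
    return float(np.exp(np.std(np.log(arr), ddof=1)))


def gse(gsd_value: float, n: int) -> float:
    """Geometric standard error ``gsd ** (1/sqrt(n))``.

    Equals ``gsd`` at n = 1 and tends to 1 as n grows; it is the
    multiplicative uncertainty of the gMean.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    if gsd_value < 1:
        raise ValidationError(f"gsd must be >= 1, got {gsd_value}")
    return float(gsd_value ** (1.0 / np.sqrt(n)))


def gci(values: Sequence[float], z: float = DEFAULT_Z) -> tuple[float, float]:
    """Geometric confidence interval ``(gmean / gse**z, gmean * gse**z)``.

    Symmetric about ln(gMean) on the log scale.
    """
    arr = _as_positive_array(values, min_n=2)
    gm = gmean(arr)
    half = gse(gsd(arr), arr.size) ** z
    return (gm / half, gm * half)


@dataclass(frozen=True)
class GeometricSummary:
    """Geometric description of one metabolite x timepoint cell.

    ``gse``/``ci_low``/``ci_high`` are NaN when fewer than two values are
    available (the cell is flagged rather than rejected).
    """

    n: int
    gmean: float
    gsd: float
    gse: float
    ci_low: float
    ci_high: float
    minimum: float
    maximum: float


def summarize_values(values: Sequence[float], z: float = DEFAULT_Z) -> GeometricSummary:
    """Full geometric summary of one sample of positive concentrations."""
    arr = _as_positive_array(values, min_n=1)
    gm = gmean(arr)
    if arr.size >= 2:
        sd = gsd(arr)
        se = gse(sd, arr.size)
        lo, hi = gm / se**z, gm * se**z
    else:
        sd, se, lo, hi = np.nan, np.nan, np.nan, np.nan
    return GeometricSummary(
        n=int(arr.size),
        gmean=gm,
        gsd=float(sd),
        gse=float(se),
        ci_low=float(lo),
        ci_high=float(hi),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
    )


def summarize_panel(panel, z: float = DEFAULT_Z) -> pd.DataFrame:
    """Per-timepoint geometric summaries of a :class:`~postprandial.io.PanelMatrix`.

    Missing cells are dropped per timepoint, so n varies across columns
    (participants who withdrew contribute wherever they were observed).
    Timepoints with fewer than two observations get NaN gse/ci bounds.
    """
    rows = []
    for t in panel.timepoints_h:
        col = panel.values[t].dropna().to_numpy()
        if col.size == 0:
            raise ValidationError(
                f"timepoint {t} h of {panel.metabolite!r} has no observations"
            )
        s = summarize_values(col, z=z)
        rows.append(
            {
                "metabolite": panel.metabolite,
                "time_h": t,
                "n": s.n,
                "gmean": s.gmean,
                "gsd": s.gsd,
                "gse": s.gse,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "min": s.minimum,
                "max": s.maximum,
            }
        )
    return pd.DataFrame(rows)
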