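"""Synthetic postprandial/fasting metabolite time-courses with known truth.

The generator emulates a meal-challenge study: a fixed cohort (default 34
subjects, 18 male / 16 female) is sampled at a pre-meal reference (0 h) and
13 post-meal timepoints out to 24 h. Each metabolite follows a log-normal
two-way random-effects model with no interaction,

    ln y_ij = m(t_j) + sex_shift * 1[male] + b_i + u_j + e_ij,

with subject intercepts b_i ~ N(0, sigma_subject^2), timepoint effects
u_j ~ N(0, sigma_time^2) and residuals e_ij ~ N(0, sigma_residual^2) — the
exact model under which the two-way absolute-agreement ICC is defined, so
reliability estimates can be checked against ground truth.

The mean trajectory m(t) = ln(baseline_gmean) + amplitude * s(t) uses a small
shape library covering the qualitative families seen in postprandial data:
an early absorption peak, a late (fasting-driven) rise, a dip followed by a
rise, a monotone decline, and a flat profile. Every shape satisfies
s(0) = 0, so the pre-meal sample is the reference level.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import LONG_COLUMNS, PanelMatrix

#: 0 h pre-meal reference plus 13 post-meal draws (15/30/45/60/90 min, then
#: 2, 3, 4, 6, 8, 10, 12 and 24 h), in decimal hours.
DEFAULT_TIMEPOINTS_H = (
    0.0, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0, 24.0
)

#: Fraction of the (unit) late ramp used as the depth of the early dip in the
#: dip_then_rise shape.
DIP_DEPTH = 0.5

SHAPES = ("early_peak", "late_rise", "dip_then_rise", "decline", "flat")


@dataclass(frozen=True)
class StudyDesign:
    """Cohort and sampling grid of a meal-challenge study."""

    subject_ids: tuple[str, ...]
    sexes: tuple[str, ...]
    timepoints_h: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.subject_ids) != len(set(self.subject_ids)):
            raise ValidationError("subject ids must be unique")
        if len(self.sexes) != len(self.subject_ids):
            raise ValidationError("one sex label per subject required")
        t = np.asarray(self.timepoints_h, dtype=float)
        if t.size == 0 or t[0] != 0.0:
            raise ValidationError("first timepoint must be the 0 h reference")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("timepoints must be strictly increasing")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def sex_of(self) -> dict[str, str]:
        return dict(zip(self.subject_ids, self.sexes))


def make_design(
    n_male: int = 18,
    n_female: int = 16,
    timepoints_h: Sequence[float] = DEFAULT_TIMEPOINTS_H,
) -> StudyDesign:
    """Deterministic study design with stable, enumerated subject ids."""
    if n_male < 1 or n_female < 1:
        raise ValidationError("need at least one subject of each sex")
    width = len(str(max(n_male, n_female)))
    ids = [f"M{i + 1:0{width}d}" for i in range(n_male)]
    ids += [f"F{i + 1:0{width}d}" for i in range(n_female)]
    sexes = ["male"] * n_male + ["female"] * n_female
    return StudyDesign(
        subject_ids=tuple(ids),
        sexes=tuple(sexes),
        timepoints_h=tuple(float(t) for t in timepoints_h),
    )


@dataclass(frozen=True)
class TrajectoryProfile:
    """Ground-truth generating parameters for one metabolite.

    ``amplitude`` is the log-scale effect size: the shape function s(t) has
    unit scale, so exp(amplitude) is the peak fold-change for early_peak and
    the 24 h fold-change for late_rise/decline. ``sex_shift`` is a log-scale
    intercept offset applied to males (levels differ; within-subject relative
    changes do not). Variances are log-scale.
    """

    metabolite: str
    baseline_gmean: float
    shape: str = "flat"
    amplitude: float = 0.0
    t_peak_h: float | None = None
    t_onset_h: float | None = None
    t_end_h: float = 24.0
    sigma_subject: float = 0.0
    sigma_time: float = 0.0
    sigma_residual: float = 0.0
    sex_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.baseline_gmean <= 0:
            raise ValidationError("baseline_gmean must be > 0")
        if self.shape not in SHAPES:
            raise ValidationError(f"unknown shape {self.shape!r}; one of {SHAPES}")
        if min(self.sigma_subject, self.sigma_time, self.sigma_residual) < 0:
            raise ValidationError("variance components must be >= 0")
        if self.shape in ("early_peak", "dip_then_rise") and not self.t_peak_h:
            raise ValidationError(f"shape {self.shape!r} requires t_peak_h > 0")
        if self.shape in ("late_rise", "dip_then_rise") and self.t_onset_h is None:
            raise ValidationError(f"shape {self.shape!r} requires t_onset_h")

    @property
    def implied_icc(self) -> float:
        """Population ICC of the two-way model these parameters induce."""
        num = self.sigma_subject**2
        den = num + self.sigma_time**2 + self.sigma_residual**2
        return num / den if den > 0 else 0.0


def _hump(t: np.ndarray, t_peak: float) -> np.ndarray:
    # absorption-elimination hump with unit maximum at t_peak, 0 at t=0
    x = t / t_peak
    return x * np.exp(1.0 - x)


def _ramp(t: np.ndarray, t_onset: float, t_end: float) -> np.ndarray:
    # 0 until onset, then linear to exactly 1 at t_end
    return np.clip((t - t_onset) / (t_end - t_onset), 0.0, 1.0)


def shape_function(profile: TrajectoryProfile, t) -> np.ndarray:
    """Unit-scale trajectory shape s(t); s(0) = 0 for every shape."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValidationError("time must be >= 0")
    if profile.shape == "flat":
        return np.zeros_like(t)
    if profile.shape == "early_peak":
        return _hump(t, profile.t_peak_h)
    if profile.shape == "late_rise":
        return _ramp(t, profile.t_onset_h, profile.t_end_h)
    if profile.shape == "decline":
        onset = profile.t_onset_h or 0.0
        return -_ramp(t, onset, profile.t_end_h)
    # dip_then_rise: negative early lobe plus the late ramp
    return (
        _ramp(t, profile.t_onset_h, profile.t_end_h)
        - DIP_DEPTH * _hump(t, profile.t_peak_h)
    )


def trajectory_mean(profile: TrajectoryProfile, t) -> np.ndarray:
    """Log-scale population mean m(t) = ln(baseline) + amplitude * s(t)."""
    s = shape_function(profile, t)
    return np.log(profile.baseline_gmean) + profile.amplitude * s


def _metabolite_rng(seed: int, metabolite: str) -> np.random.Generator:
    # independent stream per metabolite: adding one never perturbs the others
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(metabolite.encode())])
    )


def simulate_panel(
    profile: TrajectoryProfile,
    design: StudyDesign,
    rng: np.random.Generator,
) -> PanelMatrix:
    """One metabolite's subjects x timepoints panel under the two-way model."""
    t = np.asarray(design.timepoints_h)
    m = trajectory_mean(profile, t)
    male = np.array([s == "male" for s in design.sexes], dtype=float)
    b = rng.normal(0.0, profile.sigma_subject, size=design.n_subjects)
    u = rng.normal(0.0, profile.sigma_time, size=t.size)
    eps = rng.normal(0.0, profile.sigma_residual, size=(design.n_subjects, t.size))
    log_y = (
        m[None, :]
        + profile.sex_shift * male[:, None]
        + b[:, None]
        + u[None, :]
        + eps
    )
    values = pd.DataFrame(np.exp(log_y), index=list(design.subject_ids), columns=t)
    return PanelMatrix(metabolite=profile.metabolite, values=values)


def simulate_study(
    profiles: Iterable[TrajectoryProfile],
    design: StudyDesign,
    seed: int,
    dropout: bool = False,
) -> pd.DataFrame:
    """Long-format dataset for all profiles; identical seed, identical bytes.

    With ``dropout=True`` the last-enumerated subject is truncated after the
    first eight blood collection timepoints (through 3 h on the default
    grid), mimicking a participant who withdrew early in the visit but
    remains in the available-case analyses.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("at least one trajectory profile required")
    frames = []
    for profile in profiles:
        rng = _metabolite_rng(seed, profile.metabolite)
        panel = simulate_panel(profile, design, rng)
        long = (
            panel.values.rename_axis("subject_id")
            .reset_index()
            .melt(id_vars="subject_id", var_name="time_h", value_name="concentration")
        )
        long["metabolite"] = profile.metabolite
        frames.append(long)
    out = pd.concat(frames, ignore_index=True)
    out["time_h"] = out["time_h"].astype(float)
    out["sex"] = out["subject_id"].map(design.sex_of)
    if dropout:
        truncated = design.subject_ids[-1]
        kept_times = design.timepoints_h[:8]
        out = out[
            (out["subject_id"] != truncated) | out["time_h"].isin(kept_times)
        ]
    return (
        out.loc[:, list(LONG_COLUMNS)]
        .sort_values(["metabolite", "subject_id", "time_h"], kind="stable")
        .reset_index(drop=True)
    )


def reference_gsd_table(
    n_metabolites: int = 132,
    n_timepoints: int = 56,
    gsd_range: tuple[float, float] = (1.1067, 1.3733),
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic metabolite x timepoint table of geometric SDs.

    A stand-in for a public challenge-study precision table used to calibrate
    expected spread when planning sample size; defaults give the 132 x 56 =
    7392-cell shape. Values are drawn uniformly within ``gsd_range``; the
    default range is solved in closed form so the cell distribution has
    median 1.24 and 80th percentile 1.32, the spread typical of metabolite
    panels across metabolic challenges (median + 0.5R and + 0.8R of a
    uniform with width R = 0.2667 starting at 1.1067).
    """
    low, high = gsd_range
    if not (1.0 < low <= high):
        raise ValidationError("gsd_range must satisfy 1 < low <= high")
    if n_metabolites < 1 or n_timepoints < 1:
        raise ValidationError("table dimensions must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x67736474]))
    vals = rng.uniform(low, high, size=(n_metabolites, n_timepoints))
    return pd.DataFrame(
        vals,
        index=[f"met_{i + 1:03d}" for i in range(n_metabolites)],
        columns=[f"t{j + 1:02d}" for j in range(n_timepoints)],
    )


def default_profiles() -> list[TrajectoryProfile]:
    """Profile library emulating the main postprandial trajectory families.

    Amplitudes reproduce representative reported peak magnitudes (a +41.8%
    glucose peak at 15 min; leucine rising +37.2% by 24 h of fasting;
    homocysteine dipping after the meal then climbing ~11% by 24 h; proline's
    large early peak; a pyridoxal-5'-phosphate decline). Variance components
    put implied ICCs in the 0.5-0.8 band typical of these biomarkers.
    """
    return [
        TrajectoryProfile(
            metabolite="glucose", baseline_gmean=5.0, shape="early_peak",
            amplitude=float(np.log(1.418)), t_peak_h=0.25,
            sigma_subject=0.06, sigma_time=0.01, sigma_residual=0.05,
        ),
        TrajectoryProfile(
            metabolite="leucine", baseline_gmean=140.0, shape="late_rise",
            amplitude=float(np.log(1.372)), t_onset_h=6.0,
            sigma_subject=0.12, sigma_time=0.02, sigma_residual=0.11,
            sex_shift=float(np.log(1.10)),
        ),
        TrajectoryProfile(
            metabolite="homocysteine", baseline_gmean=9.0, shape="dip_then_rise",
            amplitude=float(np.log(1.114)), t_peak_h=0.75, t_onset_h=3.0,
            sigma_subject=0.18, sigma_time=0.02, sigma_residual=0.08,
            sex_shift=float(np.log(1.08)),
        ),
        TrajectoryProfile(
            metabolite="proline", baseline_gmean=180.0, shape="early_peak",
            amplitude=float(np.log(1.555)), t_peak_h=1.5,
            sigma_subject=0.14, sigma_time=0.03, sigma_residual=0.12,
            sex_shift=float(np.log(1.07)),
        ),
        TrajectoryProfile(
            metabolite="plp", baseline_gmean=45.0, shape="decline",
            amplitude=float(np.log(1.0 / 0.804)),
            sigma_subject=0.25, sigma_time=0.02, sigma_residual=0.10,
        ),
    ]


def profile_with_icc(
    base: TrajectoryProfile, icc: float, total_var: float = 0.2
) -> TrajectoryProfile:
    """Rescale a profile's variance components to a target population ICC.

    The non-subject variance is split 1:3 between timepoint and residual;
    total log-scale variance is held at ``total_var``.
    """
    if not 0.0 <= icc < 1.0:
        raise ValidationError("target ICC must be in [0, 1)")
    var_s = icc * total_var
    rest = (1.0 - icc) * total_var
    return replace(
        base,
        sigma_subject=float(np.sqrt(var_s)),
        sigma_time=float(np.sqrt(0.25 * rest)),
        sigma_residual=float(np.sqrt(0.75 * rest)),
    )
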