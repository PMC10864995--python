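"""Long-format dataset I/O and the per-metabolite panel container.

The interchange format is a delimited text file (comma by default, tab
accepted) with header columns ``subject_id, sex, metabolite, time_h,
concentration``. Time is encoded in decimal hours (0.25 = 15 min); a
``time_min`` column is accepted on read and converted explicitly. All
downstream stages operate on :class:`PanelMatrix`, a subjects x timepoints
matrix for one metabolite with NaN marking missing cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

LONG_COLUMNS = ("subject_id", "sex", "metabolite", "time_h", "concentration")
SEX_LABELS = ("male", "female")


@dataclass
class PanelMatrix:
    """Subjects x timepoints concentration matrix for one metabolite.

    ``values`` is indexed by subject id with float timepoint (hours) columns,
    both sorted; missing cells are NaN and the mask is ``values.notna()``.
    """

    metabolite: str
    values: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValidationError("panel row/column labels must be unique")
        self.values = self.values.sort_index()
        self.values = self.values[sorted(self.values.columns)]
        present = self.values.to_numpy()
        if np.any(present[np.isfinite(present)] <= 0):
            raise ValidationError(
                f"panel {self.metabolite!r} contains non-positive concentrations"
            )

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    @property
    def timepoints_h(self) -> list[float]:
        return [float(t) for t in self.values.columns]

    @property
    def mask(self) -> pd.DataFrame:
        """True where a concentration is present."""
        return self.values.notna()

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_timepoints(self) -> int:
        return self.values.shape[1]


def read_long(path, delimiter: str | None = None) -> pd.DataFrame:
    """Read and validate a long-format dataset.

    Malformed rows (non-positive concentration, unknown sex label, duplicate
    (subject, metabolite, time) keys) are reported together with their
    1-based file line numbers.
    """
    sep = delimiter
    if sep is None:
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                if not line.startswith("#"):
                    sep = "\t" if "\t" in line else ","
                    break
    df = pd.read_csv(path, sep=sep, comment="#", dtype={"subject_id": str})
    if "time_min" in df.columns and "time_h" not in df.columns:
        df["time_h"] = df.pop("time_min").astype(float) / 60.0
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    df = df.loc[:, list(LONG_COLUMNS)]

    problems: list[str] = []
    lineno = df.index.to_numpy() + 2  # header is line 1
    conc = pd.to_numeric(df["concentration"], errors="coerce")
    for i in np.flatnonzero(~(conc > 0)):
        problems.append(
            f"line {lineno[i]}: concentration must be > 0, got "
            f"{df['concentration'].iloc[i]!r}"
        )
    for i in np.flatnonzero(~df["sex"].isin(SEX_LABELS)):
        problems.append(
            f"line {lineno[i]}: unknown sex label {df['sex'].iloc[i]!r} "
            f"(expected one of {SEX_LABELS})"
        )
    time = pd.to_numeric(df["time_h"], errors="coerce")
    for i in np.flatnonzero(~(time >= 0)):
        problems.append(f"line {lineno[i]}: time_h must be >= 0")
    dup = df.duplicated(subset=["subject_id", "metabolite", "time_h"], keep="first")
    for i in np.flatnonzero(dup.to_numpy()):
        problems.append(
            f"line {lineno[i]}: duplicate record for "
            f"({df['subject_id'].iloc[i]}, {df['metabolite'].iloc[i]}, "
            f"{df['time_h'].iloc[i]})"
        )
    if problems:
        raise ValidationError(
            f"{path}: {len(problems)} invalid record(s):\n" + "\n".join(problems)
        )
    df["time_h"] = time
    df["concentration"] = conc
    return df.reset_index(drop=True)


def write_long(df: pd.DataFrame, path, delimiter: str = ",") -> None:
    """Write a long-format dataset with a fixed column order."""
    df.loc[:, list(LONG_COLUMNS)].to_csv(path, sep=delimiter, index=False)


def pivot(dataset: pd.DataFrame, metabolite: str) -> PanelMatrix:
    """Extract one metabolite's subjects x timepoints panel.

    Subject and timepoint order are deterministic (sorted); absent cells are
    masked rather than imputed.
    """
    sub = dataset[dataset["metabolite"] == metabolite]
    if sub.empty:
        available = sorted(dataset["metabolite"].unique())
        raise ValidationError(
            f"metabolite {metabolite!r} not in dataset; available: {available}"
        )
    wide = sub.pivot(index="subject_id", columns="time_h", values="concentration")
    wide.columns = [float(c) for c in wide.columns]
    return PanelMatrix(metabolite=metabolite, values=wide)


def sex_map(dataset: pd.DataFrame) -> dict[str, str]:
    """Subject id -> sex label, checked for consistency across records."""
    per = dataset.groupby("subject_id")["sex"].unique()
    bad = per[per.str.len() > 1]
    if not bad.empty:
        raise ValidationError(
            f"subjects with conflicting sex labels: {list(bad.index)}"
        )
    return {s: v[0] for s, v in per.items()}


def flatten(panel: PanelMatrix, sexes: dict[str, str]) -> pd.DataFrame:
    """Inverse of :func:`pivot`: long records for the panel's observed cells."""
    long = (
        panel.values.rename_axis("subject_id")
        .reset_index()
        .melt(id_vars="subject_id", var_name="time_h", value_name="concentration")
        .dropna(subset=["concentration"])
    )
    long["time_h"] = long["time_h"].astype(float)
    long["metabolite"] = panel.metabolite
    long["sex"] = long["subject_id"].map(sexes)
    return (
        long.loc[:, list(LONG_COLUMNS)]
        .sort_values(["subject_id", "time_h"], kind="stable")
        .reset_index(drop=True)
    )
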