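"""Accuracy-in-parameter-estimation (AIPE) sample-size planning.

Instead of powering a hypothesis test, AIPE sizes a study so the estimate is
precise: here, so the 95% geometric confidence interval of a gMean is
narrow. The half-width factor of that interval is the multiplicative
margin of error MoE = gSE**z, with gSE = gSD**(1/sqrt(n)), so requiring
MoE < 1.10 at z = 1.96 is the same as requiring gSE < 1.05, and the sample
size solving gSD**(1/sqrt(n)) = gSE_max is

    n = (ln gSD / ln gSE_max)**2.

Planning needs an expected gSD; that is taken from a reference precision
table (metabolite x timepoint gSDs from a prior challenge study), and the
spread of achievable MoE across such a table is explored by a bootstrap:
for each cell and replication, draw n values and record the realised MoE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geostats import DEFAULT_Z


@dataclass(frozen=True)
class PrecisionDesign:
    """The AIPE planning record: bounds, planning gSD and required n."""

    gsd_plan: float
    z: float
    moe_max: float
    gse_max: float
    n_required: int
    rounding_rule: str
    warning: str | None = None


def moe_from_gse(gse: float, z: float = DEFAULT_Z) -> float:
    """Multiplicative margin of error gse**z (the gCI half-width factor)."""
    if gse < 1:
        raise ValidationError(f"gse must be >= 1, got {gse}")
    if z <= 0:
        raise ValidationError(f"z must be > 0, got {z}")
    return float(gse**z)


def gse_bound_from_moe(moe_max: float, z: float = DEFAULT_Z) -> float:
    """gSE bound equivalent to a MoE bound: moe_max**(1/z)."""
    if moe_max <= 1:
        raise ValidationError(f"moe_max must be > 1, got {moe_max}")
    if z <= 0:
        raise ValidationError(f"z must be > 0, got {z}")
    return float(moe_max ** (1.0 / z))


def required_n(
    gsd_plan: float, gse_max: float, rounding_rule: str = "nearest"
) -> tuple[int, str | None]:
    """Sample size achieving gSE <= gse_max under planning spread gsd_plan.

    n_exact = (ln gsd_plan / ln gse_max)**2, integerised per rounding_rule
    ('nearest' or 'up'). If one observation already meets the bound
    (gse_max >= gsd_plan), returns 1 with a warning flag.
    """
    if gsd_plan <= 1:
        raise ValidationError(f"gsd_plan must be > 1, got {gsd_plan}")
    if gse_max <= 1:
        raise ValidationError(f"gse_max must be > 1, got {gse_max}")
    if rounding_rule not in ("nearest", "up"):
        raise ValidationError(f"unknown rounding rule {rounding_rule!r}")
    n_exact = (math.log(gsd_plan) / math.log(gse_max)) ** 2
    if n_exact <= 1:
        return 1, "a single observation already meets the precision bound"
    n = round(n_exact) if rounding_rule == "nearest" else math.ceil(n_exact)
    return int(max(n, 1)), None


def plan(
    gsd_plan: float,
    moe_max: float | None = None,
    gse_max: float | None = None,
    z: float = DEFAULT_Z,
    rounding_rule: str = "nearest",
) -> PrecisionDesign:
    """Build the full AIPE design from either bound (they are equivalent)."""
    if (moe_max is None) == (gse_max is None):
        raise ValidationError("specify exactly one of moe_max or gse_max")
    if gse_max is None:
        gse_max = gse_bound_from_moe(moe_max, z)
    else:
        moe_max = moe_from_gse(gse_max, z)
    n, warning = required_n(gsd_plan, gse_max, rounding_rule)
    return PrecisionDesign(
        gsd_plan=gsd_plan,
        z=z,
        moe_max=moe_max,
        gse_max=gse_max,
        n_required=n,
        rounding_rule=rounding_rule,
        warning=warning,
    )


def inflate_for_dropout(n_required: int, dropout_rate: float) -> int:
    """Recruitment target so that n_required complete after expected dropout."""
    if not 0.0 <= dropout_rate < 1.0:
        raise ValidationError(f"dropout_rate must be in [0, 1), got {dropout_rate}")
    return int(math.ceil(n_required / (1.0 - dropout_rate)))


def precision_curve(
    gsd_plan: float, n_grid, z: float = DEFAULT_Z
) -> pd.DataFrame:
    """MoE as a function of sample size: moe(n) = gsd_plan**(z/sqrt(n))."""
    n = np.asarray(list(n_grid), dtype=int)
    if n.size == 0:
        raise ValidationError("n_grid must be non-empty")
    if np.any(np.diff(n) <= 0) or n[0] < 1:
        raise ValidationError("n_grid must be ascending positive integers")
    if gsd_plan < 1:
        raise ValidationError(f"gsd_plan must be >= 1, got {gsd_plan}")
    moe = gsd_plan ** (z / np.sqrt(n))
    return pd.DataFrame({"n": n, "moe": moe})


@dataclass(frozen=True)
class MoeDistribution:
    """Pooled bootstrap distribution of the realised margin of error."""

    moes: np.ndarray
    n: int
    reps: int
    n_cells: int
    z: float
    mode: str

    @property
    def n_estimates(self) -> int:
        return int(self.moes.size)

    def quantiles(self, probs=(0.05, 0.25, 0.5, 0.75, 0.8, 0.95)) -> dict[float, float]:
        qs = np.quantile(self.moes, list(probs))  # linear interpolation
        return {float(p): float(q) for p, q in zip(probs, qs)}

    def fraction_within(self, moe_max: float) -> float:
        """Share of simulated estimates meeting the MoE bound."""
        return float(np.mean(self.moes <= moe_max))


def bootstrap_moe_distribution(
    reference,
    n: int,
    reps: int,
    z: float = DEFAULT_Z,
    seed: int = 0,
) -> MoeDistribution:
    """Simulate the MoE distribution at sample size n over a reference table.

    Two reference modes:

    * raw mode — ``reference`` is a mapping of cell label -> array of raw
      positive measurements; each replication resamples n values with
      replacement (nonparametric bootstrap).
    * gSD-table mode — ``reference`` is a DataFrame/array of per-cell gSD
      values; each replication draws a parametric log-normal sample of size
      n with that cell's gSD (the stand-in when raw reference data are not
      at hand).

    Each of cells x reps draws yields one gSE = gSD_hat**(1/sqrt(n)) and one
    MoE = gSE**z; the pooled distribution is returned. Cell-level streams
    are split from the seed, independent of iteration order.
    """
    if reps < 1:
        raise ValidationError(f"reps must be >= 1, got {reps}")
    if n < 2:
        raise ValidationError(f"n must be >= 2, got {n}")
    if isinstance(reference, dict):
        mode = "raw"
        cells = list(reference.items())
        if not cells:
            raise ValidationError("empty reference")
        for label, vals in cells:
            arr = np.asarray(vals, dtype=float)
            if arr.size < 2 or np.any(arr <= 0):
                raise ValidationError(
                    f"reference cell {label!r} needs >= 2 positive values"
                )
    else:
        mode = "gsd_table"
        table = np.asarray(
            reference.to_numpy() if isinstance(reference, pd.DataFrame) else reference,
            dtype=float,
        ).ravel()
        if table.size == 0:
            raise ValidationError("empty reference")
        if np.any(table < 1):
            raise ValidationError("gSD table values must be >= 1")

    root = np.random.SeedSequence([seed, 0x6D6F65])
    if mode == "raw":
        streams = root.spawn(len(cells))
        moes = np.empty(len(cells) * reps)
        pos = 0
        for (label, vals), ss in zip(cells, streams):
            arr = np.asarray(vals, dtype=float)
            rng = np.random.default_rng(ss)
            idx = rng.integers(0, arr.size, size=(reps, n))
            logs = np.log(arr)[idx]
            gsd_hat = np.exp(np.std(logs, axis=1, ddof=1))
            moes[pos : pos + reps] = gsd_hat ** (z / np.sqrt(n))
            pos += reps
    else:
        rng = np.random.default_rng(root)
        sigma = np.log(table)  # log-scale SD per cell
        draws = rng.standard_normal(size=(table.size, reps, n))
        sd_hat = np.std(draws * sigma[:, None, None], axis=2, ddof=1)
        moes = np.exp(sd_hat / np.sqrt(n) * z).ravel()
    return MoeDistribution(
        moes=moes,
        n=n,
        reps=reps,
        n_cells=len(cells) if mode == "raw" else table.size,
        z=z,
        mode=mode,
    )


def gsd_table_quantiles(reference, probs) -> dict[float, float]:
    """Empirical quantiles over all cells of a gSD table.

    Uses numpy's default linear interpolation between order statistics.
    """
    table = np.asarray(
        reference.to_numpy() if isinstance(reference, pd.DataFrame) else reference,
        dtype=float,
    ).ravel()
    if table.size == 0:
        raise ValidationError("empty table")
    probs = list(probs)
    if any(not 0.0 <= p <= 1.0 for p in probs):
        raise ValidationError("probs must lie in [0, 1]")
    qs = np.quantile(table, probs)
    return {float(p): float(q) for p, q in zip(probs, qs)}
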