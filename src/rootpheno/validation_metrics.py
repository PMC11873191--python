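"""Agreement statistics for trait tables: RMSE, MBE, and R-squared.

Conventions: in a :class:`PairedSeries`, ``observed`` holds the algorithm's
values and ``standard`` the reference values; MBE = mean(observed -
standard), so a negative MBE means the algorithm underestimates.
R-squared defaults to squared Pearson correlation; a regression variant
(coefficient of determination of the fitted line) is available for
comparison since either reading matches published fit-of-plot figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, UndefinedTraitError

__all__ = ["PairedSeries", "rmse", "mbe", "r_squared", "compare_tables"]


@dataclass(frozen=True)
class PairedSeries:
    """Paired algorithm/reference measurements for one trait."""

    observed: np.ndarray
    standard: np.ndarray
    trait_name: str = ""

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=np.float64)
        std = np.asarray(self.standard, dtype=np.float64)
        if obs.ndim != 1 or std.ndim != 1:
            raise InvalidArgumentError("paired series must be one-dimensional")
        if obs.shape != std.shape:
            raise InvalidArgumentError(
                f"paired series lengths differ: {obs.size} vs {std.size}"
            )
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "standard", std)

    @property
    def n(self) -> int:
        return self.observed.size


def rmse(p: PairedSeries) -> float:
    """Root mean squared difference sqrt(mean((o_i - s_i)^2))."""
    if p.n == 0:
        raise InvalidArgumentError("RMSE is undefined for an empty series")
    return float(np.sqrt(np.mean((p.observed - p.standard) ** 2)))


def mbe(p: PairedSeries) -> float:
    """Mean bias error mean(o_i - s_i); negative = underestimation."""
    if p.n == 0:
        raise InvalidArgumentError("MBE is undefined for an empty series")
    return float(np.mean(p.observed - p.standard))


def r_squared(
    p: PairedSeries, mode: Literal["pearson", "regression"] = "pearson"
) -> float:
    """Agreement R² between observed and standard values.

    ``pearson`` (default): squared Pearson correlation of the pairs.
    ``regression``: coefficient of determination of the least-squares line
    observed ~ standard (identical to Pearson² for simple linear
    regression with intercept; kept as an explicit mode for clarity).
    """
    if p.n < 2:
        raise InvalidArgumentError("R-squared needs at least 2 pairs")
    o, s = p.observed, p.standard
    if np.ptp(o) == 0 or np.ptp(s) == 0:
        raise UndefinedTraitError("R-squared is undefined for a constant series")
    if mode == "pearson":
        r = np.corrcoef(o, s)[0, 1]
        return float(r * r)
    if mode == "regression":
        slope, intercept = np.polyfit(s, o, 1)
        pred = slope * s + intercept
        ss_res = float(np.sum((o - pred) ** 2))
        ss_tot = float(np.sum((o - o.mean()) ** 2))
        return 1.0 - ss_res / ss_tot
    raise InvalidArgumentError(f"unknown R-squared mode {mode!r}")


def compare_tables(
    observed: pd.DataFrame,
    reference: pd.DataFrame,
    key: str,
    traits: Sequence[str],
    r2_mode: Literal["pearson", "regression"] = "pearson",
) -> pd.DataFrame:
    """Join two trait tables on ``key`` and report RMSE/MBE/R² per trait.

    Rows present in only one table are dropped from the comparison; R² is
    reported as NaN when fewer than 2 pairs or a constant series makes it
    undefined.
    """
    for name, df in (("observed", observed), ("reference", reference)):
        if key not in df.columns:
            raise InvalidArgumentError(f"{name} table lacks key column {key!r}")
    merged = observed.merge(reference, on=key, suffixes=("_obs", "_ref"))
    if merged.empty:
        raise InvalidArgumentError(f"no rows share a {key!r} value between the tables")
    rows: List[dict] = []
    for trait in traits:
        obs_col, ref_col = f"{trait}_obs", f"{trait}_ref"
        if obs_col not in merged.columns or ref_col not in merged.columns:
            raise InvalidArgumentError(f"trait column {trait!r} missing from one table")
        pair = PairedSeries(merged[obs_col].to_numpy(), merged[ref_col].to_numpy(), trait)
        try:
            r2 = r_squared(pair, mode=r2_mode)
        except (InvalidArgumentError, UndefinedTraitError):
            r2 = math.nan
        rows.append(
            {"trait": trait, "n": pair.n, "rmse": rmse(pair), "mbe": mbe(pair), "r2": r2}
        )
    return pd.DataFrame(rows)
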