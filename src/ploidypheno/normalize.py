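"""Internal-standard (LSC) normalization of fitness components.

Raw fitness components are converted to relative log2-scale measures by
normalizing each measurement to the replicate wells of the wild-type
reference strain cultivated on the same run:

    LSC = log2(x) - (1/K) * sum_k log2(wt_k)

where ``x`` is a strain's raw component value (lag in h, doubling time in
h, or efficiency in delta-OD) and ``wt_k`` the K same-run, same-component
reference measurements. Because any run-wide multiplicative effect enters
``x`` and every ``wt_k`` identically, it cancels exactly — this is the
whole point of carrying internal standards on every run.

Sign convention: to keep directionality consistent across components the
efficiency LSC is inverted, so for all three components a *larger LSC
means worse performance* (longer lag, slower doubling, lower yield).
``flip_sign=True`` outputs the opposite orientation ("larger = better"),
matching the usual figure convention.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .types import COMPONENTS

__all__ = ["lsc", "build_trait_matrix", "MissingStandardsError"]

_COMPONENT_COLS = {
    "lag": "lag_h",
    "rate": "doubling_time_h",
    "efficiency": "efficiency_od",
}

StandardsAgg = Literal["mean_log", "log_mean"]


class MissingStandardsError(ValueError):
    """A run has no usable internal-standard measurements for a component."""


def _standards_level(values: np.ndarray, agg: StandardsAgg) -> float:
    if agg == "mean_log":
        return float(np.mean(np.log2(values)))
    if agg == "log_mean":
        return float(np.log2(np.mean(values)))
    raise ValueError(f"unknown standards aggregation {agg!r}")


def lsc(
    x: float,
    standards: Sequence[float],
    component: str,
    agg: StandardsAgg = "mean_log",
) -> float:
    """Relative (LSC) value of one raw component measurement.

    Parameters
    ----------
    x : float
        Raw component value (> 0). NaN propagates to a NaN output.
    standards : sequence of float
        Same-run, same-component wild-type measurements; all > 0.
    component : str
        One of ``"lag"``, ``"rate"``, ``"efficiency"``. The efficiency LSC
        is sign-inverted so that larger LSC = worse performance for every
        component.
    agg : str
        ``"mean_log"`` (default; mean of log2 standards) or ``"log_mean"``
        (log2 of the standards' mean).
    """
    if component not in COMPONENTS:
        raise ValueError(f"unknown component {component!r}")
    standards = np.asarray(standards, dtype=float)
    standards = standards[~np.isnan(standards)]
    if standards.size == 0:
        raise MissingStandardsError("no usable standards")
    if np.any(standards <= 0):
        raise ValueError("standards must be > 0")
    if np.isnan(x):
        return float("nan")
    if x <= 0:
        raise ValueError(f"component value must be > 0, got {x}")
    value = float(np.log2(x)) - _standards_level(standards, agg)
    return -value if component == "efficiency" else value


def build_trait_matrix(
    components: pd.DataFrame,
    agg: StandardsAgg = "mean_log",
    flip_sign: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the strain x trait LSC matrix from a components table.

    Parameters
    ----------
    components : DataFrame
        Well-level table as produced by :func:`ploidypheno.growth.extract_table`:
        one row per culture with columns ``well_id, strain_id, ploidy,
        mating_type, environment, run_id, is_standard, lag_h,
        doubling_time_h, efficiency_od, grew``. Standards (``is_standard``)
        provide the per-run normalization level and are not themselves rows
        of the output.
    agg, flip_sign
        See :func:`lsc`.

    Returns
    -------
    matrix : DataFrame
        Rows indexed by ``(strain_id, ploidy, mating_type)``; columns a
        ``(environment, component)`` MultiIndex; cells are replicate-mean
        LSC values, NaN where a culture is missing or censored (a censored
        lag propagates as missing, never as an extreme value).
    counts : DataFrame
        Same shape; number of replicates averaged into each cell.

    Raises
    ------
    MissingStandardsError
        If any run containing sample cultures lacks usable standards for a
        needed component; the error names the run.
    """
    required = {
        "well_id", "strain_id", "ploidy", "mating_type", "environment",
        "run_id", "is_standard", "lag_h", "doubling_time_h", "efficiency_od", "grew",
    }
    missing_cols = required - set(components.columns)
    if missing_cols:
        raise ValueError(f"components table missing columns: {sorted(missing_cols)}")

    df = components.copy()
    # Censored / non-grown cultures contribute no lag or rate value.
    not_grew = ~df["grew"].astype(bool)
    df.loc[not_grew, ["lag_h", "doubling_time_h"]] = np.nan

    std = df[df["is_standard"].astype(bool)]
    samples = df[~df["is_standard"].astype(bool)]

    # Per (run, component) normalization level from the standards.
    levels: dict[tuple[str, str], float] = {}
    for run_id, grp in std.groupby("run_id"):
        for comp, col in _COMPONENT_COLS.items():
            vals = grp[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals) & (vals > 0)]
            if vals.size:
                levels[(run_id, comp)] = _standards_level(vals, agg)

    long_rows = []
    for comp, col in _COMPONENT_COLS.items():
        sub = samples[
            ["strain_id", "ploidy", "mating_type", "environment", "run_id", col]
        ].copy()
        key = list(zip(sub["run_id"], [comp] * len(sub)))
        level = np.array([levels.get(k, np.nan) for k in key])
        bad_runs = sorted(set(sub.loc[np.isnan(level), "run_id"]))
        if bad_runs:
            raise MissingStandardsError(
                f"run(s) without usable '{comp}' standards: {bad_runs}"
            )
        x = sub[col].to_numpy(dtype=float)
        with np.errstate(invalid="ignore", divide="ignore"):
            if np.any(x[np.isfinite(x)] <= 0):
                raise ValueError(f"non-positive {comp} value in components table")
            val = np.log2(x) - level
        if comp == "efficiency":
            val = -val
        sub["component"] = comp
        sub["lsc"] = val
        long_rows.append(sub.drop(columns=[col]))

    long = pd.concat(long_rows, ignore_index=True)
    if flip_sign:
        long["lsc"] = -long["lsc"]

    grouped = long.groupby(
        ["strain_id", "ploidy", "mating_type", "environment", "component"],
        sort=True,
    )["lsc"]
    mean = grouped.mean()
    n = grouped.count()
    matrix = mean.unstack(["environment", "component"]).sort_index(axis=1)
    counts = n.unstack(["environment", "component"]).reindex(
        index=matrix.index, columns=matrix.columns
    ).fillna(0).astype(int)
    matrix.columns.names = ["environment", "component"]
    return matrix, counts
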