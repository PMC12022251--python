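"""Quality-control flagging of implausible yield values.

Two screening rules run per statistical series (one geographic unit ×
product × season × production system):

* **High-yield outliers** (flag code 1): a year is flagged when its yield
  Z-score exceeds ``z_threshold`` standard deviations above the series
  mean *and* the value is at least ``neighbor_ratio`` (default 250%) of
  either the nearest preceding or the nearest subsequent observed yield.
  The rule is suppressed entirely unless at least one yield in the series
  exceeds ``yield_guard`` (default 0.5 t/ha): very low-yielding systems
  legitimately show high variance relative to their mean.

* **Low interannual variance** (flag code 2): repeated values, or values
  lying exactly on a linear trend, betray report recycling rather than
  measurement.  The discrete second difference d(t) = y(t+1) − 2·y(t) +
  y(t−1) is zero along any line; wherever ``run_length`` consecutive
  second differences are each smaller in magnitude than
  ``second_diff_frac`` of the series' median yield, every year spanned by
  the window is flagged.

Flags annotate; they never remove or alter the statistics themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvariantError
from .model import (
    FLAG_LOW_VARIANCE,
    FLAG_NONE,
    FLAG_OUTLIER,
    StatSeries,
    iter_series,
)


@dataclass(frozen=True)
class QCParams:
    """Tunable thresholds of the two QC rules.

    z_threshold
        Standard-deviation multiples above the mean for the outlier test.
    neighbor_ratio
        Minimum ratio of a candidate outlier to its nearest observed
        neighbour (2.5 = 250%); the test is inclusive (>=).
    yield_guard
        Outlier rule only applies if some yield in the series exceeds this
        (t/ha).
    second_diff_frac
        Low-variance band, as a fraction of the series median yield.
    run_length
        Number of consecutive sub-threshold second differences required.
    sd_ddof
        Delta degrees of freedom for the standard deviation (0 =
        population convention, the default).
    """

    z_threshold: float = 3.0
    neighbor_ratio: float = 2.5
    yield_guard: float = 0.5
    second_diff_frac: float = 0.015
    run_length: int = 3
    sd_ddof: int = 0

    def __post_init__(self) -> None:
        for name in ("z_threshold", "neighbor_ratio", "yield_guard", "second_diff_frac"):
            if getattr(self, name) <= 0:
                raise InvariantError(f"QCParams.{name} must be > 0")
        if self.run_length < 1:
            raise InvariantError("QCParams.run_length must be >= 1")


@dataclass
class FlagResult:
    """Per-year flags aligned to a series, with rule diagnostics."""

    years: np.ndarray
    flags: np.ndarray
    diagnostics: dict = field(default_factory=dict)


def _nearest_observed_neighbors(observed_idx: np.ndarray, n: int):
    """For each position, index of nearest observed position before/after
    (-1 when none exists)."""
    prev = np.full(n, -1, dtype=int)
    nxt = np.full(n, -1, dtype=int)
    obs = np.zeros(n, dtype=bool)
    obs[observed_idx] = True
    last = -1
    for i in range(n):
        prev[i] = last
        if obs[i]:
            last = i
    nxt_last = -1
    for i in range(n - 1, -1, -1):
        nxt[i] = nxt_last
        if obs[i]:
            nxt_last = i
    return prev, nxt


def flag_outliers(series: StatSeries, params: QCParams = QCParams()) -> FlagResult:
    """Apply the high-yield outlier rule to one series.

    Returns per-year flags (0 or 1) and diagnostics (``z``, ``ratio_prev``,
    ``ratio_next``).  Series with fewer than two observed yields, zero
    standard deviation, or no yield above the guard produce no flags.
    """
    y = series.yields
    n = len(y)
    flags = np.zeros(n, dtype=int)
    z = np.full(n, np.nan)
    ratio_prev = np.full(n, np.nan)
    ratio_next = np.full(n, np.nan)
    obs = np.flatnonzero(np.isfinite(y))
    diag = {"z": z, "ratio_prev": ratio_prev, "ratio_next": ratio_next}
    if len(obs) < 2 or np.nanmax(y) <= params.yield_guard:
        return FlagResult(series.years.copy(), flags, diag)
    mean = float(np.mean(y[obs]))
    sd = float(np.std(y[obs], ddof=params.sd_ddof))
    if sd == 0.0:
        return FlagResult(series.years.copy(), flags, diag)
    z[obs] = (y[obs] - mean) / sd
    prev, nxt = _nearest_observed_neighbors(obs, n)
    for i in obs:
        if prev[i] >= 0 and y[prev[i]] != 0:
            ratio_prev[i] = y[i] / y[prev[i]]
        if nxt[i] >= 0 and y[nxt[i]] != 0:
            ratio_next[i] = y[i] / y[nxt[i]]
        if z[i] <= params.z_threshold:
            continue
        anomalous = False
        if prev[i] >= 0 and y[i] >= params.neighbor_ratio * y[prev[i]]:
            anomalous = True
        if nxt[i] >= 0 and y[i] >= params.neighbor_ratio * y[nxt[i]]:
            anomalous = True
        if anomalous and (prev[i] >= 0 or nxt[i] >= 0):
            flags[i] = FLAG_OUTLIER
    return FlagResult(series.years.copy(), flags, diag)


def flag_low_variance(series: StatSeries, params: QCParams = QCParams()) -> FlagResult:
    """Apply the low-variance (repeated value / on-trend) rule to one series.

    Second differences are computed on maximal runs of *consecutively*
    observed years only; a gap in reporting breaks the run.  Overlapping
    qualifying windows merge into one flagged span.
    """
    y = series.yields
    years = series.years
    n = len(y)
    flags = np.zeros(n, dtype=int)
    second_diff = np.full(n, np.nan)
    diag = {"second_diff": second_diff}
    obs_mask = np.isfinite(y)
    if obs_mask.sum() < params.run_length + 2:
        return FlagResult(years.copy(), flags, diag)
    threshold = params.second_diff_frac * float(np.median(y[obs_mask]))

    # maximal runs of consecutive calendar years with observed yield
    obs_positions = np.flatnonzero(obs_mask)
    runs: list[list[int]] = [[int(obs_positions[0])]]
    for p in obs_positions[1:]:
        if years[p] - years[runs[-1][-1]] == 1:
            runs[-1].append(int(p))
        else:
            runs.append([int(p)])

    for run in runs:
        if len(run) < params.run_length + 2:
            continue
        vals = y[run]
        d = vals[2:] - 2 * vals[1:-1] + vals[:-2]  # centred at run[1:-1]
        for centre_pos, dval in zip(run[1:-1], d):
            second_diff[centre_pos] = dval
        small = np.abs(d) < threshold
        w = params.run_length
        for start in range(len(d) - w + 1):
            if small[start : start + w].all():
                # window of centres run[start+1 .. start+w] spans one year
                # more on each side
                flags[run[start] : run[start + w + 1] + 1] = FLAG_LOW_VARIANCE
    return FlagResult(years.copy(), flags, diag)


def combine_flags(outliers: FlagResult, low_variance: FlagResult) -> np.ndarray:
    """Merge the two rules into one code per year; outlier (1) wins over
    low variance (2) because a record carries a single integer flag."""
    return np.where(
        outliers.flags == FLAG_OUTLIER,
        FLAG_OUTLIER,
        np.where(low_variance.flags == FLAG_LOW_VARIANCE, FLAG_LOW_VARIANCE, FLAG_NONE),
    )


def apply_qc(
    records: pd.DataFrame,
    params: QCParams = QCParams(),
    return_diagnostics: bool = False,
):
    """Recompute qc_flag for every series in a records table.

    Statistic values are never modified; flags are recomputed from scratch
    (not OR-ed with pre-existing flags), so the operation is idempotent.

    Returns the flagged copy, plus a long-format diagnostics table when
    ``return_diagnostics`` is set.
    """
    out = records.copy()
    out["qc_flag"] = FLAG_NONE
    diag_rows = []
    for key, series, index in iter_series(records):
        res_out = flag_outliers(series, params)
        res_lv = flag_low_variance(series, params)
        out.loc[index, "qc_flag"] = combine_flags(res_out, res_lv)
        if return_diagnostics:
            diag_rows.append(
                pd.DataFrame(
                    {
                        "fnid": key[0],
                        "product": key[1],
                        "season_name": key[2],
                        "crop_production_system": key[3],
                        "harvest_year": series.years,
                        "z": res_out.diagnostics["z"],
                        "ratio_prev": res_out.diagnostics["ratio_prev"],
                        "ratio_next": res_out.diagnostics["ratio_next"],
                        "second_diff": res_lv.diagnostics["second_diff"],
                    }
                )
            )
    if return_diagnostics:
        diagnostics = (
            pd.concat(diag_rows, ignore_index=True)
            if diag_rows
            else pd.DataFrame(
                columns=[
                    "fnid", "product", "season_name", "crop_production_system",
                    "harvest_year", "z", "ratio_prev", "ratio_next", "second_diff",
                ]
            )
        )
        return out, diagnostics
    return out
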