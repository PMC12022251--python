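"""Cross-validation of harmonized statistics against national references.

Subnational, per-season records are summed to national annual production
per (country, product, harvest year) and correlated (Pearson) with an
independent national reference series (FAOSTAT-style).  A correlation is
only reported when at least ``min_years`` overlapping years exist (default
5) and neither series is constant; otherwise the cell is returned with the
reason it is undefined.  Because subnational calibration conserves
national totals, national-level agreement is unaffected by the boundary
calibration upstream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def national_annual_production(records: pd.DataFrame) -> pd.DataFrame:
    """Sum production over units, seasons and production systems.

    Annual assignment is by harvest year.  Years with no observed
    subnational production are absent from the result, not zero.
    Returns columns ``country_code, product, year, production``.
    """
    obs = records[records["production"].notna()]
    out = (
        obs.groupby(["country_code", "product", "harvest_year"], dropna=False)[
            "production"
        ]
        .sum()
        .reset_index()
        .rename(columns={"harvest_year": "year"})
    )
    return out


def correlate_with_reference(
    national: pd.DataFrame,
    reference: pd.DataFrame,
    min_years: int = 5,
    log: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Pearson r per (country, product) between national and reference series.

    Parameters
    ----------
    national, reference
        Tables with columns ``country_code, product, year, production``.
    min_years
        Minimum number of exactly-matching overlap years.
    log
        Correlate log-production instead of raw production (both series
        must be positive over the overlap).

    Returns the long-format table (``r`` NaN where undefined, with
    ``reason``) and a summary dict with the median r over defined cells
    and per-product medians.
    """
    rows = []
    ref_groups = {
        k: g.set_index("year")["production"]
        for k, g in reference.groupby(["country_code", "product"])
    }
    for key, g in national.groupby(["country_code", "product"]):
        series = g.set_index("year")["production"]
        ref = ref_groups.get(key)
        row = {"country_code": key[0], "product": key[1], "n_years": 0,
               "r": np.nan, "reason": ""}
        if ref is None:
            row["reason"] = "no reference series"
            rows.append(row)
            continue
        common = series.index.intersection(ref.index)
        x = series.loc[common].to_numpy(float)
        y = ref.loc[common].to_numpy(float)
        row["n_years"] = len(common)
        if len(common) < min_years:
            row["reason"] = "insufficient overlap"
        else:
            if log:
                if (x <= 0).any() or (y <= 0).any():
                    row["reason"] = "non-positive values under log"
                    rows.append(row)
                    continue
                x, y = np.log(x), np.log(y)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                row["reason"] = "constant series"
            else:
                row["r"] = float(stats.pearsonr(x, y).statistic)
        rows.append(row)
    table = pd.DataFrame(
        rows, columns=["country_code", "product", "n_years", "r", "reason"]
    )
    defined = table["r"].dropna()
    summary = {
        "median_r": float(defined.median()) if len(defined) else np.nan,
        "n_defined": int(len(defined)),
        "n_cells": int(len(table)),
        "median_r_by_product": {
            p: float(g["r"].dropna().median())
            for p, g in table.groupby("product")
            if g["r"].notna().any()
        },
    }
    return table, summary
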