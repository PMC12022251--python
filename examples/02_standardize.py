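"""Sub-crop re-aggregation and coverage-gated admin aggregation.

Folds pearl/finger millet into one continuous "millet" series, then
aggregates two districts to their region behind the 50%-of-expected-
production gate.
"""

import numpy as np
import pandas as pd

from harvstat import aggregate_admin, aggregate_subcrops
from harvstat.model import CANONICAL_COLUMNS

base = {
    "country": "Synthetica", "country_code": "SY", "admin_1": "Region 0",
    "admin_2": "D", "season_name": "annual", "planting_month": 3,
    "harvest_month": 11, "crop_production_system": "none", "qc_flag": 0,
    "yield": np.nan,
}
rows = []
for fnid, prod_60_40 in (("SY00", 60.0), ("SY01", 40.0)):
    for year in range(2000, 2006):
        for crop in ("pearl millet", "finger millet"):
            if fnid == "SY01" and year == 2005:
                continue  # the smaller district misses the last year
            rows.append({**base, "fnid": fnid, "product": crop,
                         "planting_year": year, "harvest_year": year,
                         "area": prod_60_40 / 4, "production": prod_60_40 / 2})
records = pd.DataFrame(rows, columns=CANONICAL_COLUMNS)

millet = aggregate_subcrops(records, {"pearl millet": "millet",
                                      "finger millet": "millet"})
print("sub-crops folded:", sorted(millet["product"].unique()),
      "->", len(millet), "records")

region, coverage = aggregate_admin(
    millet, {"SY00": "SYREG0", "SY01": "SYREG0"}, return_coverage=True
)
print(region[["fnid", "harvest_year", "production", "area", "yield"]])
print(coverage[["harvest_year", "coverage"]].drop_duplicates())
# 2005 still aggregates: the reporting district carries ~60% of the
# region's expected (Gaussian-smoothed) production, above the 50% gate.
# Were only the 40%-share district reporting, the year would be missing.
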