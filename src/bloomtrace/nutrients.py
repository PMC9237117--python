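"""Coastal vs. offshore monthly nutrient climatology with excess phosphate.

Surface bottle observations (date, lon, lat, nitrate, phosphate) are zoned
by distance to coast — *coastal* below 40 nautical miles, *offshore* beyond
60 nm, with the 40-60 nm band excluded so offshore bins are never touched by
recently upwelled coastal water — and binned into climatological months May
through September. Excess phosphate relative to the Redfield N:P ratio is

    P* = PO4 - NO3 / 16   (µmol L^-1),

positive where water is nitrogen-depleted but phosphorus-replete. Per
(month, zone, variable) bin the summary is box-whisker style: median and
quartiles of the full bin, whiskers at the most extreme points retained
after discarding outliers beyond 1.5 interquartile ranges from the
quartiles. Quartiles use linear interpolation between order statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .environment import distance_to_coast_field
from .fields_io import Grid, bilinear_masked

__all__ = [
    "classify_zone",
    "pstar",
    "monthly_whisker_stats",
    "COASTAL_MAX_NM",
    "OFFSHORE_MIN_NM",
    "CLIMATOLOGY_MONTHS",
]

COASTAL_MAX_NM = 40.0
OFFSHORE_MIN_NM = 60.0
CLIMATOLOGY_MONTHS = (5, 6, 7, 8, 9)  # May .. September
VARIABLES = ("no3", "po4", "pstar")


def classify_zone(dist_nm):
    """Zone a distance to coast: <40 nm coastal, >60 nm offshore, else excluded."""
    d = np.asarray(dist_nm, dtype=float)
    if np.any(d[~np.isnan(d)] < 0.0):
        raise ValueError("distance to coast must be non-negative")
    zone = np.where(
        d < COASTAL_MAX_NM, "coastal", np.where(d > OFFSHORE_MIN_NM, "offshore", "excluded")
    )
    return zone.item() if np.isscalar(dist_nm) else zone


def pstar(po4, no3):
    """Excess phosphate over the 1:16 Redfield P:N ratio: po4 - no3/16."""
    return np.asarray(po4, dtype=float) - np.asarray(no3, dtype=float) / 16.0


def _whisker_row(values: np.ndarray) -> dict:
    """Box-whisker summary of one bin with a 1.5*IQR outlier fence."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return {
            "median": np.nan, "q25": np.nan, "q75": np.nan,
            "whisker_lo": np.nan, "whisker_hi": np.nan,
            "n_used": 0, "n_outliers": 0,
        }
    q25, q75 = np.percentile(v, [25.0, 75.0])
    iqr = q75 - q25
    keep = (v >= q25 - 1.5 * iqr) & (v <= q75 + 1.5 * iqr)
    retained = v[keep]
    return {
        "median": float(np.median(v)),
        "q25": float(q25),
        "q75": float(q75),
        "whisker_lo": float(retained.min()),
        "whisker_hi": float(retained.max()),
        "n_used": int(retained.size),
        "n_outliers": int(v.size - retained.size),
    }


def monthly_whisker_stats(
    records: pd.DataFrame,
    grid: Grid | None = None,
    dist_field: np.ndarray | None = None,
    months=CLIMATOLOGY_MONTHS,
) -> pd.DataFrame:
    """Monthly per-zone whisker climatology of no3, po4 and P*.

    ``records`` needs columns date, lon, lat, no3, po4. Distance to coast is
    interpolated from ``dist_field`` on ``grid`` at each record position
    (the field is computed from the grid if not supplied); records in the
    40-60 nm band, or outside ``months``, contribute to no bin. Empty bins
    are reported with ``n_used`` 0 and NaN statistics, so every (month,
    zone, variable) combination appears exactly once.
    """
    if grid is None:
        raise ValueError("a grid (with land mask) is required for zoning")
    if dist_field is None:
        dist_field = distance_to_coast_field(grid)
    rec = records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    rec["month"] = rec["date"].dt.month
    rec["dist_nm"] = bilinear_masked(
        dist_field, grid, rec["lon"].to_numpy(), rec["lat"].to_numpy()
    )
    rec = rec[np.isfinite(rec["dist_nm"])]
    rec["zone"] = classify_zone(rec["dist_nm"].to_numpy())
    rec["pstar"] = pstar(rec["po4"].to_numpy(), rec["no3"].to_numpy())

    rows = []
    for month in months:
        for zone in ("coastal", "offshore"):
            sel = rec[(rec["month"] == month) & (rec["zone"] == zone)]
            for var in VARIABLES:
                row = {"month": month, "zone": zone, "variable": var}
                row.update(_whisker_row(sel[var].to_numpy() if len(sel) else np.array([])))
                rows.append(row)
    return pd.DataFrame(rows)
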