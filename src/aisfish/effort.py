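"""Fishing-effort aggregation in kW-days.

AIS-side effort: every fishing-labeled message represents one reporting
interval (nominally 5 minutes) of towing at the vessel's engine power, so
it contributes power * interval / 86400 kW-days to the 1x1 nautical-mile
grid cell containing it.  Logbook-side effort allocates each trip's whole
duration (departure to arrival, in days, times engine power) to the ICES
rectangles where catches were notified, proportionally to catch weight.
The two measure different things — AIS counts fishing time only, logbooks
whole days at sea — so the comparison is about spatial pattern (rank
correlation), not absolute magnitude.

The 1-NM grid is a local equirectangular grid with half-open cells: one
cell spans 1/60 degree of latitude and 1/n degrees of longitude, with n
chosen so cell width is as close to 1 NM as possible at the grid's
latitude while still dividing a degree evenly.  The anchor is the ICES
lattice point south-west of the data, so cells nest exactly inside the
0.5 x 1 degree statistical rectangles and re-aggregating the fine grid to
rectangles reproduces a direct rectangle-level computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ices import ices_encode

log = logging.getLogger(__name__)

SECONDS_PER_DAY = 86400.0
DEFAULT_INTERVAL_S = 300.0


@dataclass
class EffortGrid:
    """Per-cell fishing effort (kW-days) on a local equirectangular grid."""

    lat0: float
    lon0: float
    dlat: float
    dlon: float
    values: np.ndarray
    skipped_messages: int = 0

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def cell_center(self, i, j) -> tuple[np.ndarray, np.ndarray]:
        return (self.lat0 + (np.asarray(i) + 0.5) * self.dlat,
                self.lon0 + (np.asarray(j) + 0.5) * self.dlon)

    def to_frame(self) -> pd.DataFrame:
        """Non-empty cells as rows (lat, lon centroids, kw_days)."""
        i, j = np.nonzero(self.values)
        lat, lon = self.cell_center(i, j)
        return pd.DataFrame(dict(lat=lat, lon=lon, kw_days=self.values[i, j]))


def ais_effort(labeled: pd.DataFrame, power_kw, interval: float = DEFAULT_INTERVAL_S,
               cell_nm: float = 1.0) -> EffortGrid:
    """Grid the fishing-labeled messages into kW-days at ``cell_nm`` resolution.

    ``power_kw`` maps ais_vessel_id to engine power; messages from vessels
    without a power entry are skipped and counted.  Each fishing message
    adds power * interval / 86400 kW-days to its cell.
    """
    power = pd.Series(power_kw, dtype=float)
    fishing = labeled.loc[labeled["label"] == "fishing"].copy()
    # anchor on the ICES lattice so 1-NM cells nest exactly inside the
    # 0.5 x 1 degree rectangles and coarse re-aggregation is exact
    lat0 = float(np.floor(labeled["lat"].min() * 2) / 2)
    lon0 = float(np.floor(labeled["lon"].min()))
    dlat = cell_nm / 60.0
    n_sub = max(1, round(60.0 * np.cos(np.radians(lat0 + 0.25)) / cell_nm))
    dlon = 1.0 / n_sub

    p = fishing["ais_vessel_id"].map(power)
    skipped = int(p.isna().sum())
    if skipped:
        log.warning("%d fishing messages skipped: vessel has no register power",
                    skipped)
    fishing = fishing.loc[p.notna()]
    p = p.dropna().to_numpy()

    i = np.floor((fishing["lat"].to_numpy() - lat0) / dlat).astype(int)
    j = np.floor((fishing["lon"].to_numpy() - lon0) / dlon).astype(int)
    n_i = int(i.max()) + 1 if len(i) else 1
    n_j = int(j.max()) + 1 if len(j) else 1
    values = np.zeros((n_i, n_j))
    np.add.at(values, (i, j), p * interval / SECONDS_PER_DAY)
    return EffortGrid(lat0=lat0, lon0=lon0, dlat=dlat, dlon=dlon,
                      values=values, skipped_messages=skipped)


def allocate_trip_days(duration_days: float, catches: np.ndarray
                       ) -> tuple[np.ndarray, bool]:
    """Split a trip's duration across rectangles proportionally to catch.

    Zero total catch falls back to an equal split (flagged).  The returned
    allocation always sums to ``duration_days`` exactly.
    """
    catches = np.asarray(catches, dtype=float)
    total = catches.sum()
    if total <= 0:
        return np.full(len(catches), duration_days / len(catches)), True
    return duration_days * catches / total, False


def logbook_effort(logbook: pd.DataFrame, power_kw) -> pd.DataFrame:
    """Logbook-derived effort per ICES rectangle, in kW-days.

    Each trip's departure-to-arrival duration is converted to fractional
    days, split across its rectangles proportionally to catch weight, and
    multiplied by the vessel's engine power.  Returns one row per
    rectangle with the summed effort.
    """
    power = pd.Series(power_kw, dtype=float)
    rows = []
    for (vessel, trip), grp in logbook.groupby(["vessel_id", "trip_id"]):
        dep = pd.to_datetime(grp["departure"].iloc[0])
        arr = pd.to_datetime(grp["arrival"].iloc[0])
        if not dep < arr:
            raise ValueError(f"trip {trip}: departure not before arrival")
        duration = (arr - dep).total_seconds() / SECONDS_PER_DAY
        by_rect = grp.groupby("ices_rectangle")["catch_kg"].sum()
        days, flagged = allocate_trip_days(duration, by_rect.to_numpy())
        if flagged:
            log.warning("trip %s: zero total catch, equal split across rectangles",
                        trip)
        kw = float(power.get(vessel, np.nan))
        if np.isnan(kw):
            log.warning("trip %s: vessel %s has no register power, skipped",
                        trip, vessel)
            continue
        for rect, d in zip(by_rect.index, days):
            rows.append(dict(rectangle=rect, kw_days=d * kw))
    out = pd.DataFrame(rows, columns=["rectangle", "kw_days"])
    return out.groupby("rectangle", as_index=False)["kw_days"].sum()


def grid_to_rectangles(grid: EffortGrid) -> pd.DataFrame:
    """Re-aggregate the fine AIS grid to ICES rectangles (by cell centroid)."""
    cells = grid.to_frame()
    if cells.empty:
        return pd.DataFrame(columns=["rectangle", "kw_days"])
    cells["rectangle"] = [ices_encode(la, lo).code
                          for la, lo in zip(cells["lat"], cells["lon"])]
    return cells.groupby("rectangle", as_index=False)["kw_days"].sum()


def compare_efforts(grid: EffortGrid, logbook_eff: pd.DataFrame
                    ) -> tuple[pd.DataFrame, float]:
    """Per-rectangle AIS vs logbook effort and their Spearman correlation.

    Rectangles present on only one side enter with 0 on the other.  With
    disjoint supports or fewer than 2 rectangles the correlation is
    undefined and returned as NaN.
    """
    ais = grid_to_rectangles(grid).rename(columns={"kw_days": "ais_kw_days"})
    lb = logbook_eff.rename(columns={"kw_days": "logbook_kw_days"})
    table = ais.merge(lb, on="rectangle", how="outer").fillna(0.0)
    both = (table["ais_kw_days"] > 0) & (table["logbook_kw_days"] > 0)
    if len(table) < 2 or not both.any():
        log.warning("effort comparison: disjoint or trivial spatial support")
        return table, float("nan")
    rho = stats.spearmanr(table["ais_kw_days"], table["logbook_kw_days"]).statistic
    return table, float(rho)
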