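"""Validation of the fishing classification against logbook fishing grounds.

A vessel's use of space is summarised by a utilisation distribution (UD),
a bivariate probability density estimated by Gaussian kernel density on
its logbook fishing-operation coordinates.  Each classified AIS message is
scored by the UD raster value at its location, normalized per vessel by
the raster maximum so scores lie in [0, 1] with 1 at the heart of the
fishing grounds.  If the speed classification works, fishing-labeled
messages should score systematically higher than non-fishing ones; a
paired t test across vessels checks this.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

MIN_LOGBOOK_POINTS = 5
DEFAULT_CELL_DEG = 0.01


@dataclass
class UtilisationDistribution:
    """Kernel UD raster for one vessel on a regular lat/lon grid.

    ``values[i, j]`` is the density in the cell with latitude band i
    (south to north) and longitude band j (west to east); the density
    integrates to 1 over the raster (sum * cell area = 1, in degree^2).
    """

    vessel_id: str
    values: np.ndarray
    lat_min: float
    lon_min: float
    cell_size: float
    bandwidth: float
    n_points: int

    @property
    def max_value(self) -> float:
        return float(self.values.max())

    def lookup(self, lat, lon) -> np.ndarray:
        """Raster value at each point; 0 outside the raster bounds."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        i = np.floor((lat - self.lat_min) / self.cell_size).astype(int)
        j = np.floor((lon - self.lon_min) / self.cell_size).astype(int)
        n_i, n_j = self.values.shape
        inside = (i >= 0) & (i < n_i) & (j >= 0) & (j < n_j)
        out = np.zeros(lat.shape)
        out[inside] = self.values[i[inside], j[inside]]
        return out


def reference_bandwidth(lats: np.ndarray, lons: np.ndarray) -> float:
    """Reference-rule bandwidth h = 0.5 * (sd_x + sd_y) * n^(-1/6), degrees."""
    n = len(lats)
    return 0.5 * (np.std(lons) + np.std(lats)) * n ** (-1.0 / 6.0)


def estimate_ud(points: pd.DataFrame, bandwidth: float | None = None,
                cell_size: float = DEFAULT_CELL_DEG,
                vessel_id: str = "") -> UtilisationDistribution:
    """Estimate the kernel UD of one vessel from its logbook points.

    ``points`` needs lat/lon columns with at least 5 rows.  A bivariate
    Gaussian product kernel with a common bandwidth (reference rule unless
    given) is evaluated at cell centres of a grid covering the point
    bounding box padded by 3 bandwidths, then normalized to integrate to 1.
    """
    lats = points["lat"].to_numpy(dtype=float)
    lons = points["lon"].to_numpy(dtype=float)
    if len(lats) < MIN_LOGBOOK_POINTS:
        raise ValueError(f"need >= {MIN_LOGBOOK_POINTS} logbook points, got {len(lats)}")
    h = reference_bandwidth(lats, lons) if bandwidth is None else float(bandwidth)
    h = max(h, cell_size)  # never narrower than one cell
    pad = 3 * h
    lat_min, lat_max = lats.min() - pad, lats.max() + pad
    lon_min, lon_max = lons.min() - pad, lons.max() + pad
    n_i = int(np.ceil((lat_max - lat_min) / cell_size))
    n_j = int(np.ceil((lon_max - lon_min) / cell_size))
    ci = lat_min + (np.arange(n_i) + 0.5) * cell_size
    cj = lon_min + (np.arange(n_j) + 0.5) * cell_size
    # product Gaussian kernel, evaluated separably then summed over points
    ki = np.exp(-0.5 * ((ci[:, None] - lats[None, :]) / h) ** 2)
    kj = np.exp(-0.5 * ((cj[:, None] - lons[None, :]) / h) ** 2)
    values = ki @ kj.T / (len(lats) * 2 * np.pi * h * h)
    total = values.sum() * cell_size ** 2
    if total <= 0:
        raise ValueError("degenerate UD: zero total density")
    values /= total
    return UtilisationDistribution(vessel_id=vessel_id, values=values,
                                   lat_min=lat_min, lon_min=lon_min,
                                   cell_size=cell_size, bandwidth=h,
                                   n_points=len(lats))


def score_messages(messages: pd.DataFrame, ud: UtilisationDistribution
                   ) -> pd.DataFrame:
    """Overlay messages on the UD raster: raw cell value and [0,1] score.

    The normalized score divides by the vessel's raster maximum, so a
    message in the densest fishing-ground cell scores 1 and one outside
    the raster scores 0.
    """
    if ud.max_value <= 0:
        raise ValueError("zero-valued UD raster")
    out = messages.copy()
    raw = ud.lookup(out["lat"].to_numpy(), out["lon"].to_numpy())
    out["ud_raw"] = raw
    out["ud_score"] = raw / ud.max_value
    return out


@dataclass
class ValidationSummary:
    n_vessels: int
    fishing_mean: float
    fishing_sd: float
    nonfishing_mean: float
    nonfishing_sd: float
    t_statistic: float
    df: int
    p_value: float
    degenerate: bool = False


def paired_test(per_vessel: pd.DataFrame) -> ValidationSummary:
    """Two-sided paired t test of fishing vs non-fishing mean scores.

    ``per_vessel`` needs columns fishing_mean and nonfishing_mean, one row
    per vessel with both label groups.  Zero-variance nonzero differences
    make the statistic infinite; that case is reported as p = 0 with a
    degeneracy flag rather than raising.
    """
    pv = per_vessel.dropna(subset=["fishing_mean", "nonfishing_mean"])
    n = len(pv)
    if n < 2:
        raise ValueError("paired test needs >= 2 vessels with both label groups")
    diff = pv["fishing_mean"].to_numpy() - pv["nonfishing_mean"].to_numpy()
    degenerate = bool(np.allclose(np.std(diff), 0.0))
    if degenerate and not np.allclose(diff.mean(), 0.0):
        t, p = np.inf * np.sign(diff.mean()), 0.0
    elif degenerate:
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(pv["fishing_mean"], pv["nonfishing_mean"])
    return ValidationSummary(
        n_vessels=n,
        fishing_mean=float(pv["fishing_mean"].mean()),
        fishing_sd=float(pv["fishing_mean"].std(ddof=1)),
        nonfishing_mean=float(pv["nonfishing_mean"].mean()),
        nonfishing_sd=float(pv["nonfishing_mean"].std(ddof=1)),
        t_statistic=float(t), df=n - 1, p_value=float(p), degenerate=degenerate)


def validate_fleet(labeled: pd.DataFrame, logbook: pd.DataFrame,
                   matches: pd.DataFrame | None = None,
                   cell_size: float = DEFAULT_CELL_DEG
                   ) -> tuple[ValidationSummary, pd.DataFrame]:
    """Full validation: per-vessel UDs, message scores, fleet paired test.

    ``labeled`` carries ais_vessel_id and a label column; ``logbook`` is
    keyed by register vessel_id, so ``matches`` (from the linkage step)
    translates between the two.  Vessels with too few logbook points or a
    missing label group are excluded and logged.  Returns the fleet
    summary and the per-vessel mean-score table.
    """
    if matches is not None:
        key = matches.loc[matches["method"] != "unmatched",
                          ["register_id", "ais_vessel_id"]]
        lb = logbook.merge(key, left_on="vessel_id", right_on="register_id")
    else:
        lb = logbook.rename(columns={"vessel_id": "ais_vessel_id"})
    rows = []
    for vessel, msgs in labeled.groupby("ais_vessel_id"):
        pts = lb[lb["ais_vessel_id"] == vessel]
        if len(pts) < MIN_LOGBOOK_POINTS:
            log.info("vessel %s excluded: %d logbook points", vessel, len(pts))
            continue
        ud = estimate_ud(pts, cell_size=cell_size, vessel_id=str(vessel))
        scored = score_messages(msgs, ud)
        means = scored.groupby("label")["ud_score"].mean()
        if {"fishing", "non-fishing"} - set(means.index):
            log.info("vessel %s excluded: missing a label group", vessel)
            continue
        rows.append(dict(ais_vessel_id=vessel, fishing_mean=means["fishing"],
                         nonfishing_mean=means["non-fishing"],
                         n_messages=len(scored)))
    per_vessel = pd.DataFrame(rows)
    return paired_test(per_vessel), per_vessel
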